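"""SAXS shape analysis.

Implements the standard solution-scattering toolbox used to characterise the
dumbbell-to-globule collapse of a two-lobed protein: Guinier analysis,
the dimensionless Kratky transform (globular reference peak at
(sqrt(3), 3/e ~ 1.104)), pair-distance distribution P(r) by regularised
indirect Fourier transform, exact Debye forward scattering from bead or
atomic coordinates, reduced chi^2 model comparison, the CorMap longest-run
frame-similarity test, and genetic-algorithm ensemble selection of conformer
subsets whose averaged scattering fits the data.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy.spatial.distance import pdist

from .io import ScatteringCurve

logger = logging.getLogger("camdyn.saxs")

__all__ = [
    "GuinierResult",
    "PairDistribution",
    "FitQuality",
    "EnsembleFit",
    "guinier_fit",
    "dimensionless_kratky",
    "kratky_peak",
    "ift_pr",
    "estimate_dmax",
    "debye_scattering",
    "sphere_form_factor",
    "reduced_chi2",
    "cormap_compare",
    "longest_run_survival",
    "ensemble_select",
]


# --------------------------------------------------------------------------
# Guinier analysis
# --------------------------------------------------------------------------

@dataclasses.dataclass
class GuinierResult:
    """Radius of gyration and forward scattering from the Guinier law.

    ln I(q) = ln I(0) - q^2 Rg^2 / 3, fitted over a self-consistent low-q
    window with q_max * Rg below the configured limit.
    """

    Rg: float
    I0: float
    Rg_err: float
    I0_err: float
    fit_range: tuple[float, float]
    n_points: int
    qRg_max: float


def _weighted_linfit(x, y, w):
    """Weighted least squares line y = a + b x; returns (a, b, var_a, var_b)."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx <= 0:
        raise ValueError("degenerate abscissa in linear fit")
    b = np.sum(w * (x - xm) * (y - ym)) / sxx
    a = ym - b * xm
    # scale covariance by reduced chi^2 so errors reflect actual scatter
    n = len(x)
    resid = y - (a + b * x)
    s2 = np.sum(w * resid**2) / max(n - 2, 1)
    var_b = s2 / sxx
    var_a = s2 * (1.0 / W + xm**2 / sxx)
    return a, b, var_a, var_b


def guinier_fit(
    curve: ScatteringCurve,
    qRg_limit: float = 1.3,
    q_min: float | None = None,
    max_iter: int = 50,
) -> GuinierResult:
    """Self-consistent Guinier fit of the low-q region.

    Starts from the smallest usable q and iteratively shrinks the upper end
    of the window until q_max * Rg <= qRg_limit.  Weighted by 1/sigma^2 of
    ln I.  Raises ``ValueError`` when no convergent region with a negative
    slope exists.
    """
    m = (curve.I > 0) & np.isfinite(curve.I)
    if q_min is not None:
        m &= curve.q >= q_min
    q, I, sig = curve.q[m], curve.I[m], curve.sigma[m]
    if q.size < 3:
        raise ValueError("no Guinier region: fewer than 3 usable points")
    x = q**2
    y = np.log(I)
    w = (I / sig) ** 2  # sigma_lnI = sigma/I

    hi = q.size  # exclusive upper index of the window
    Rg_prev = None
    for _ in range(max_iter):
        if hi < 3:
            raise ValueError("no Guinier region: window shrank below 3 points")
        a, b, va, vb = _weighted_linfit(x[:hi], y[:hi], w[:hi])
        if b >= 0:
            # shrink and retry: upturns at higher q can hide a valid region
            hi -= 1
            continue
        Rg = float(np.sqrt(-3.0 * b))
        new_hi = int(np.searchsorted(q, qRg_limit / Rg, side="right"))
        new_hi = min(new_hi, q.size)
        if new_hi < 3:
            new_hi = 3
        if new_hi == hi and Rg_prev is not None and abs(Rg - Rg_prev) < 1e-9 * Rg:
            break
        if new_hi == hi:
            break
        hi, Rg_prev = new_hi, Rg
    else:
        raise ValueError("no Guinier region: range search did not converge")

    a, b, va, vb = _weighted_linfit(x[:hi], y[:hi], w[:hi])
    if b >= 0:
        raise ValueError("no Guinier region: non-negative slope")
    Rg = float(np.sqrt(-3.0 * b))
    I0 = float(np.exp(a))
    Rg_err = float(1.5 * np.sqrt(vb) / Rg)  # dRg/db = -3/(2 Rg)
    return GuinierResult(
        Rg=Rg,
        I0=I0,
        Rg_err=Rg_err,
        I0_err=float(I0 * np.sqrt(va)),
        fit_range=(float(q[0]), float(q[hi - 1])),
        n_points=int(hi),
        qRg_max=float(q[hi - 1] * Rg),
    )


# --------------------------------------------------------------------------
# Dimensionless Kratky
# --------------------------------------------------------------------------

def dimensionless_kratky(curve: ScatteringCurve, g: GuinierResult) -> np.ndarray:
    """Return (qRg, (qRg)^2 I/I0) pairs as an (N, 2) array.

    Globular particles peak at (sqrt(3), 3/e ~ 1.104); extended or flexible
    chains push the maximum to higher coordinates.
    """
    if g.I0 <= 0:
        raise ValueError("I0 must be positive")
    x = curve.q * g.Rg
    y = x**2 * curve.I / g.I0
    return np.column_stack([x, y])


def kratky_peak(xy: np.ndarray) -> tuple[float, float]:
    """Coordinates of the maximum of a dimensionless Kratky curve.

    Refines the grid maximum with a parabolic interpolation of the three
    surrounding points so the analytic peak (sqrt(3), 3/e) is recovered to
    high accuracy on reasonable grids.
    """
    x, y = xy[:, 0], xy[:, 1]
    i = int(np.argmax(y))
    if 0 < i < len(x) - 1:
        x0, x1, x2 = x[i - 1 : i + 2]
        y0, y1, y2 = y[i - 1 : i + 2]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        A = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        B = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        if A < 0:
            xv = -B / (2 * A)
            C = y1 - A * x1**2 - B * x1
            return float(xv), float(A * xv**2 + B * xv + C)
    return float(x[i]), float(y[i])


# --------------------------------------------------------------------------
# Indirect Fourier transform P(r)
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PairDistribution:
    """Real-space pair-distance distribution from regularised IFT."""

    r: np.ndarray
    p: np.ndarray
    Dmax: float
    alpha: float
    Rg_real: float
    I0_real: float
    chi2_red: float


def _ift_kernel(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """K[i, j] = 4 pi sinc(q_i r_j) dr   with sin(x)/x -> 1 at x = 0."""
    dr = r[1] - r[0]
    qr = np.outer(q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(qr > 1e-12, np.sin(qr) / np.where(qr > 1e-12, qr, 1.0), 1.0)
    K = 4.0 * np.pi * K * dr
    # trapezoid end-correction
    K[:, 0] *= 0.5
    K[:, -1] *= 0.5
    return K


def ift_pr(
    curve: ScatteringCurve,
    Dmax: float,
    alpha: float | None = None,
    n_r: int = 101,
) -> PairDistribution:
    """Regularised indirect Fourier transform of I(q) to P(r).

    Solves I(q) = 4 pi int_0^Dmax p(r) sin(qr)/(qr) dr on an ``n_r``-point
    grid by least squares with a second-difference smoothness penalty of
    weight *alpha* and the endpoint constraints p(0) = p(Dmax) = 0.  When
    *alpha* is None it is chosen by an L-curve corner search.
    """
    if Dmax <= 0:
        raise ValueError("Dmax must be positive")
    q_res = np.pi / curve.q.max()
    if Dmax < q_res:
        warnings.warn(
            f"Dmax={Dmax:.1f} A below the resolution limit pi/q_max={q_res:.1f} A"
        )
    r = np.linspace(0.0, Dmax, n_r)
    K = _ift_kernel(curve.q, r)
    # endpoint constraints: solve only for the interior points
    A = K[:, 1:-1] / curve.sigma[:, None]
    b = curve.I / curve.sigma
    n_int = n_r - 2
    # second differences over the full grid including the fixed zero endpoints
    D = np.zeros((n_r - 2, n_int))
    for k in range(n_r - 2):
        for j, c in ((k - 1, 1.0), (k, -2.0), (k + 1, 1.0)):
            if 0 <= j < n_int:
                D[k, j] = c
    # scale the penalty so alpha is roughly dimensionless across problems
    scale = np.linalg.norm(A, "fro") / max(np.linalg.norm(D, "fro"), 1e-30)

    def solve(al):
        M = np.vstack([A, np.sqrt(al) * scale * D])
        rhs = np.concatenate([b, np.zeros(n_r - 2)])
        sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        return sol

    if alpha is None:
        # discrepancy-style rule: the largest (smoothest) alpha whose misfit
        # stays within a few percent of the best attainable chi^2
        alphas = np.logspace(-6, 2, 17)
        sols = [solve(al) for al in alphas]
        dof = max(len(curve.q) - 1, 1)
        chi2s = np.array([np.sum((A @ s - b) ** 2) / dof for s in sols])
        chi2_min = chi2s.min()
        tol = chi2_min * 1.05 + 0.05
        ok = np.flatnonzero(chi2s <= tol)
        i_best = int(ok.max()) if ok.size else int(np.argmin(chi2s))
        alpha = float(alphas[i_best])
        p_int = sols[i_best]
    else:
        p_int = solve(alpha)

    p = np.zeros(n_r)
    p[1:-1] = p_int
    resid = (K @ p - curve.I) / curve.sigma
    # conventional normalisation: the smoothness penalty keeps the effective
    # parameter count far below the grid size, so N-1 is the usual divisor
    chi2 = float(np.sum(resid**2) / max(len(curve.q) - 1, 1))

    integral = np.trapezoid(p, r)
    if integral <= 0:
        warnings.warn("P(r) integrates to a non-positive value")
        Rg_real = float("nan")
    else:
        Rg2 = np.trapezoid(r**2 * p, r) / (2.0 * integral)
        Rg_real = float(np.sqrt(Rg2)) if Rg2 > 0 else float("nan")
    I0_real = float(4.0 * np.pi * integral)
    return PairDistribution(r, p, float(Dmax), float(alpha), Rg_real, I0_real, chi2)


def estimate_dmax(
    curve: ScatteringCurve,
    grid: np.ndarray,
    alpha: float | None = 1e-2,
) -> tuple[float, np.ndarray]:
    """Scan ift_pr over a Dmax grid and pick the best by a composite score.

    Score = chi2_red + negativity penalty + endpoint-slope penalty + a mild
    parsimony term in Dmax.  The negativity term punishes oscillating
    solutions (Dmax too large), the slope term truncated distributions
    (Dmax too small), and parsimony selects the smallest support that still
    fits, mirroring the usual manual criterion.  Returns (best Dmax,
    (Dmax, score) profile).  Warns when the profile is not unimodal.
    """
    grid = np.asarray(grid, float)
    scores = np.empty_like(grid)
    span = grid.max() - grid.min() or 1.0
    for i, dmax in enumerate(grid):
        pr = ift_pr(curve, dmax, alpha=alpha)
        pos = np.sum(np.abs(pr.p))
        neg = np.sum(np.abs(np.minimum(pr.p, 0.0)))
        neg_frac = neg / pos if pos > 0 else 1.0
        pmax = np.max(np.abs(pr.p)) or 1.0
        dr = pr.r[1] - pr.r[0]
        end_slope = abs(pr.p[-2] - pr.p[-1]) / dr * dmax / pmax
        parsimony = 0.5 * (dmax - grid.min()) / span
        scores[i] = pr.chi2_red + 20.0 * neg_frac + 0.05 * end_slope + parsimony
    i_best = int(np.argmin(scores))
    # unimodality check on the smoothed score profile
    sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(scores))))) // 2
    if sign_changes > 1:
        warnings.warn("Dmax score profile is multimodal; argmin returned")
    return float(grid[i_best]), np.column_stack([grid, scores])


# --------------------------------------------------------------------------
# Debye forward scattering
# --------------------------------------------------------------------------

def debye_scattering(
    coords: np.ndarray,
    qgrid: np.ndarray,
    weights: np.ndarray | None = None,
    use_histogram: bool | None = None,
    hist_bin: float = 0.1,
) -> ScatteringCurve:
    """Vacuum Debye scattering I(q) = sum_ij f_i f_j sin(q r_ij)/(q r_ij).

    *coords* is (N, 3) in Angstrom; *weights* are per-scatterer form-factor
    amplitudes (unit by default).  For large N a pair-distance histogram
    accelerates the double sum; bin width 0.1 A keeps it within 0.1% of the
    exact sum at typical q ranges.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("coords must be a non-empty (N, 3) array")
    if not np.all(np.isfinite(coords)):
        raise ValueError("NaN/inf coordinates")
    q = np.asarray(qgrid, float)
    n = coords.shape[0]
    f = np.ones(n) if weights is None else np.asarray(weights, float)
    self_term = np.sum(f**2)
    if n == 1:
        I = np.full_like(q, self_term)
        return ScatteringCurve(q, I, np.ones_like(q), {"model": "debye"})
    if use_histogram is None:
        use_histogram = n > 400
    if use_histogram:
        d = pdist(coords)
        w = np.outer(f, f)[np.triu_indices(n, 1)] if weights is not None else np.ones_like(d)
        nbins = max(int(np.ceil(d.max() / hist_bin)), 1)
        rng_ = (0.0, nbins * hist_bin)
        hist, _ = np.histogram(d, bins=nbins, range=rng_, weights=w)
        dsum, _ = np.histogram(d, bins=nbins, range=rng_, weights=w * d)
        # evaluate the kernel at each bin's weight-averaged distance: second-
        # order accurate, keeps the result within 0.1% of the exact sum
        nonzero = hist > 0
        centers = dsum[nonzero] / hist[nonzero]
        qr = np.outer(q, centers)
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.where(qr > 1e-12, np.sin(qr) / np.where(qr > 1e-12, qr, 1.0), 1.0)
        I = self_term + 2.0 * sinc @ hist[nonzero]
    else:
        d = pdist(coords)
        fw = np.outer(f, f)[np.triu_indices(n, 1)]
        qr = np.outer(q, d)
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.where(qr > 1e-12, np.sin(qr) / np.where(qr > 1e-12, qr, 1.0), 1.0)
        I = self_term + 2.0 * sinc @ fw
    return ScatteringCurve(q, I, np.ones_like(q), {"model": "debye", "n_scatterers": n})


def sphere_form_factor(q: np.ndarray, radius: float, I0: float = 1.0) -> np.ndarray:
    """Analytic solid-sphere intensity, used as an independent oracle."""
    q = np.asarray(q, float)
    x = q * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(
            x > 1e-8, 3.0 * (np.sin(x) - x * np.cos(x)) / np.where(x > 1e-8, x**3, 1.0), 1.0
        )
    return I0 * amp**2


# --------------------------------------------------------------------------
# Reduced chi^2
# --------------------------------------------------------------------------

@dataclasses.dataclass
class FitQuality:
    chi2_red: float
    scale: float
    offset: float
    residuals: np.ndarray


def reduced_chi2(
    model: ScatteringCurve, data: ScatteringCurve, fit_offset: bool = False
) -> FitQuality:
    """Reduced chi^2 of a model curve against data with optimal scaling.

    chi2_red = 1/(N-k) * sum((I_d - c I_m - b)^2 / sigma^2) with the scale c
    (and offset b when *fit_offset*) solved analytically; the normalisation
    counts them as fitted nuisance parameters.
    """
    if not np.array_equal(model.q, data.q):
        lo = max(model.q.min(), data.q.min())
        hi = min(model.q.max(), data.q.max())
        qc = data.q[(data.q >= lo) & (data.q <= hi)]
        if qc.size < 2:
            raise ValueError("fewer than 2 overlapping points")
        model = model.interpolate_to(qc)
        data = data.truncate(lo, hi)
    w = 1.0 / data.sigma**2
    Im, Id = model.I, data.I
    if fit_offset:
        X = np.column_stack([Im, np.ones_like(Im)])
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * Id))
        c, b = float(beta[0]), float(beta[1])
        k = 2
    else:
        c = float(np.sum(w * Im * Id) / np.sum(w * Im**2))
        b = 0.0
        k = 1
    resid = (Id - c * Im - b) / data.sigma
    n = len(Id)
    chi2 = float(np.sum(resid**2) / max(n - k, 1))
    return FitQuality(chi2_red=chi2, scale=c, offset=b, residuals=resid)


# --------------------------------------------------------------------------
# CorMap longest-run test
# --------------------------------------------------------------------------

def _count_no_long_run(n: int, m: int) -> int:
    """Number of length-n binary sequences whose longest run is <= m.

    Equals 2 * (compositions of n into parts of size <= m): pick the first
    symbol, then run lengths alternate symbols.
    """
    if m <= 0:
        return 0
    comp = np.zeros(n + 1, dtype=object)
    comp[0] = 1
    for i in range(1, n + 1):
        comp[i] = sum(comp[i - k] for k in range(1, min(m, i) + 1))
    return 2 * comp[n]


def longest_run_survival(n: int, C: int) -> float:
    """P(longest same-sign run >= C) for n fair Bernoulli signs."""
    if C <= 1:
        return 1.0
    if C > n:
        return 0.0
    total = 2**n
    return float((total - _count_no_long_run(n, C - 1)) / total)


def cormap_compare(a: ScatteringCurve, b: ScatteringCurve) -> tuple[int, float]:
    """Correlation-map similarity of two frames on a common q-grid.

    Returns the longest run of consecutive same-sign point-wise differences
    and the exact probability of a run at least that long under the fair-sign
    null.  Zero differences are conservatively broken as alternating signs.
    """
    if not np.array_equal(a.q, b.q):
        raise ValueError("curves must share a common q-grid")
    d = a.I - b.I
    n = d.size
    if n < 10:
        raise ValueError("need at least 10 points for a reliable run test")
    signs = np.sign(d)
    # conservative tie-break: zeros alternate, capping any run they sit in
    flip = 1.0
    for i in range(n):
        if signs[i] == 0:
            signs[i] = flip
            flip = -flip
    runs = np.diff(np.flatnonzero(np.concatenate(([True], signs[1:] != signs[:-1], [True]))))
    C = int(runs.max())
    return C, longest_run_survival(n, C)


# --------------------------------------------------------------------------
# Genetic-algorithm ensemble selection
# --------------------------------------------------------------------------

@dataclasses.dataclass
class EnsembleFit:
    """Best conformer multiset found by the genetic algorithm."""

    member_indices: tuple[int, ...]
    weights: np.ndarray
    chi2: float
    scale: float
    generations: int
    rg_selected: np.ndarray | None = None  # per-run best-member Rg values


def _ensemble_chi2(idx, pool_I, data_I, w):
    Im = pool_I[list(idx)].mean(axis=0)
    c = np.sum(w * Im * data_I) / np.sum(w * Im**2)
    resid2 = w * (data_I - c * Im) ** 2
    n = data_I.size
    return float(np.sum(resid2) / max(n - 1, 1)), float(c)


def ensemble_select(
    pool_curves: list[ScatteringCurve] | np.ndarray,
    data: ScatteringCurve,
    ensemble_size: int = 2,
    population: int = 100,
    generations: int = 200,
    mutation_rate: float = 0.1,
    elitism: int = 2,
    n_runs: int = 1,
    seed: int | None = None,
    pool_rg: np.ndarray | None = None,
) -> EnsembleFit:
    """Select a conformer multiset whose averaged curve best fits the data.

    Chromosomes are multisets of pool indices (repetition allowed, i.e.
    implicit weighting); fitness is the reduced chi^2 of the equal-weight
    average after analytic scaling.  Tournament selection, uniform
    crossover, per-gene mutation, and elitism; ``n_runs`` independent
    restarts return the overall best and, when *pool_rg* is given, the
    distribution of selected-member Rg values across runs.
    """
    if isinstance(pool_curves, np.ndarray):
        pool_I = np.asarray(pool_curves, float)
    else:
        for c in pool_curves:
            if not np.array_equal(c.q, data.q):
                raise ValueError("pool curves must be on the data q-grid")
        pool_I = np.stack([c.I for c in pool_curves])
    n_pool = pool_I.shape[0]
    if n_pool < 1 or ensemble_size < 1:
        raise ValueError("empty pool or ensemble")
    w = 1.0 / data.sigma**2
    rng = np.random.default_rng(seed)

    best_overall = None
    rg_sel = [] if pool_rg is not None else None
    for _run in range(n_runs):
        pop = rng.integers(0, n_pool, size=(population, ensemble_size))
        fitness = np.array([_ensemble_chi2(ind, pool_I, data.I, w)[0] for ind in pop])
        baseline = fitness.min()
        for _gen in range(generations):
            order = np.argsort(fitness)
            new_pop = [pop[i].copy() for i in order[:elitism]]
            while len(new_pop) < population:
                # tournament of 2, twice, then uniform crossover
                i1, i2 = rng.integers(0, population, 2)
                p1 = pop[i1] if fitness[i1] < fitness[i2] else pop[i2]
                i1, i2 = rng.integers(0, population, 2)
                p2 = pop[i1] if fitness[i1] < fitness[i2] else pop[i2]
                mask = rng.random(ensemble_size) < 0.5
                child = np.where(mask, p1, p2)
                mut = rng.random(ensemble_size) < mutation_rate
                child[mut] = rng.integers(0, n_pool, mut.sum())
                new_pop.append(child)
            pop = np.array(new_pop)
            fitness = np.array(
                [_ensemble_chi2(ind, pool_I, data.I, w)[0] for ind in pop]
            )
        i_best = int(np.argmin(fitness))
        chi2, scale = _ensemble_chi2(pop[i_best], pool_I, data.I, w)
        if chi2 > baseline + 1e-12:
            warnings.warn("GA failed to improve over its random initial population")
        if rg_sel is not None:
            rg_sel.extend(np.asarray(pool_rg)[pop[i_best]])
        if best_overall is None or chi2 < best_overall[0]:
            best_overall = (chi2, scale, tuple(sorted(int(i) for i in pop[i_best])))

    chi2, scale, members = best_overall
    uniq, counts = np.unique(members, return_counts=True)
    weights = np.zeros(len(uniq))
    weights[:] = counts / counts.sum()
    return EnsembleFit(
        member_indices=tuple(int(u) for u in uniq),
        weights=weights,
        chi2=chi2,
        scale=scale,
        generations=generations,
        rg_selected=np.array(rg_sel) if rg_sel is not None else None,
    )
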