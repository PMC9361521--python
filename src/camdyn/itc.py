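"""One-site binding analysis of isothermal titration calorimetry data.

The forward model is the standard Wiseman single-site isotherm with
perfusion (displaced-volume) bookkeeping: after injection i the cumulative
binding heat is Q_i = n Theta_i [M]_i dH V0, with Theta_i the bound fraction
from the one-site quadratic, and the observed injection heat is
Q_i - Q_{i-1} plus the average-concentration displacement correction and an
optional constant dilution offset.  Heats are in microcalories and molar
enthalpies in cal/mol throughout.

`OneSiteBinding` follows the model/fit/results pattern: build it from a
:class:`Titration`, call :meth:`~OneSiteBinding.fit`, and inspect the
returned :class:`BindingFit` (estimates, covariance-based errors, Wiseman
c-value, residuals, ``summary()``).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import least_squares

__all__ = ["Titration", "BindingFit", "OneSiteBinding", "one_site_heats"]


@dataclasses.dataclass
class Titration:
    """An ITC titration: cell/syringe concentrations and injection heats."""

    cell_conc: float  # M, macromolecule in the cell
    syringe_conc: float  # M, ligand in the syringe
    cell_volume: float  # mL
    injections: np.ndarray  # uL per injection
    heats: np.ndarray | None = None  # ucal per injection
    temperature: float = 298.15  # K

    def __post_init__(self):
        self.injections = np.asarray(self.injections, float)
        if self.heats is not None:
            self.heats = np.asarray(self.heats, float)
            if self.heats.shape != self.injections.shape:
                raise ValueError("injections and heats must have equal length")
            if not np.all(np.isfinite(self.heats)):
                raise ValueError("non-finite heats")
        if min(self.cell_conc, self.syringe_conc, self.cell_volume) <= 0:
            raise ValueError("concentrations and cell volume must be positive")
        if self.injections.size == 0 or np.any(self.injections <= 0):
            raise ValueError("injections must be non-empty and positive")
        if self.injections.sum() > 0.5 * self.cell_volume * 1000.0:
            raise ValueError("cumulative injected volume exceeds half the cell volume")


def _concentrations(t: Titration) -> tuple[np.ndarray, np.ndarray]:
    """Per-injection total [M] and [X] in the cell with perfusion dilution."""
    v0 = t.cell_volume * 1e-3  # L
    dv_cum = np.cumsum(t.injections) * 1e-6  # L
    # standard perfusion-cell bookkeeping (overfill displaces mixed content)
    macro = t.cell_conc * (1.0 - dv_cum / (2.0 * v0)) / (1.0 + dv_cum / (2.0 * v0))
    lig = t.syringe_conc * (dv_cum / v0) / (1.0 + dv_cum / (2.0 * v0))
    return macro, lig


def one_site_heats(
    params: tuple[float, float, float, float], titration: Titration
) -> np.ndarray:
    """Per-injection heats (ucal) of the one-site model.

    *params* = (kd [M], n sites, dH [cal/mol], dilution_offset [ucal]).
    """
    kd, n, dh, offset = params
    if kd <= 0 or n <= 0:
        raise ValueError("kd and n must be positive")
    v0 = titration.cell_volume * 1e-3
    macro, lig = _concentrations(titration)
    nm = n * macro
    b = 1.0 + lig / nm + kd / nm
    disc = b**2 - 4.0 * lig / nm
    if np.any(disc < 0):
        raise ValueError("unphysical bound fraction (negative discriminant)")
    theta = 0.5 * (b - np.sqrt(disc))
    if np.any((theta < -1e-9) | (theta > 1 + 1e-9)):
        raise ValueError("unphysical bound fraction")
    q = n * theta * macro * dh * v0  # cal, cumulative
    q_prev = np.concatenate([[0.0], q[:-1]])
    dv = titration.injections * 1e-6
    dq = q - q_prev + (dv / v0) * 0.5 * (q + q_prev)
    return dq * 1e6 + offset  # ucal


@dataclasses.dataclass
class BindingFit:
    """One-site fit results: estimates, 1-SD errors, diagnostics."""

    kd: float
    n: float
    dH: float
    dilution_offset: float
    kd_err: float
    n_err: float
    dH_err: float
    offset_err: float
    c_value: float
    chi2_red: float
    residuals: np.ndarray
    converged: bool
    warnings: list[str] = dataclasses.field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "One-site binding fit",
            "-" * 44,
            f"K_D          {self.kd * 1e6:10.3g} +/- {self.kd_err * 1e6:.3g} uM",
            f"n            {self.n:10.3g} +/- {self.n_err:.3g} sites",
            f"dH           {self.dH / 1000:10.4g} +/- {self.dH_err / 1000:.3g} kcal/mol",
            f"offset       {self.dilution_offset:10.3g} +/- {self.offset_err:.3g} ucal",
            f"Wiseman c    {self.c_value:10.3g}",
            f"chi2_red     {self.chi2_red:10.3g}",
            f"converged    {self.converged}",
        ]
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)


class OneSiteBinding:
    """One-site ITC binding model fitted by nonlinear least squares.

    Parameters
    ----------
    titration : Titration with measured ``heats``.
    blank : optional blank titration (titrant into buffer); its heats are
        subtracted point-wise and the dilution offset is then held at zero.
    fit_offset : fit a constant per-injection dilution heat (default True
        when no blank is given).
    exclude_first : drop the first injection (syringe-diffusion artifact).
    """

    def __init__(
        self,
        titration: Titration,
        blank: Titration | None = None,
        fit_offset: bool | None = None,
        exclude_first: bool = False,
    ):
        if titration.heats is None:
            raise ValueError("titration carries no measured heats")
        self.titration = titration
        self.heats = titration.heats.copy()
        if blank is not None:
            if blank.heats is None or blank.heats.shape != self.heats.shape:
                raise ValueError("blank must carry heats of matching length")
            self.heats = self.heats - blank.heats
        self.fit_offset = fit_offset if fit_offset is not None else blank is None
        self.exclude_first = exclude_first
        self.mask = np.ones(self.heats.size, bool)
        if exclude_first:
            self.mask[0] = False
        if self.mask.sum() < 6:
            raise ValueError("need at least 6 informative injections")

    def fit(
        self,
        kd0: float = 1e-6,
        n0: float = 1.0,
        dh0: float | None = None,
    ) -> BindingFit:
        y = self.heats[self.mask]
        if dh0 is None:
            # rough enthalpy scale from the first retained heat
            lig_per_inj = (
                self.titration.syringe_conc * self.titration.injections[self.mask][0] * 1e-6
            )
            dh0 = (y[0] * 1e-6) / max(lig_per_inj, 1e-30)
            if dh0 == 0:
                dh0 = -1e4

        def residual(theta):
            log_kd, n, dh, off = theta
            model = one_site_heats(
                (np.exp(log_kd), n, dh, off if self.fit_offset else 0.0),
                self.titration,
            )
            return model[self.mask] - y

        x0 = np.array([np.log(kd0), n0, dh0, 0.0])
        res = least_squares(
            residual,
            x0,
            bounds=([np.log(1e-12), 1e-3, -np.inf, -np.inf],
                    [np.log(1.0), 100.0, np.inf, np.inf]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
        )
        log_kd, n, dh, off = res.x
        kd = float(np.exp(log_kd))
        m, p = res.fun.size, res.x.size - (0 if self.fit_offset else 1)
        dof = max(m - p, 1)
        s2 = float(res.fun @ res.fun) / dof
        # covariance from the Jacobian; transform log_kd back to kd
        try:
            JtJ = res.jac.T @ res.jac
            cov = np.linalg.pinv(JtJ) * s2
            errs = np.sqrt(np.maximum(np.diag(cov), 0.0))
            kd_err = float(kd * errs[0])
            n_err, dh_err, off_err = map(float, errs[1:])
        except np.linalg.LinAlgError:
            kd_err = n_err = dh_err = off_err = float("nan")
        c = n * self.titration.cell_conc / kd
        warns = []
        if c < 1 or c > 1000:
            warns.append(
                f"Wiseman c = {c:.3g} outside [1, 1000]: fitted K_D unreliable"
            )
            warnings.warn(warns[-1])
        if not res.success:
            warns.append("optimizer did not report convergence; best-found returned")
        return BindingFit(
            kd=kd,
            n=float(n),
            dH=float(dh),
            dilution_offset=float(off if self.fit_offset else 0.0),
            kd_err=kd_err,
            n_err=n_err,
            dH_err=dh_err,
            offset_err=off_err if self.fit_offset else 0.0,
            c_value=float(c),
            chi2_red=s2,
            residuals=res.fun,
            converged=bool(res.success),
            warnings=warns,
        )


def one_site_fit(
    titration: Titration, blank: Titration | None = None, **kwargs
) -> BindingFit:
    """Functional wrapper around :class:`OneSiteBinding`."""
    return OneSiteBinding(titration, blank=blank).fit(**kwargs)
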