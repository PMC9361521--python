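"""Differential HDX-MS processing.

Peptide-level deuterium-uptake bookkeeping for a two-state (free vs
ligand-bound) continuous-labelling experiment: deuterium-fraction
accounting through sequential mixing steps, theoretical maximum exchangeable
amides, relative fractional uptake (RFU), per-time and time-averaged state
differences, and per-peptide significance testing with two Wald tests
(a magnitude test on the state main effect and a kinetics test on the
state x time interaction) under Benjamini-Hochberg FDR control at 5%.

No back-exchange correction is applied anywhere; results are relative
deuterium levels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HDXDataset",
    "UptakeStats",
    "deuterium_fraction",
    "max_exchangeable",
    "fractional_uptake",
    "delta_uptake",
    "wald_fdr",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclasses.dataclass
class HDXDataset:
    """Peptide x state x time x replicate deuterium uptake table.

    ``data`` columns: peptide, start, end, sequence, state, time, replicate,
    uptake (Da).  ``d_fraction`` is the deuterium excess of the labelling
    mixture used as the RFU denominator correction.
    """

    data: pd.DataFrame
    d_fraction: float = 0.80

    def __post_init__(self):
        required = {"peptide", "start", "end", "sequence", "state", "time",
                    "replicate", "uptake"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"uptake table missing columns {sorted(missing)}")
        if not 0 < self.d_fraction <= 1:
            raise ValueError("d_fraction must lie in (0, 1]")
        bad = self.data[self.data.start >= self.data.end]
        if len(bad):
            raise ValueError("peptide start must be below end")
        # flag incomplete replicate blocks per peptide x state x time
        counts = self.data.groupby(["peptide", "state", "time"]).size()
        self.incomplete_blocks = counts[counts != counts.max()].index.tolist()

    @property
    def states(self) -> list[str]:
        return sorted(self.data.state.unique())

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data.time.unique())

    def peptide_table(self) -> pd.DataFrame:
        return (
            self.data[["peptide", "start", "end", "sequence"]]
            .drop_duplicates("peptide")
            .set_index("peptide")
            .sort_index()
        )


def deuterium_fraction(stages: list[tuple[float, float]]) -> float:
    """Volume-weighted deuterium fraction after sequential mixing.

    Each stage is (added volume, D-fraction of the added liquid); the first
    stage initialises the pot.  E.g. 30 uL protiated protein + 120 uL
    deuterated buffer gives ~0.80; diluting 20 uL of that with 40 uL of
    protiated quench gives ~0.27.
    """
    if not stages:
        raise ValueError("empty stage list")
    vol, frac = 0.0, 0.0
    for v, f in stages:
        if v <= 0 or not 0 <= f <= 1:
            raise ValueError("volumes must be positive and fractions in [0, 1]")
        frac = (frac * vol + f * v) / (vol + v)
        vol += v
    return frac


def max_exchangeable(sequence: str) -> int:
    """Theoretical maximum exchangeable backbone amides of a peptide.

    Convention: N - 1 - (prolines at positions 2..N); the N-terminal amide
    of each peptic peptide back-exchanges too fast to be observed, and Pro
    has no amide hydrogen.
    """
    seq = sequence.upper()
    unknown = set(seq) - _AA
    if unknown:
        raise ValueError(f"unknown residue codes {sorted(unknown)}")
    if len(seq) <= 1:
        return 0
    return len(seq) - 1 - seq[1:].count("P")


def fractional_uptake(uptake: float, max_d: int, d_fraction: float) -> float:
    """Relative fractional uptake in %: 100 * uptake / (max_d * d_fraction)."""
    if max_d < 1:
        raise ValueError("max_d must be at least 1")
    if not 0 < d_fraction <= 1:
        raise ValueError("d_fraction must lie in (0, 1]")
    return 100.0 * uptake / (max_d * d_fraction)


def _rfu_frame(ds: HDXDataset) -> pd.DataFrame:
    df = ds.data.copy()
    pept = ds.peptide_table()
    max_d = pept.sequence.map(max_exchangeable)
    if (max_d < 1).any():
        raise ValueError("peptide with no exchangeable amides")
    df["max_d"] = df.peptide.map(max_d)
    df["rfu"] = 100.0 * df.uptake / (df.max_d * ds.d_fraction)
    return df


def delta_uptake(
    dataset: HDXDataset, state_a: str, state_b: str
) -> pd.DataFrame:
    """Replicate-mean fractional uptake differences (state_b - state_a).

    Returns one row per peptide with per-time deltas (%), their time average
    ``avg_delta`` (the quantity painted onto the structure), and the deltas
    in Da.  Peptides present in only one state are excluded with a warning.
    """
    df = _rfu_frame(dataset)
    present = df.groupby("peptide").state.agg(lambda s: set(s))
    keep = present[present.apply(lambda s: {state_a, state_b} <= s)].index
    dropped = sorted(set(present.index) - set(keep))
    if dropped:
        import warnings

        warnings.warn(f"peptides present in one state only, excluded: {dropped}")
    df = df[df.peptide.isin(keep)]
    mean = (
        df.groupby(["peptide", "state", "time"])[["rfu", "uptake"]]
        .mean()
        .unstack("state")
    )
    delta_rfu = mean[("rfu", state_b)] - mean[("rfu", state_a)]
    delta_da = mean[("uptake", state_b)] - mean[("uptake", state_a)]
    out = delta_rfu.unstack("time")
    out.columns = [f"delta_rfu_{t:g}s" for t in out.columns]
    out["avg_delta"] = delta_rfu.groupby("peptide").mean()
    da = delta_da.unstack("time")
    da.columns = [f"delta_da_{t:g}s" for t in da.columns]
    out = out.join(da)
    pept = dataset.peptide_table()
    return pept.join(out, how="inner").reset_index()


@dataclasses.dataclass
class UptakeStats:
    """Per-peptide differential statistics with FDR-controlled calls."""

    table: pd.DataFrame  # peptide, start, end, sequence, avg_delta,
    #                      p_magnitude, p_kinetics, q_magnitude, q_kinetics,
    #                      significant
    fdr: float
    state_a: str
    state_b: str

    def summary(self) -> str:
        t = self.table
        n_sig = int(t.significant.sum())
        lines = [
            f"Differential HDX ({self.state_b} - {self.state_a}), "
            f"BH FDR {self.fdr:.0%}",
            f"peptides: {len(t)}   significant: {n_sig}",
        ]
        cols = ["peptide", "start", "end", "avg_delta", "p_magnitude",
                "p_kinetics", "significant"]
        lines.append(t[cols].to_string(index=False, float_format="%.3g"))
        return "\n".join(lines)


def _wald_tests(y, state, t_codes, n_times):
    """Magnitude and kinetics Wald p-values for one peptide.

    Magnitude: t-test of the state coefficient in the additive OLS model
    uptake ~ state + time(categorical).  Kinetics: F-test of the full
    state x time interaction block.  Returns (p_magnitude, p_kinetics);
    NaN on zero residual variance.
    """
    n = len(y)
    time_dummies = np.zeros((n, n_times - 1))
    for j in range(1, n_times):
        time_dummies[:, j - 1] = t_codes == j
    X_add = np.column_stack([np.ones(n), state, time_dummies])
    inter = state[:, None] * time_dummies
    X_full = np.column_stack([X_add, inter])

    fit_add = sm.OLS(y, X_add).fit()
    fit_full = sm.OLS(y, X_full).fit()
    tiny = 1e-10 * max(float(y @ y), 1e-300)  # exact-tie degenerate case
    if fit_add.df_resid <= 0 or fit_add.ssr <= tiny:
        return np.nan, np.nan
    p_mag = float(fit_add.pvalues[1])
    if fit_full.df_resid <= 0 or fit_full.ssr <= tiny:
        p_kin = np.nan
    else:
        _, p_kin, _ = fit_full.compare_f_test(fit_add)
        p_kin = float(p_kin)
    return p_mag, p_kin


def wald_fdr(
    dataset: HDXDataset,
    state_a: str | None = None,
    state_b: str | None = None,
    fdr: float = 0.05,
) -> UptakeStats:
    """Per-peptide Wald magnitude/kinetics tests with BH-FDR control.

    Fits, per peptide, a fixed-effects linear model of replicate uptake on
    state and categorical labelling time; the state main effect tests a
    shift in exchange magnitude and the interaction block a change in
    exchange kinetics.  Benjamini-Hochberg is applied across peptides
    separately for each test family; a peptide is significant when either
    test passes.
    """
    if state_a is None or state_b is None:
        st = dataset.states
        if len(st) != 2:
            raise ValueError("specify state_a/state_b for >2 states")
        state_a, state_b = st
    df = dataset.data[dataset.data.state.isin([state_a, state_b])]
    counts = df.groupby(["peptide", "state", "time"]).size()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per state x time block")
    times = np.sort(df.time.unique())
    t_index = {t: i for i, t in enumerate(times)}

    rows = []
    for pid, grp in df.groupby("peptide"):
        y = grp.uptake.to_numpy(float)
        state = (grp.state == state_b).to_numpy(float)
        t_codes = grp.time.map(t_index).to_numpy()
        p_mag, p_kin = _wald_tests(y, state, t_codes, len(times))
        rows.append((pid, p_mag, p_kin))
    res = pd.DataFrame(rows, columns=["peptide", "p_magnitude", "p_kinetics"])

    significant = np.zeros(len(res), dtype=bool)
    for col, qcol in (("p_magnitude", "q_magnitude"), ("p_kinetics", "q_kinetics")):
        ok = res[col].notna().to_numpy()
        res[qcol] = np.nan
        if ok.any():
            rej, q, *_ = multipletests(res.loc[ok, col], alpha=fdr, method="fdr_bh")
            res.loc[ok, qcol] = q
            significant[ok] |= rej
    res["significant"] = significant

    deltas = delta_uptake(dataset, state_a, state_b)[
        ["peptide", "start", "end", "sequence", "avg_delta"]
    ]
    table = deltas.merge(res, on="peptide")
    return UptakeStats(table=table, fdr=fdr, state_a=state_a, state_b=state_b)


def paint_values_per_residue(
    stats_table: pd.DataFrame, value_col: str = "avg_delta", n_residues: int | None = None
) -> pd.DataFrame:
    """Assign each residue the value of its shortest covering peptide.

    Returns a (residue, value) frame suitable for painting onto a structure;
    residues with no covering peptide are omitted.
    """
    t = stats_table.assign(length=stats_table.end - stats_table.start + 1)
    n_res = n_residues or int(t.end.max())
    values = {}
    for res in range(1, n_res + 1):
        cover = t[(t.start <= res) & (t.end >= res)]
        if len(cover):
            values[res] = float(cover.sort_values("length").iloc[0][value_col])
    return pd.DataFrame({"residue": list(values), "value": list(values.values())})
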