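"""Readers and writers for the external formats the pipeline touches.

Scattering curves are plain 3-column text (q, I, sigma) as deposited by
SEC-SAXS beamlines; tables (chemical shifts, relaxation decays, deuterium
uptake, ITC injections) are delimited text with a header row validated
against a :class:`TableSpec`.  Readers reject violated invariants instead of
silently repairing them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("camdyn")

__all__ = [
    "ScatteringCurve",
    "TableSpec",
    "SHIFT_TABLE",
    "DECAY_TABLE",
    "UPTAKE_TABLE",
    "ITC_TABLE",
    "read_saxs_dat",
    "read_table",
    "write_report",
    "read_report",
]


@dataclasses.dataclass
class ScatteringCurve:
    """One-dimensional scattering profile I(q) with 1-SD uncertainties.

    q is the momentum transfer 4*pi*sin(theta)/lambda in inverse Angstrom;
    I may be on absolute (cm^-1) or arbitrary scale, sigma shares I's units.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma.shape):
            raise ValueError("q, I, sigma must have equal length")
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("curve must be a non-empty 1-D profile")
        if np.any(self.q < 0):
            raise ValueError("q must be non-negative")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        finite = np.isfinite(self.I)
        if np.any(self.sigma[finite] <= 0):
            raise ValueError("sigma must be positive wherever I is finite")

    def __len__(self) -> int:
        return self.q.size

    def truncate(self, q_min: float = 0.0, q_max: float = np.inf) -> "ScatteringCurve":
        m = (self.q >= q_min) & (self.q <= q_max)
        return ScatteringCurve(self.q[m], self.I[m], self.sigma[m], dict(self.metadata))

    def interpolate_to(self, q: np.ndarray) -> "ScatteringCurve":
        """Linear interpolation of I and sigma onto a new grid inside the overlap."""
        q = np.asarray(q, float)
        if q.min() < self.q.min() - 1e-12 or q.max() > self.q.max() + 1e-12:
            raise ValueError("target grid extends beyond measured range")
        return ScatteringCurve(
            q,
            np.interp(q, self.q, self.I),
            np.interp(q, self.q, self.sigma),
            dict(self.metadata),
        )


def read_saxs_dat(
    path, *, fill_sigma: bool = False, q_unit: str = "A^-1"
) -> ScatteringCurve:
    """Read a 3-column (q, I, sigma) beamline ``.dat`` file.

    Header/comment lines (leading '#' or non-numeric text) are kept in
    ``metadata['header']``.  ``q_unit='nm^-1'`` converts to inverse Angstrom.
    With ``fill_sigma=True`` a missing third column is filled with 1.0.
    """
    path = Path(path)
    header: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            parts = s.replace(",", " ").split()
            try:
                vals = [float(x) for x in parts]
            except ValueError:
                header.append(s.lstrip("# "))
                continue
            if s.startswith("#"):
                header.append(s.lstrip("# "))
                continue
            rows.append(vals)
    if not rows:
        raise ValueError(f"no numeric data in {path}")
    ncol = min(len(r) for r in rows)
    if ncol < 2:
        raise ValueError(f"{path}: need at least q and I columns")
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    q, I = arr[:, 0], arr[:, 1]
    if ncol >= 3:
        sigma = arr[:, 2]
    elif fill_sigma:
        sigma = np.ones_like(I)
    else:
        raise ValueError(f"{path}: missing sigma column (pass fill_sigma=True to fill)")
    if q_unit == "nm^-1":
        q = q / 10.0
    elif q_unit != "A^-1":
        raise ValueError(f"unknown q unit {q_unit!r}")
    # drop rows where I or sigma are not usable (masked points in depositions)
    ok = np.isfinite(q) & np.isfinite(I) & np.isfinite(sigma) & (sigma > 0)
    meta = {"path": str(path), "header": header}
    return ScatteringCurve(q[ok], I[ok], sigma[ok], meta)


@dataclasses.dataclass(frozen=True)
class TableSpec:
    """Named-column contract for a delimited text table.

    ``columns`` maps mandatory column names to dtypes; ``unit_scale`` maps a
    column to a multiplicative factor applied on read (e.g. ms -> s);
    ``key`` names columns whose combinations must be unique.
    """

    name: str
    columns: Mapping[str, type]
    unit_scale: Mapping[str, float] = dataclasses.field(default_factory=dict)
    key: Sequence[str] = ()


SHIFT_TABLE = TableSpec(
    "shifts", {"residue": int, "dH": float, "dN": float}, key=("residue",)
)
DECAY_TABLE = TableSpec("decay", {"delay": float, "signal": float, "noise_sd": float})
UPTAKE_TABLE = TableSpec(
    "uptake",
    {
        "peptide": int,
        "start": int,
        "end": int,
        "sequence": str,
        "state": str,
        "time": float,
        "replicate": int,
        "uptake": float,
    },
    key=("peptide", "state", "time", "replicate"),
)
ITC_TABLE = TableSpec(
    "itc", {"injection": int, "volume": float, "heat": float}, key=("injection",)
)


def read_table(path, spec: TableSpec, unit_scale: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Read a comma- or tab-delimited table and validate it against *spec*."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = set(spec.columns) - set(df.columns)
    if missing:
        raise ValueError(f"{spec.name} table missing columns: {sorted(missing)}")
    for col, dtype in spec.columns.items():
        df[col] = df[col].astype(dtype)
    scales = dict(spec.unit_scale)
    scales.update(unit_scale or {})
    for col, factor in scales.items():
        df[col] = df[col] * factor
    if spec.key:
        dup = df.duplicated(subset=list(spec.key))
        if dup.any():
            raise ValueError(
                f"{spec.name} table has duplicate keys {list(spec.key)}: "
                f"rows {df.index[dup].tolist()[:5]}"
            )
    return df


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(result, path, table: pd.DataFrame | None = None) -> Path:
    """Serialize a result object as a JSON summary plus an optional CSV table.

    ``path`` is the JSON file; a table, if given, is written next to it with
    suffix ``.csv`` and is round-trippable by :func:`read_table` /
    ``pandas.read_csv``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = _to_jsonable(result)
    if not isinstance(payload, dict):
        payload = {"value": payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    if table is not None:
        table.to_csv(path.with_suffix(".csv"), index=False, float_format="%.6g")
    logger.info("wrote report %s", path)
    return path


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
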