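"""Tabular inputs and outputs: microdata, coverage, under-5 mortality, gradients.

Microdata are one row per child: wealth quintile (1 = poorest .. 5 =
wealthiest), one column per risk factor holding either the integer level
index or the level label, and an optional positive survey weight
(default 1).  Only complete cases for the active factor set are analysed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DiseaseSpec, Outcome, RiskFactorSpec

logger = logging.getLogger("quintrisk")

N_QUINTILES = 5
QUINTILES = tuple(range(1, N_QUINTILES + 1))

CARESEEK_KINDS = ("diarrhoea", "ari", "fever")


@dataclass
class ChildTable:
    """Child-level microdata with integer-coded factor levels.

    ``data`` holds columns ``quintile``, one integer column per factor in
    ``factor_names``, and ``weight``.  ``n_dropped`` counts rows removed by
    complete-case filtering at load time.
    """

    data: pd.DataFrame
    factor_names: tuple[str, ...]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.data)

    @property
    def weights(self) -> np.ndarray:
        return self.data["weight"].to_numpy(dtype=float)

    def total_weight(self) -> float:
        return float(self.data["weight"].sum())

    def quintile_weights(self) -> np.ndarray:
        """Weighted child count per quintile (length 5)."""
        sums = self.data.groupby("quintile")["weight"].sum()
        return np.array([float(sums.get(q, 0.0)) for q in QUINTILES])

    def restrict(self, factor_names: Sequence[str]) -> "ChildTable":
        """Complete-case subtable for the given factors (idempotent)."""
        missing = [f for f in factor_names if f not in self.data.columns]
        if missing:
            raise ValueError(f"microdata lacks factor columns: {missing}")
        mask = self.data[list(factor_names)].notna().all(axis=1)
        dropped = int((~mask).sum())
        if dropped:
            logger.info("complete-case filter: dropped %d rows", dropped)
        out = self.data.loc[mask].copy()
        for f in factor_names:
            out[f] = out[f].astype(int)
        if out.empty:
            raise ValueError("no complete-case rows remain for factors " f"{list(factor_names)}")
        return ChildTable(out, tuple(factor_names), n_dropped=self.n_dropped + dropped)


def _decode_levels(col: pd.Series, factor: RiskFactorSpec, path: str | Path) -> pd.Series:
    """Map a raw factor column (labels or indices) to integer level indices."""
    label_map = {lab: i for i, lab in enumerate(factor.levels)}
    out = pd.Series(np.nan, index=col.index, dtype=float)
    for idx, val in col.items():
        if pd.isna(val):
            continue
        if isinstance(val, str) and not val.strip().lstrip("-").isdigit():
            if val not in label_map:
                raise ValueError(
                    f"{path}: row {idx}, column {factor.name!r}: unknown level label {val!r}"
                )
            out.loc[idx] = label_map[val]
        else:
            lev = int(val)
            if not (0 <= lev < factor.n_levels):
                raise ValueError(
                    f"{path}: row {idx}, column {factor.name!r}: level index {lev} out of "
                    f"range 0..{factor.n_levels - 1}"
                )
            out.loc[idx] = lev
    return out


def load_microdata(
    path: str | Path,
    spec: DiseaseSpec,
    outcome: Outcome | None = None,
) -> ChildTable:
    """Read a microdata CSV and keep complete cases for the spec's factors.

    With ``outcome`` set, completeness is required only for that outcome's
    factor set; otherwise for the union of case and death factors.
    """
    df = pd.read_csv(path)
    if "quintile" not in df.columns:
        raise ValueError(f"{path}: missing required column 'quintile'")
    q = pd.to_numeric(df["quintile"], errors="raise")
    bad = ~q.isin(QUINTILES)
    if bad.any():
        raise ValueError(
            f"{path}: quintile out of range (row {int(np.flatnonzero(bad)[0])}); "
            "expected integers 1..5"
        )
    if outcome is None:
        names = spec.all_factor_names
        factors = {f.name: f for fs in (spec.case_factors, spec.death_factors) for f in fs}
    else:
        factors = {f.name: f for f in spec.factors_for(outcome)}
        names = list(factors)
    out = pd.DataFrame({"quintile": q.astype(int)})
    for name in names:
        if name not in df.columns:
            raise ValueError(f"{path}: missing factor column {name!r}")
        out[name] = _decode_levels(df[name], factors[name], path)
    if "weight" in df.columns:
        w = pd.to_numeric(df["weight"], errors="raise")
        if (w <= 0).any():
            raise ValueError(f"{path}: survey weights must be positive")
        out["weight"] = w.astype(float)
    else:
        out["weight"] = 1.0
    table = ChildTable(out, tuple(names))
    return table.restrict(names)


@dataclass
class CoverageTable:
    """Per-quintile immunization coverage and care-seeking proportions.

    ``vaccine_coverage`` maps vaccine name to a length-5 array (quintiles
    I..V); a vaccine absent from a country's programme is represented by
    zero coverage.  ``careseek`` maps 'diarrhoea' / 'ari' / 'fever' to a
    length-5 array, or omits kinds the survey did not report.
    """

    vaccine_coverage: dict[str, np.ndarray] = field(default_factory=dict)
    careseek: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in list(self.vaccine_coverage.items()) + list(self.careseek.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (N_QUINTILES,):
                raise ValueError(f"coverage column {name!r}: need 5 quintile values")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"coverage column {name!r}: values must be in [0,1]")

    def coverage_for(self, vaccine: str) -> np.ndarray:
        """Coverage for a vaccine; absent vaccines count as zero coverage."""
        if vaccine in self.vaccine_coverage:
            return np.asarray(self.vaccine_coverage[vaccine], dtype=float)
        return np.zeros(N_QUINTILES)


def load_coverage(path: str | Path) -> CoverageTable:
    """Read a coverage CSV: columns ``quintile``, ``<vaccine>_coverage``,
    ``careseek_diarrhoea``, ``careseek_ari``, ``careseek_fever`` (care-seeking
    columns optional)."""
    df = pd.read_csv(path)
    if "quintile" not in df.columns:
        raise ValueError(f"{path}: missing required column 'quintile'")
    df = df.sort_values("quintile")
    if list(df["quintile"]) != list(QUINTILES):
        raise ValueError(f"{path}: need exactly one row per quintile 1..5")
    vaccine_coverage, careseek = {}, {}
    for col in df.columns:
        if col == "quintile":
            continue
        vals = df[col].to_numpy(dtype=float)
        if col.endswith("_coverage"):
            vaccine_coverage[col[: -len("_coverage")]] = vals
        elif col.startswith("careseek_"):
            kind = col[len("careseek_"):]
            if kind not in CARESEEK_KINDS:
                raise ValueError(f"{path}: unknown care-seeking column {col!r}")
            if not np.all(np.isnan(vals)):
                careseek[kind] = vals
        else:
            logger.warning("%s: ignoring unrecognized column %r", path, col)
    return CoverageTable(vaccine_coverage, careseek)


def resolve_treatment_coverage(coverage: CoverageTable, disease: str) -> np.ndarray:
    """Per-quintile treatment coverage proxied by care-seeking.

    Diarrhoea uses diarrhoea care-seeking.  Pneumonia uses care-seeking for
    acute respiratory infections, falling back to fever when ARI is not
    reported.  Measles uses the quintile-wise average of the diarrhoea and
    ARI percentages.
    """
    cs = coverage.careseek
    if disease == "diarrhoea":
        if "diarrhoea" in cs:
            return np.asarray(cs["diarrhoea"], dtype=float)
        raise ValueError("treatment coverage for diarrhoea: careseek_diarrhoea missing")
    if disease == "pneumonia":
        for kind in ("ari", "fever"):
            if kind in cs:
                return np.asarray(cs[kind], dtype=float)
        raise ValueError(
            "treatment coverage for pneumonia: neither careseek_ari nor careseek_fever present"
        )
    if disease == "measles":
        if "diarrhoea" in cs and "ari" in cs:
            return (np.asarray(cs["diarrhoea"], float) + np.asarray(cs["ari"], float)) / 2.0
        raise ValueError(
            "treatment coverage for measles: needs both careseek_diarrhoea and careseek_ari"
        )
    raise ValueError(f"unknown disease {disease!r}")


@dataclass
class U5MRTable:
    """Under-5 mortality per quintile, deaths per 1000 live births."""

    u5mr: np.ndarray

    def __post_init__(self) -> None:
        self.u5mr = np.asarray(self.u5mr, dtype=float)
        if self.u5mr.shape != (N_QUINTILES,):
            raise ValueError("u5mr: need 5 quintile values")
        if np.any(self.u5mr <= 0):
            raise ValueError("u5mr: values must be positive")


def load_u5mr(path: str | Path) -> U5MRTable:
    df = pd.read_csv(path)
    for col in ("quintile", "u5mr_per_1000"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.sort_values("quintile")
    if list(df["quintile"]) != list(QUINTILES):
        raise ValueError(f"{path}: need exactly one row per quintile 1..5")
    return U5MRTable(df["u5mr_per_1000"].to_numpy(dtype=float))


def write_gradients(gradient, path: str | Path) -> None:
    """Write a quintile gradient as CSV, lossless at 6 decimals."""
    arrays = np.stack([gradient.mean, gradient.median, gradient.ui_low, gradient.ui_high])
    if not np.all(np.isfinite(arrays)):
        raise ValueError("gradient contains non-finite values; refusing to write")
    df = pd.DataFrame(
        {
            "quintile": list(QUINTILES),
            "mean": gradient.mean,
            "median": gradient.median,
            "ui_low": gradient.ui_low,
            "ui_high": gradient.ui_high,
            "reference": gradient.reference,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_gradients(path: str | Path):
    """Read a gradient CSV written by :func:`write_gradients`."""
    from .report import QuintileGradient

    df = pd.read_csv(path).sort_values("quintile")
    return QuintileGradient(
        mean=df["mean"].to_numpy(dtype=float),
        median=df["median"].to_numpy(dtype=float),
        ui_low=df["ui_low"].to_numpy(dtype=float),
        ui_high=df["ui_high"].to_numpy(dtype=float),
        reference=int(df["reference"].iloc[0]),
    )
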