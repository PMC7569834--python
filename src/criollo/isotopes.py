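"""Seed-isotope traits: %Ndfa by 15N natural abundance, and Delta13C.

The natural-abundance method estimates the percentage of plant nitrogen
derived from atmospheric fixation as

    %Ndfa = 100 * (d15N_ref - d15N_fix) / (d15N_ref - B)

where d15N_ref is the delta-15N of a non-fixing reference line grown in the
same environment, d15N_fix is the delta-15N of the fixing genotype, and B
is the delta-15N of plants whose entire N comes from fixation (a growth-
room calibration constant supplied by the user; it is not hard-coded).

Water-use efficiency is indexed by carbon isotope discrimination

    Delta13C = (d13C_air - d13C_plant) / (1 + d13C_plant)

evaluated in fractional units (per-mil / 1000) and reported back in
per-mil; lower Delta13C means higher water-use efficiency.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("criollo")

ISOTOPE_COLUMNS = [
    "genotype", "environment", "plot", "delta15N", "delta13C", "is_reference",
]


@dataclass(frozen=True)
class IsotopeConfig:
    """Calibration constants for the isotope trait calculations.

    B: per-mil delta-15N of fully fixation-fed plants (growth-room mean).
    delta13c_air: per-mil delta-13C of free air, approximately -8.
    center_per_environment: optionally center delta-15N within each
    environment before the %Ndfa calculation (off by default; raw values
    are used unless a normalization is explicitly requested).
    """

    B: float
    delta13c_air: float = -8.0
    center_per_environment: bool = False


def estimate_b_value(reference_free_n_records: Sequence[float]) -> float:
    """Mean delta-15N of plants grown on N-free media (the B-value)."""
    vals = np.asarray(list(reference_free_n_records), dtype=np.float64)
    if vals.size == 0:
        raise ValueError("cannot estimate B from zero records")
    return float(vals.mean())


def percent_ndfa(delta15n_ref: float, delta15n_fix: float, b: float) -> float:
    """%N derived from the atmosphere; unclamped (may fall outside [0,100])."""
    denom = delta15n_ref - b
    if denom == 0:
        raise ValueError("delta15N_ref equals B: %Ndfa denominator is zero")
    return 100.0 * (delta15n_ref - delta15n_fix) / denom


def carbon_discrimination(
    delta13c_plant: float, delta13c_air: float = -8.0
) -> float:
    """Delta13C (per-mil) from plant and air delta-13C (per-mil)."""
    if delta13c_plant <= -1000.0:
        raise ValueError("delta13C below the physical -1000 per-mil bound")
    p = delta13c_plant / 1000.0
    a = delta13c_air / 1000.0
    return 1000.0 * (a - p) / (1.0 + p)


def delta13c_from_discrimination(
    delta_cap: float, delta13c_air: float = -8.0
) -> float:
    """Inverse of :func:`carbon_discrimination` (both in per-mil)."""
    d = delta_cap / 1000.0
    a = delta13c_air / 1000.0
    return 1000.0 * (a - d) / (1.0 + d)


def read_isotope_table(path: str | Path) -> pd.DataFrame:
    """Read a per-plot isotope TSV (genotype, environment, plot, delta15N,
    delta13C, is_reference)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ISOTOPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"isotope table missing columns: {sorted(missing)}")
    truthy = {"true", "1", "yes", "t"}
    df["is_reference"] = [
        str(v).strip().lower() in truthy for v in df["is_reference"]
    ]
    return df


def ndfa_table(records: pd.DataFrame, cfg: IsotopeConfig) -> pd.DataFrame:
    """Fill ndfa_percent and delta_cap_13C for every non-reference plot.

    The reference delta-15N is the mean over reference-line plots within
    the same environment. %Ndfa is not clamped; values outside [0, 100]
    are flagged in ``ndfa_out_of_range``.
    """
    df = records.copy()
    if (df["delta13C"] >= 0).any():
        logger.warning("ndfa_table: non-negative delta13C values present; "
                       "plant tissue is expected to be depleted (< 0 per-mil)")
    if cfg.center_per_environment:
        df["delta15N"] = df["delta15N"] - df.groupby("environment")[
            "delta15N"
        ].transform("mean")
    ndfa = np.full(len(df), np.nan)
    for env, sub in df.groupby("environment"):
        ref = sub.loc[sub["is_reference"], "delta15N"]
        if ref.empty:
            raise ValueError(f"no reference-line records in environment {env!r}")
        ref_mean = float(ref.mean())
        if ref_mean - cfg.B <= 0:
            raise ValueError(
                f"environment {env!r}: reference delta15N ({ref_mean:.3g}) "
                f"does not exceed B ({cfg.B:.3g})"
            )
        fix = ~sub["is_reference"]
        ndfa[sub.index[fix]] = [
            percent_ndfa(ref_mean, v, cfg.B)
            for v in sub.loc[fix, "delta15N"]
        ]
    df["ndfa_percent"] = ndfa
    df["ndfa_out_of_range"] = (ndfa < 0) | (ndfa > 100)
    df["delta_cap_13C"] = [
        carbon_discrimination(v, cfg.delta13c_air) for v in df["delta13C"]
    ]
    return df


def pearson_matrix(traits: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between trait columns.

    Cells backed by fewer than ``min_pairs`` complete observation pairs are
    left undefined (NaN). The diagonal is exactly 1 for any trait with at
    least one observation.
    """
    numeric = traits.select_dtypes(include=[np.number])
    corr = numeric.corr(method="pearson", min_periods=min_pairs)
    for t in corr.columns:
        if numeric[t].notna().any():
            corr.loc[t, t] = 1.0
    return corr


@dataclass
class BiplotResult:
    """Genotype scores and trait loadings of a genotype x trait biplot."""

    scores: pd.DataFrame  # genotypes x components
    loadings: pd.DataFrame  # traits x components
    variance_explained: np.ndarray


def gt_biplot(traits: pd.DataFrame) -> BiplotResult:
    """Principal-component decomposition of a standardized trait table.

    Traits are centered and scaled to unit variance; genotypes with any
    missing cell are dropped (logged). Scores are the left singular vectors
    scaled by the singular values; loadings are the right singular vectors
    scaled by singular values / sqrt(n - 1), so loading inner products
    approximate trait correlations and acute/obtuse loading angles track
    positive/negative correlation.
    """
    numeric = traits.select_dtypes(include=[np.number])
    complete = numeric.dropna(axis=0)
    n_dropped = len(numeric) - len(complete)
    if n_dropped:
        logger.info("gt_biplot: dropped %d genotypes with missing cells",
                    n_dropped)
    if complete.shape[0] < 3 or complete.shape[1] < 2:
        raise ValueError("biplot needs >= 3 complete genotypes and >= 2 traits")
    x = complete.to_numpy(dtype=np.float64)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    comps = [f"PC{i + 1}" for i in range(len(s))]
    var = s**2
    loadings = vt.T * s / np.sqrt(len(complete) - 1)
    return BiplotResult(
        scores=pd.DataFrame(u * s, index=complete.index, columns=comps),
        loadings=pd.DataFrame(loadings, index=complete.columns, columns=comps),
        variance_explained=var / var.sum(),
    )
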