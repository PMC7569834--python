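"""Selection-signal screens contrasting two breeding-history groups.

Two callers: a diversity-ratio region caller (windows where one group's pi
exceeds the other's by more than a threshold factor, merged and length-
filtered) and a weighted-F_ST outlier caller with fixed-width candidate
flanks around each significant marker. Group-level comparisons use the
Welch two-sample t-test, treating windows as independent observations (the
spatial autocorrelation between neighbouring windows is documented, not
corrected).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io import GenomicInterval
from .popgen import FstRecord, WindowStat


@dataclass
class DivergentRegion:
    """A merged run of windows where group A's diversity dominates B's."""

    interval: GenomicInterval
    pi_a: float
    pi_b: float
    ratio: float  # inf when pi_b == 0
    n_windows: int


@dataclass
class OutlierSite:
    """A marker whose weighted F_ST exceeds the significance threshold."""

    chrom: str
    pos: int  # 1-based bp
    fst: float
    flank: GenomicInterval | None = None
    overlapping_genes: list[str] = field(default_factory=list)


@dataclass
class GroupComparison:
    statistic: str
    mean_a: float
    mean_b: float
    welch_t: float
    df: float
    p_two_sided: float


def _window_grid_key(w: WindowStat) -> tuple[str, int, int]:
    return (w.interval.chrom, w.interval.start, w.interval.end)


def call_high_diversity_regions(
    wins_a: Sequence[WindowStat],
    wins_b: Sequence[WindowStat],
    ratio_threshold: float = 3.0,
    min_length: int = 25_000,
) -> list[DivergentRegion]:
    """Call regions where pi_A exceeds ratio_threshold x pi_B.

    A window qualifies iff it is defined (holds >= 1 SNP) in both groups
    and pi_a > ratio_threshold * pi_b; pi_b = 0 qualifies whenever
    pi_a > 0 (ratio recorded as inf). Adjacent qualifying windows on a
    chromosome (sharing a boundary) are merged, and merged spans shorter
    than ``min_length`` bp are dropped.
    """
    b_by_key = {}
    b_end_by_start: dict[tuple[str, int], int] = {}
    for w in wins_b:
        key = _window_grid_key(w)
        if key in b_by_key:
            raise ValueError(f"duplicate window {key} in group B")
        b_by_key[key] = w
        b_end_by_start[(w.interval.chrom, w.interval.start)] = w.interval.end
    for w in wins_a:
        start_key = (w.interval.chrom, w.interval.start)
        if start_key in b_end_by_start and b_end_by_start[start_key] != w.interval.end:
            raise ValueError(f"mismatched window grids at {start_key}")

    qualifying: list[tuple[GenomicInterval, float, float]] = []
    for w in sorted(wins_a, key=_window_grid_key):
        other = b_by_key.get(_window_grid_key(w))
        if other is None:
            continue
        if w.pi > ratio_threshold * other.pi and w.pi > 0:
            qualifying.append((w.interval, w.pi, other.pi))

    merged: list[DivergentRegion] = []
    for iv, pa, pb in qualifying:
        if (
            merged
            and merged[-1].interval.chrom == iv.chrom
            and merged[-1].interval.end == iv.start
        ):
            prev = merged[-1]
            tot = prev.interval.length + iv.length
            pi_a = (prev.pi_a * prev.interval.length + pa * iv.length) / tot
            pi_b = (prev.pi_b * prev.interval.length + pb * iv.length) / tot
            merged[-1] = DivergentRegion(
                interval=GenomicInterval(iv.chrom, prev.interval.start, iv.end),
                pi_a=pi_a,
                pi_b=pi_b,
                ratio=pi_a / pi_b if pi_b > 0 else math.inf,
                n_windows=prev.n_windows + 1,
            )
        else:
            merged.append(
                DivergentRegion(
                    interval=iv,
                    pi_a=pa,
                    pi_b=pb,
                    ratio=pa / pb if pb > 0 else math.inf,
                    n_windows=1,
                )
            )
    return [r for r in merged if r.interval.length >= min_length]


def call_fst_outliers(
    records: Sequence[FstRecord], fst_threshold: float = 0.5
) -> list[OutlierSite]:
    """Markers whose weighted F_ST strictly exceeds the threshold, sorted."""
    out = [
        OutlierSite(chrom=r.interval.chrom, pos=r.pos, fst=r.fst_weighted)
        for r in records
        if r.fst_weighted > fst_threshold
    ]
    out.sort(key=lambda s: (s.chrom, s.pos))
    return out


def extract_candidate_windows(
    sites: Sequence[OutlierSite],
    flank: int = 50_000,
    genes: Sequence[tuple[GenomicInterval, str]] | None = None,
) -> list[OutlierSite]:
    """Attach a centered candidate flank (default 100 kb) to each outlier.

    The flank is [pos - flank, pos + flank) clipped at the chromosome
    start; when gene intervals are supplied, genes intersecting the flank
    are listed on the site.
    """
    out: list[OutlierSite] = []
    for s in sites:
        start = max(0, s.pos - flank)
        end = s.pos + flank
        iv = GenomicInterval(s.chrom, start, end)
        overlaps = (
            [gid for g_iv, gid in genes if g_iv.overlaps(iv)] if genes else []
        )
        out.append(
            OutlierSite(
                chrom=s.chrom,
                pos=s.pos,
                fst=s.fst,
                flank=iv,
                overlapping_genes=overlaps,
            )
        )
    return out


def welch_t_test(
    xs: Sequence[float], ys: Sequence[float], statistic: str = ""
) -> GroupComparison:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("each sample needs >= 2 observations")
    vx, vy = xs.var(ddof=1), ys.var(ddof=1)
    if vx == 0 and vy == 0:
        if xs.mean() == ys.mean():
            # degenerate case: no variance, no difference
            return GroupComparison(
                statistic, float(xs.mean()), float(ys.mean()),
                0.0, float(len(xs) + len(ys) - 2), 1.0,
            )
        return GroupComparison(
            statistic, float(xs.mean()), float(ys.mean()),
            math.inf if xs.mean() > ys.mean() else -math.inf,
            float(len(xs) + len(ys) - 2), float(np.finfo(float).tiny),
        )
    res = stats.ttest_ind(xs, ys, equal_var=False)
    return GroupComparison(
        statistic=statistic,
        mean_a=float(xs.mean()),
        mean_b=float(ys.mean()),
        welch_t=float(res.statistic),
        df=float(res.df),
        p_two_sided=float(res.pvalue),
    )


def genome_wide_summary(wins: Sequence[WindowStat]) -> tuple[float, float]:
    """(mean pi, mean Tajima's D) over all windows; undefined D excluded.

    Windows without SNPs never reach this function (they are omitted by the
    windowed scans), so the averages run over defined windows only.
    """
    if not wins:
        raise ValueError("no windows to summarize")
    mean_pi = float(np.mean([w.pi for w in wins]))
    ds = np.asarray([w.tajima_d for w in wins], dtype=np.float64)
    defined = ds[~np.isnan(ds)]
    mean_d = float(defined.mean()) if defined.size else math.nan
    return mean_pi, mean_d


def regions_frame(regions: Sequence[DivergentRegion]):
    """Region table mirroring the high-diversity layout (coords in Mbp)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "Chr": [r.interval.chrom for r in regions],
            "Start_Mbp": [r.interval.start / 1e6 for r in regions],
            "End_Mbp": [r.interval.end / 1e6 for r in regions],
            "pi_landrace": [r.pi_a for r in regions],
            "pi_ppb": [r.pi_b for r in regions],
            "ratio": ["Inf" if math.isinf(r.ratio) else r.ratio for r in regions],
        }
    )


def outliers_frame(sites: Sequence[OutlierSite]):
    """Outlier table mirroring the significant-marker layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "Chr": [s.chrom for s in sites],
            "SNP_Position_Mbp": [s.pos / 1e6 for s in sites],
            "FST": [s.fst for s in sites],
            "n_candidate_genes": [len(s.overlapping_genes) for s in sites],
        }
    )
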