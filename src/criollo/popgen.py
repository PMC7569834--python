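"""Per-site and windowed population-genetic statistics.

Implements frequency-based estimators for an inbred diploid SNP panel:
per-site nucleotide diversity, windowed pi (per-bp, monomorphic positions
implicitly zero), Tajima's D from the standard 1989 constants, and the
Weir & Cockerham (1984) two-population variance components with the
window-weighted ratio sum(a) / sum(a+b+c).

"Sliding windows" default to non-overlapping tiles (step = size), the
behaviour of the standard windowed-scan tools; an explicit step is exposed
for overlapping scans.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .io import MISSING, GenomicInterval, GenotypeMatrix, PopulationMap

logger = logging.getLogger("criollo")


@dataclass(frozen=True)
class WindowSpec:
    """Window size/step in bp. step=None means non-overlapping tiles."""

    size: int = 1_000_000
    step: int | None = None

    def __post_init__(self) -> None:
        step = self.size if self.step is None else self.step
        if self.size <= 0:
            raise ValueError("window size must be positive")
        if not (0 < step <= self.size):
            raise ValueError("need 0 < step <= size")
        object.__setattr__(self, "step", step)


@dataclass
class WindowStat:
    """Windowed diversity summary for one group of samples."""

    interval: GenomicInterval
    n_snps: int
    pi: float  # per-bp diversity (sum of site pi / window size)
    S: int  # segregating sites within the group
    k_hat: float  # mean pairwise differences, in sites (not per-bp)
    tajima_d: float = math.nan  # NaN = undefined (S == 0) or not computed
    group: str | None = None


@dataclass(frozen=True)
class TajimaConstants:
    """The standard constants derived from chromosome sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@dataclass
class FstRecord:
    """Weir-Cockerham components summed over the sites of one window."""

    interval: GenomicInterval
    pos: int  # 1-based site position (single-SNP window) or midpoint
    a: float
    b: float
    c: float
    fst_weighted: float  # sum(a) / sum(a+b+c)
    fst_mean: float  # mean of per-site ratios
    n_snps: int


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------

def site_pi(alt_count: int, n_chrom: int) -> float:
    """Per-site nucleotide diversity from an alternate-allele count.

    Equals the fraction of chromosome pairs that differ:
    2*alt*(n-alt) / (n*(n-1)).
    """
    if n_chrom < 2:
        raise ValueError("need at least 2 chromosomes")
    if not (0 <= alt_count <= n_chrom):
        raise ValueError("alt_count outside [0, n_chrom]")
    return 2.0 * alt_count * (n_chrom - alt_count) / (n_chrom * (n_chrom - 1))


def _site_pi_vec(alt: np.ndarray, nch: np.ndarray) -> np.ndarray:
    alt = alt.astype(np.float64)
    nch = nch.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * alt * (nch - alt) / (nch * (nch - 1.0))
    return np.where(nch >= 2, pi, np.nan)


def tajima_constants(n_chrom: int) -> TajimaConstants:
    """Constants of the standardized D statistic for sample size n."""
    if n_chrom < 2:
        raise ValueError("Tajima constants need n >= 2")
    n = n_chrom
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajima_d_from_summary(k_hat: float, S: int, n_chrom: int) -> float:
    """D = (k_hat - S/a1) / sqrt(e1*S + e2*S*(S-1)); NaN when S == 0."""
    if S == 0:
        return math.nan
    c = tajima_constants(n_chrom)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (k_hat - S / c.a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# window machinery
# ---------------------------------------------------------------------------

def _iter_windows(
    g: GenotypeMatrix, spec: WindowSpec
) -> Iterator[tuple[GenomicInterval, np.ndarray]]:
    """Yield (interval, site-index array) for every window holding >= 1 SNP.

    Chromosome length is the max observed position rounded up to a whole
    window, so no assembly file is needed.
    """
    step: int = spec.step  # type: ignore[assignment]
    for chrom in g.chromosomes():
        on = np.flatnonzero(g.chrom == chrom)
        pos = g.pos[on]
        if step == spec.size:
            # non-overlapping tiles: visit only occupied bins
            bins = (pos - 1) // spec.size
            boundaries = np.flatnonzero(np.diff(bins)) + 1
            for chunk in np.split(np.arange(pos.size), boundaries):
                start = int(bins[chunk[0]]) * spec.size
                yield GenomicInterval(chrom, start, start + spec.size), on[chunk]
            continue
        chrom_len = int(math.ceil(pos.max() / spec.size) * spec.size)
        start = 0
        while start < chrom_len:
            end = start + spec.size
            lo = np.searchsorted(pos, start + 1, side="left")
            hi = np.searchsorted(pos, end, side="right")
            if hi > lo:
                yield GenomicInterval(chrom, start, end), on[lo:hi]
            start += step


def _group_site_summaries(
    g: GenotypeMatrix, samples: Sequence[str] | None
) -> tuple[np.ndarray, np.ndarray]:
    """(alt counts, non-missing chromosome counts) for a sample subset."""
    sub = g if samples is None else g.subset_samples(samples)
    if sub.n_samples == 0:
        raise ValueError("empty sample subset")
    return sub.alt_counts(), sub.n_chrom()


def windowed_pi(
    g: GenotypeMatrix,
    samples: Sequence[str] | None = None,
    spec: WindowSpec = WindowSpec(),
    group: str | None = None,
) -> list[WindowStat]:
    """Per-bp nucleotide diversity in windows, for a sample subset.

    pi = (sum of per-site pi over the window's SNPs) / window size; sites
    where fewer than two chromosomes are typed are skipped (logged).
    Windows without SNPs are omitted.
    """
    alt, nch = _group_site_summaries(g, samples)
    pi_site = _site_pi_vec(alt, nch)
    n_skipped = int(np.isnan(pi_site).sum())
    if n_skipped:
        logger.info("windowed_pi: skipped %d sites with <2 typed chromosomes",
                    n_skipped)
    out: list[WindowStat] = []
    for iv, idx in _iter_windows(g, spec):
        p = pi_site[idx]
        ok = ~np.isnan(p)
        seg = (alt[idx] > 0) & (alt[idx] < nch[idx]) & ok
        k_hat = float(np.nansum(p))
        out.append(
            WindowStat(
                interval=iv,
                n_snps=int(ok.sum()),
                pi=k_hat / spec.size,
                S=int(seg.sum()),
                k_hat=k_hat,
                group=group,
            )
        )
    return out


def windowed_tajima_d(
    g: GenotypeMatrix,
    samples: Sequence[str] | None = None,
    spec: WindowSpec = WindowSpec(),
    group: str | None = None,
) -> list[WindowStat]:
    """Tajima's D per window; NaN where the window has no segregating site.

    The chromosome sample size per window is the modal non-missing
    chromosome count over the window's sites (after imputation this is
    simply twice the number of samples).
    """
    alt, nch = _group_site_summaries(g, samples)
    pi_site = _site_pi_vec(alt, nch)
    out: list[WindowStat] = []
    for iv, idx in _iter_windows(g, spec):
        ok = nch[idx] >= 2
        idx = idx[ok]
        if idx.size == 0:
            continue
        seg = (alt[idx] > 0) & (alt[idx] < nch[idx])
        S = int(seg.sum())
        k_hat = float(np.nansum(pi_site[idx]))
        counts = np.bincount(nch[idx])
        n_modal = int(np.argmax(counts))  # argmax breaks ties toward lower n
        d = tajima_d_from_summary(k_hat, S, n_modal) if n_modal >= 2 else math.nan
        out.append(
            WindowStat(
                interval=iv,
                n_snps=int(idx.size),
                pi=k_hat / spec.size,
                S=S,
                k_hat=k_hat,
                tajima_d=d,
                group=group,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST (two populations, diploid)
# ---------------------------------------------------------------------------

def _wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized 1984 variance components for r = 2 populations.

    n: typed diploid counts, p: alt-allele frequencies, h: observed
    heterozygote frequencies. Returns (a, b, c): among-population,
    among-individual-within-population, within-individual.
    """
    n1 = n1.astype(np.float64)
    n2 = n2.astype(np.float64)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - 1.0 / (nbar - 1.0)
        * (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar)
        - (r - 1.0) / r * s2
        - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def fst_site_components(
    counts_pop1: tuple[int, float, float],
    counts_pop2: tuple[int, float, float],
) -> tuple[float, float, float]:
    """Weir-Cockerham (a, b, c) at one site for two populations.

    Each argument is (typed diploid count, alt-allele frequency, observed
    heterozygote frequency).
    """
    n1, p1, h1 = counts_pop1
    n2, p2, h2 = counts_pop2
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 typed diploids per population")
    a, b, c = _wc_components(
        np.asarray([n1]), np.asarray([p1]), np.asarray([h1]),
        np.asarray([n2]), np.asarray([p2]), np.asarray([h2]),
    )
    return float(a[0]), float(b[0]), float(c[0])


def _group_freqs(g: GenotypeMatrix, samples: Sequence[str]):
    sub = g.subset_samples(samples)
    d = sub.dosage
    typed = d != MISSING
    n = typed.sum(axis=0).astype(np.float64)
    alt = np.where(typed, d, 0).sum(axis=0).astype(np.float64)
    het = (d == 1).sum(axis=0).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, h


def windowed_fst(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    group_a: str,
    group_b: str,
    spec: WindowSpec = WindowSpec(size=100),
) -> list[FstRecord]:
    """Weighted Weir-Cockerham F_ST per window between two groups.

    Per window, fst_weighted = sum(a) / sum(a+b+c) over the contained
    sites; with the default 100 bp windows on array data most windows hold
    a single SNP, so windowed and per-site values coincide. Sites where a
    population is entirely missing (or has a single typed diploid) are
    skipped with a log message. Negative estimates are reported, not
    clamped.
    """
    ids = set(g.sample_ids)
    samples_a = [s for s in popmap.samples_in(group_a) if s in ids]
    samples_b = [s for s in popmap.samples_in(group_b) if s in ids]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"groups {group_a!r}/{group_b!r} need >= 2 genotyped samples each"
        )
    n1, p1, h1 = _group_freqs(g, samples_a)
    n2, p2, h2 = _group_freqs(g, samples_b)
    usable = (n1 >= 2) & (n2 >= 2)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("windowed_fst: skipped %d sites with <2 typed diploids "
                    "in a population", n_skipped)
    a = np.full(g.n_sites, np.nan)
    b = np.full(g.n_sites, np.nan)
    c = np.full(g.n_sites, np.nan)
    a[usable], b[usable], c[usable] = _wc_components(
        n1[usable], p1[usable], h1[usable],
        n2[usable], p2[usable], h2[usable],
    )
    denom_site = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_site = np.where(denom_site > 0, a / denom_site, np.nan)

    out: list[FstRecord] = []
    for iv, idx in _iter_windows(g, spec):
        idx = idx[usable[idx]]
        if idx.size == 0:
            continue
        sa, sden = float(np.sum(a[idx])), float(np.sum(denom_site[idx]))
        if sden <= 0:
            continue
        ratios = ratio_site[idx]
        pos = int(g.pos[idx[0]]) if idx.size == 1 else int(
            (iv.start + iv.end) // 2
        )
        out.append(
            FstRecord(
                interval=iv,
                pos=pos,
                a=sa,
                b=float(np.sum(b[idx])),
                c=float(np.sum(c[idx])),
                fst_weighted=sa / sden,
                fst_mean=float(np.nanmean(ratios)) if np.isfinite(ratios).any()
                else math.nan,
                n_snps=int(idx.size),
            )
        )
    return out


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage with the site's modal non-missing dosage.

    Deterministic: ties pick the lower dosage. Sites where every call is
    missing are dropped (logged).
    """
    d = g.dosage.copy()
    typed = d != MISSING
    keep = typed.any(axis=0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("impute_missing: dropped %d all-missing sites", n_dropped)
    counts = np.stack([(d == k).sum(axis=0) for k in (0, 1, 2)])
    mode = np.argmax(counts, axis=0).astype(np.int8)  # first max -> lower dosage
    n_missing = int((~typed[:, keep]).sum())
    total = typed[:, keep].size
    if n_missing:
        logger.info("impute_missing: imputed %.3f%% of calls",
                    100.0 * n_missing / total)
    filled = np.where(typed, d, mode[np.newaxis, :])
    return GenotypeMatrix(
        sample_ids=list(g.sample_ids),
        chrom=g.chrom[keep],
        pos=g.pos[keep],
        ref=g.ref[keep],
        alt=g.alt[keep],
        dosage=filled[:, keep],
    )


# ---------------------------------------------------------------------------
# tabular export, mirroring the classic windowed-scan column layouts
# ---------------------------------------------------------------------------

def window_stats_frame(wins: Sequence[WindowStat]):
    """DataFrame with CHROM, BIN_START (1-based), BIN_END, N_VARIANTS, PI,
    TajimaD columns."""
    import pandas as pd

    return pd.DataFrame(
        {
            "CHROM": [w.interval.chrom for w in wins],
            "BIN_START": [w.interval.start + 1 for w in wins],
            "BIN_END": [w.interval.end for w in wins],
            "N_VARIANTS": [w.n_snps for w in wins],
            "PI": [w.pi for w in wins],
            "TajimaD": [w.tajima_d for w in wins],
            "GROUP": [w.group for w in wins],
        }
    )


def fst_records_frame(records: Sequence[FstRecord]):
    """DataFrame with CHROM, BIN_START, BIN_END, N_VARIANTS, WEIGHTED_FST,
    MEAN_FST columns."""
    import pandas as pd

    return pd.DataFrame(
        {
            "CHROM": [r.interval.chrom for r in records],
            "BIN_START": [r.interval.start + 1 for r in records],
            "BIN_END": [r.interval.end for r in records],
            "POS": [r.pos for r in records],
            "N_VARIANTS": [r.n_snps for r in records],
            "WEIGHTED_FST": [r.fst_weighted for r in records],
            "MEAN_FST": [r.fst_mean for r in records],
        }
    )
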