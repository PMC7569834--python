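"""Synthetic SNP panels and isotope phenotypes with known ground truth.

The genotype generator is frequency-based (Balding-Nichols-style): each
site gets an ancestral allele frequency from a symmetric Beta law rescaled
to the common-variant range typical of genotyping arrays, the two
subpopulation frequencies are perturbed around it, and diploid genotypes
are drawn with a high inbreeding coefficient (beans are predominantly
self-pollinating). Regions of elevated diversity in one group and fixed
(or nearly fixed) frequency differences are planted explicitly, so every
downstream scan can be scored against truth. A fixed fraction of sites is
simulated below the MAF 0.01 floor so the default panel filters from 5398
to exactly 4314 sites.

The isotope generator runs the natural-abundance model forward: given a
true %Ndfa, delta-15N of a fixing plot is
ref - (ndfa/100) * (ref - B) + noise, and delta-13C is the exact inverse
of the discrimination formula at the drawn true Delta13C, so zero-noise
data invert exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    GenomicInterval,
    GenotypeMatrix,
    PopulationMap,
    write_population_map,
    write_vcf,
)
from .isotopes import delta13c_from_discrimination

LANDRACE = "LANDRACE"
PPB = "PPB"
ADMIXED = "ADMIXED"


@dataclass(frozen=True)
class PlantedRegion:
    """A genomic span where group A's heterozygosity is multiplied."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    multiplier: float
    n_snps: int = 30

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class PlantedOutlier:
    """A site with a planted between-group allele-frequency gap."""

    chrom: str
    pos: int  # 1-based
    freq_gap: float


def _default_regions() -> list[PlantedRegion]:
    spans = [("Pv01", 10), ("Pv03", 20), ("Pv05", 28), ("Pv08", 5), ("Pv11", 38)]
    return [
        PlantedRegion(c, mb * 1_000_000, (mb + 3) * 1_000_000, multiplier=4.0)
        for c, mb in spans
    ]


def _default_outliers() -> list[PlantedOutlier]:
    # echo the chromosomes where the F_ST screen is expected to fire
    sites = [
        ("Pv02", 48_900_000, 1.0),
        ("Pv02", 49_200_000, 0.9),
        ("Pv07", 600_000, 1.0),
        ("Pv07", 4_200_000, 0.9),
        ("Pv07", 38_900_000, 1.0),
        ("Pv09", 5_500_000, 0.9),
        ("Pv09", 7_800_000, 1.0),
        ("Pv09", 13_500_000, 0.9),
        ("Pv11", 30_000_000, 1.0),
        ("Pv11", 30_500_000, 0.9),
    ]
    return [PlantedOutlier(c, p, g) for c, p, g in sites]


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults emulate the array-genotyped panel the pipeline targets: two
    subpopulations of 29 inbred lines plus 14 admixed individuals (72
    total), 11 chromosomes of 50 Mbp, 5398 biallelic sites of which a
    planted fraction sits below the MAF 0.01 floor (leaving 4314 after
    filtering), inbreeding F = 0.98, 2% missing calls.
    """

    n_group_a: int = 29
    n_group_b: int = 29
    n_admixed: int = 14
    admixture: float = 0.5
    n_chromosomes: int = 11
    chrom_length: int = 50_000_000
    n_snps: int = 5398
    beta_shape: float = 2.0
    freq_low: float = 0.10  # array-ascertainment range of the baseline law
    freq_high: float = 0.90
    background_fst: float = 0.01
    inbreeding: float = 0.98
    missing_rate: float = 0.02
    maf_floor_fraction: float = 1084 / 5398
    planted_regions: list[PlantedRegion] = field(default_factory=_default_regions)
    planted_outliers: list[PlantedOutlier] = field(default_factory=_default_outliers)
    seed: int = 0

    def chrom_names(self) -> list[str]:
        return [f"Pv{k + 1:02d}" for k in range(self.n_chromosomes)]

    def validate(self) -> None:
        for r in self.planted_regions:
            if r.multiplier <= 1.0:
                raise ValueError(
                    f"region {r.chrom}:{r.start}-{r.end}: multiplier must be > 1"
                )
        for o in self.planted_outliers:
            if not (0.0 <= o.freq_gap <= 1.0):
                raise ValueError(f"outlier {o.chrom}:{o.pos}: |pA-pB| must be <= 1")
        if not (0.0 <= self.inbreeding <= 1.0):
            raise ValueError("inbreeding F must be in [0, 1]")
        if not (0.0 <= self.admixture <= 1.0):
            raise ValueError("admixture proportion must be in [0, 1]")


@dataclass
class SimTruth:
    """Everything needed to score the downstream recovery tests."""

    regions: list[PlantedRegion]
    outliers: list[PlantedOutlier]
    freq_a: np.ndarray  # generating alt-allele frequency per site, group A
    freq_b: np.ndarray
    site_class: np.ndarray  # 0 background, 1 region, 2 outlier, 3 sub-MAF-floor
    seed: int


# site-class codes
_BG, _REGION, _OUTLIER, _LOWMAF = 0, 1, 2, 3


def _balding_nichols(rng, p: np.ndarray, theta: float) -> np.ndarray:
    if theta <= 0:
        return p.copy()
    shape1 = p * (1.0 - theta) / theta
    shape2 = (1.0 - p) * (1.0 - theta) / theta
    return rng.beta(shape1, shape2)


def _draw_group(rng, n: int, p: np.ndarray, f: float) -> np.ndarray:
    """Diploid dosages for n individuals at frequencies p with inbreeding f."""
    s = p.size
    ibd = rng.random((n, s)) < f
    g1 = (rng.random((n, s)) < p[None, :]).astype(np.int8)
    g2 = (rng.random((n, s)) < p[None, :]).astype(np.int8)
    return np.where(ibd, 2 * g1, g1 + g2).astype(np.int8)


def simulate_genotypes(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Draw a genotype panel with planted truth; deterministic under seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms = cfg.chrom_names()
    region_by_chrom: dict[str, list[PlantedRegion]] = {}
    for r in cfg.planted_regions:
        if r.chrom not in chroms:
            raise ValueError(f"region on unknown chromosome {r.chrom}")
        if r.end > cfg.chrom_length:
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} exceeds "
                             f"chromosome length {cfg.chrom_length}")
        region_by_chrom.setdefault(r.chrom, []).append(r)

    # --- site positions ------------------------------------------------
    n_reserved = sum(r.n_snps for r in cfg.planted_regions) + len(
        cfg.planted_outliers
    )
    n_background = cfg.n_snps - n_reserved
    if n_background < 0:
        raise ValueError("n_snps too small for the planted sites")
    per_chrom = np.full(cfg.n_chromosomes, n_background // cfg.n_chromosomes)
    per_chrom[: n_background % cfg.n_chromosomes] += 1

    pos_by_chrom: dict[str, set[int]] = {c: set() for c in chroms}
    for o in cfg.planted_outliers:
        pos_by_chrom[o.chrom].add(o.pos)
    for r in cfg.planted_regions:
        have = {p for p in pos_by_chrom[r.chrom] if r.start < p <= r.end}
        while len(have) < r.n_snps:
            cand = rng.integers(r.start + 1, r.end + 1, r.n_snps - len(have))
            have.update(int(v) for v in cand)
        pos_by_chrom[r.chrom].update(have)
    for k, c in enumerate(chroms):
        need = int(per_chrom[k])
        while need > 0:
            cand = rng.integers(1, cfg.chrom_length + 1, need)
            before = len(pos_by_chrom[c])
            pos_by_chrom[c].update(int(v) for v in cand)
            need -= len(pos_by_chrom[c]) - before

    chrom_arr: list[str] = []
    pos_list: list[int] = []
    for c in chroms:
        for p in sorted(pos_by_chrom[c]):
            chrom_arr.append(c)
            pos_list.append(p)
    chrom_a = np.asarray(chrom_arr, dtype=object)
    pos_a = np.asarray(pos_list, dtype=np.int64)
    n_sites = pos_a.size

    # --- site classes ---------------------------------------------------
    site_class = np.zeros(n_sites, dtype=np.int8)
    region_mult = np.ones(n_sites)
    for r in cfg.planted_regions:
        inside = (chrom_a == r.chrom) & (pos_a > r.start) & (pos_a <= r.end)
        site_class[inside] = _REGION
        region_mult[inside] = r.multiplier
    outlier_gap = np.zeros(n_sites)
    for o in cfg.planted_outliers:
        hit = (chrom_a == o.chrom) & (pos_a == o.pos)
        site_class[hit] = _OUTLIER
        outlier_gap[hit] = o.freq_gap
    n_low = int(round(cfg.maf_floor_fraction * cfg.n_snps))
    bg_idx = np.flatnonzero(site_class == _BG)
    if n_low > bg_idx.size:
        raise ValueError("maf_floor_fraction leaves too few background sites")
    low_idx = rng.choice(bg_idx, size=n_low, replace=False)
    site_class[low_idx] = _LOWMAF

    # --- generating frequencies -----------------------------------------
    span = cfg.freq_high - cfg.freq_low
    p_anc = cfg.freq_low + span * rng.beta(cfg.beta_shape, cfg.beta_shape, n_sites)
    freq_a = _balding_nichols(rng, p_anc, cfg.background_fst)
    freq_b = _balding_nichols(rng, p_anc, cfg.background_fst)

    # Region sites sit at modest absolute diversity (the windowed tables of
    # such scans show per-window pi below the genome-wide mean): this keeps
    # the A/B heterozygosity ratio at the configured multiplier without
    # forcing a between-group frequency gap large enough to masquerade as an
    # F_ST outlier.
    is_region = site_class == _REGION
    pa_region = rng.uniform(0.15, 0.25, int(is_region.sum()))
    h_a = 2.0 * pa_region * (1.0 - pa_region)
    h_b = h_a / region_mult[is_region]
    disc = 1.0 - 2.0 * h_b
    if (disc < 0).any():
        raise ValueError("infeasible diversity multiplier in a planted region")
    freq_a[is_region] = pa_region
    freq_b[is_region] = (1.0 - np.sqrt(disc)) / 2.0  # branch nearest p_A

    is_out = site_class == _OUTLIER
    freq_a[is_out] = 0.5 + outlier_gap[is_out] / 2.0
    freq_b[is_out] = 0.5 - outlier_gap[is_out] / 2.0

    freq_adm = cfg.admixture * freq_a + (1.0 - cfg.admixture) * freq_b

    # --- genotypes -------------------------------------------------------
    blocks = [
        (cfg.n_group_a, freq_a),
        (cfg.n_group_b, freq_b),
        (cfg.n_admixed, freq_adm),
    ]
    dosage = np.vstack(
        [_draw_group(rng, n, p, cfg.inbreeding) for n, p in blocks if n > 0]
    )
    n_total = dosage.shape[0]

    # sub-floor sites: alternate monomorphic / singleton heterozygote, the
    # singleton only when one allele copy stays under MAF 0.01 with slack
    # for per-site missingness
    singleton_ok = 2 * n_total >= 110
    for k, s in enumerate(sorted(int(v) for v in low_idx)):
        dosage[:, s] = 0
        if singleton_ok and k % 2 == 1:
            dosage[int(rng.integers(0, n_total)), s] = 1

    missing_mask = rng.random(dosage.shape) < cfg.missing_rate
    dosage[missing_mask] = MISSING

    # keep every non-floor site above the MAF threshold after missingness
    group_slices = []
    off = 0
    for n, p in blocks:
        if n > 0:
            group_slices.append((slice(off, off + n), p))
            off += n
    normal = site_class != _LOWMAF

    def _violations() -> np.ndarray:
        typed = dosage != MISSING
        alt = np.where(typed, dosage, 0).sum(axis=0)
        nch = 2 * typed.sum(axis=0)
        return normal & (np.minimum(alt, nch - alt) < 2)

    for _ in range(6):
        viol = _violations()
        if not viol.any():
            break
        vidx = np.flatnonzero(viol)
        for sl, p in group_slices:
            redraw = _draw_group(rng, sl.stop - sl.start, p[vidx], cfg.inbreeding)
            redraw[missing_mask[sl, :][:, vidx]] = MISSING
            dosage[np.ix_(range(sl.start, sl.stop), vidx)] = redraw
    for s in np.flatnonzero(_violations()):
        rows = np.flatnonzero(dosage[:, s] != MISSING)[:2]
        dosage[rows, s] = 1

    # --- assemble ---------------------------------------------------------
    sample_ids = (
        [f"LND{i + 1:03d}" for i in range(cfg.n_group_a)]
        + [f"PPB{i + 1:03d}" for i in range(cfg.n_group_b)]
        + [f"ADM{i + 1:03d}" for i in range(cfg.n_admixed)]
    )
    bases = np.asarray(["A", "C", "G", "T"], dtype=object)
    ref = bases[rng.integers(0, 4, n_sites)]
    shift = rng.integers(1, 4, n_sites)
    alt_alleles = bases[
        (np.searchsorted(bases.astype(str), ref.astype(str)) + shift) % 4
    ]
    g = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=chrom_a,
        pos=pos_a,
        ref=ref,
        alt=alt_alleles,
        dosage=dosage,
    )
    groups = (
        {f"LND{i + 1:03d}": LANDRACE for i in range(cfg.n_group_a)}
        | {f"PPB{i + 1:03d}": PPB for i in range(cfg.n_group_b)}
        | {f"ADM{i + 1:03d}": ADMIXED for i in range(cfg.n_admixed)}
    )
    pm = PopulationMap(group=groups, is_reference={s: False for s in sample_ids})
    truth = SimTruth(
        regions=list(cfg.planted_regions),
        outliers=list(cfg.planted_outliers),
        freq_a=freq_a,
        freq_b=freq_b,
        site_class=site_class,
        seed=cfg.seed,
    )
    return g, pm, truth


# ---------------------------------------------------------------------------
# scoring helpers for the recovery tests
# ---------------------------------------------------------------------------

def score_region_calls(called, truth: SimTruth) -> tuple[float, int]:
    """(sensitivity, false-region count) of a region-scan result."""
    planted = [r.interval for r in truth.regions]
    hit = sum(
        1 for p in planted if any(c.interval.overlaps(p) for c in called)
    )
    false = sum(
        1 for c in called if not any(c.interval.overlaps(p) for p in planted)
    )
    sens = hit / len(planted) if planted else math.nan
    return sens, false


def score_outlier_calls(called, truth: SimTruth) -> tuple[float, int]:
    """(sensitivity, false-outlier count) of an F_ST outlier result."""
    planted = {(o.chrom, o.pos) for o in truth.outliers}
    called_keys = {(c.chrom, c.pos) for c in called}
    hit = len(planted & called_keys)
    sens = hit / len(planted) if planted else math.nan
    return sens, len(called_keys - planted)


# ---------------------------------------------------------------------------
# isotope phenotypes
# ---------------------------------------------------------------------------

@dataclass
class IsotopeTruth:
    b_true: float
    delta15n_ref_true: float
    ndfa_true: dict[str, float]
    delta_cap_true: dict[str, float]
    noise_sd: float
    delta13c_noise_sd: float
    seed: int


DEFAULT_NDFA_MEANS = {LANDRACE: 46.4, PPB: 40.1}
DEFAULT_DELTA_CAP_MEANS = {LANDRACE: 18.2, PPB: 17.7}


def simulate_isotopes(
    genotype_ids: list[str],
    groups: dict[str, str],
    seed: int = 0,
    b_true: float = -2.0,
    delta15n_ref_true: float = 3.0,
    ndfa_group_means: dict[str, float] | None = None,
    ndfa_sd: float = 6.0,
    noise_sd: float = 0.2,
    delta_cap_group_means: dict[str, float] | None = None,
    delta_cap_sd: float = 0.8,
    delta13c_noise_sd: float = 0.0,
    n_plots: int = 3,
    n_ref_plots: int = 4,
    environment: str = "SYN1",
    reference_id: str = "R99",
    delta13c_air: float = -8.0,
) -> tuple[pd.DataFrame, IsotopeTruth]:
    """Forward-simulate per-plot seed-isotope measurements.

    Fixing plots get delta15N = ref - (ndfa/100)*(ref - B) + N(0, noise_sd);
    reference plots get ref + noise. delta13C is the exact inverse of the
    discrimination formula at each genotype's true Delta13C (plus optional
    noise), so zero-noise data invert exactly.
    """
    rng = np.random.default_rng(seed)
    ndfa_means = dict(DEFAULT_NDFA_MEANS, **(ndfa_group_means or {}))
    cap_means = dict(DEFAULT_DELTA_CAP_MEANS, **(delta_cap_group_means or {}))
    overall_ndfa = float(np.mean(list(ndfa_means.values())))
    overall_cap = float(np.mean(list(cap_means.values())))

    ndfa_true: dict[str, float] = {}
    cap_true: dict[str, float] = {}
    rows: list[dict] = []
    for gid in genotype_ids:
        grp = groups.get(gid, "")
        ndfa = float(
            np.clip(rng.normal(ndfa_means.get(grp, overall_ndfa), ndfa_sd), 5, 95)
        )
        cap = float(rng.normal(cap_means.get(grp, overall_cap), delta_cap_sd))
        ndfa_true[gid] = ndfa
        cap_true[gid] = cap
        d13c_clean = delta13c_from_discrimination(cap, delta13c_air)
        for plot in range(1, n_plots + 1):
            d15n = (
                delta15n_ref_true
                - ndfa / 100.0 * (delta15n_ref_true - b_true)
                + rng.normal(0.0, noise_sd)
            )
            rows.append(
                {
                    "genotype": gid,
                    "environment": environment,
                    "plot": plot,
                    "delta15N": d15n,
                    "delta13C": d13c_clean + rng.normal(0.0, delta13c_noise_sd)
                    if delta13c_noise_sd > 0 else d13c_clean,
                    "is_reference": False,
                }
            )
    ref_cap = overall_cap
    ref_d13c = delta13c_from_discrimination(ref_cap, delta13c_air)
    for plot in range(1, n_ref_plots + 1):
        rows.append(
            {
                "genotype": reference_id,
                "environment": environment,
                "plot": plot,
                "delta15N": delta15n_ref_true + rng.normal(0.0, noise_sd),
                "delta13C": ref_d13c,
                "is_reference": True,
            }
        )
    truth = IsotopeTruth(
        b_true=b_true,
        delta15n_ref_true=delta15n_ref_true,
        ndfa_true=ndfa_true,
        delta_cap_true=cap_true,
        noise_sd=noise_sd,
        delta13c_noise_sd=delta13c_noise_sd,
        seed=seed,
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# neutral coalescent panel (independent loci) for the Tajima's D null
# ---------------------------------------------------------------------------

def simulate_neutral_panel(
    n_samples: int = 50,
    n_loci: int = 100,
    theta: float = 8.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Neutral-equilibrium diploid panel of independent loci.

    Each locus is one coalescent replicate (standard constant-size model,
    infinite-sites binary mutations at population-scaled rate ``theta``),
    placed on its own chromosome so a windowed Tajima's D scan sees one
    window per locus. Genome-mean D is ~0 under this model.
    """
    import msprime

    ne = 10_000.0
    length = 1.0
    mu = theta / (4.0 * ne * length)
    reps = msprime.sim_ancestry(
        samples=n_samples,
        ploidy=2,
        population_size=ne,
        sequence_length=length,
        num_replicates=n_loci,
        random_seed=seed + 1,
    )
    rng = np.random.default_rng(seed)
    chroms: list[str] = []
    pos: list[int] = []
    cols: list[np.ndarray] = []
    for k, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts,
            rate=mu,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31)),
        )
        gm = mts.genotype_matrix()  # sites x haplotypes
        if gm.size == 0:
            continue
        dosage = gm[:, 0::2] + gm[:, 1::2]  # sites x diploids
        for s in range(dosage.shape[0]):
            chroms.append(f"L{k + 1:03d}")
            pos.append(s + 1)
            cols.append(dosage[s].astype(np.int8))
    n_sites = len(pos)
    return GenotypeMatrix(
        sample_ids=[f"S{i + 1:03d}" for i in range(n_samples)],
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(["A"] * n_sites, dtype=object),
        alt=np.asarray(["T"] * n_sites, dtype=object),
        dosage=np.stack(cols, axis=1),
    )


# ---------------------------------------------------------------------------
# deterministic unit-test fixtures
# ---------------------------------------------------------------------------

_TOY_VCF = """\
##fileformat=VCFv4.2
##source=criollo
##contig=<ID=Pv01,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
Pv01\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0
Pv01\t200\t.\tC\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t0/0\t0/0
Pv01\t300\t.\tG\tA,C\t.\tPASS\t.\tGT\t0/0\t0/1\t0/2\t0/0
Pv01\t400\t.\tT\tC\t.\tPASS\t.\tGT\t0/1\t0/0\t./.\t1/1
Pv01\t500\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t1/1\t0/1\t0/1
"""

_TOY_POPMAP = """\
sample_id\tgroup\tis_reference
S1\tLANDRACE\tfalse
S2\tLANDRACE\tfalse
S3\tPPB\tfalse
S4\tPPB\tfalse
R99\tCHECK\ttrue
"""


def make_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Write the small deterministic fixtures used by the unit tests.

    The toy VCF carries 4 valid biallelic SNP sites plus one triallelic
    record that readers must drop; the isotope table includes the
    delta13C = -28.2 per-mil worked-example row; the distance table is an
    additive 4-taxon matrix. Reruns overwrite byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["toy_vcf"] = out / "toy.vcf"
    paths["toy_vcf"].write_text(_TOY_VCF)
    paths["popmap"] = out / "popmap.tsv"
    paths["popmap"].write_text(_TOY_POPMAP)

    # exact forward model: ref=3.0, B=-2.0; %Ndfa 50 -> d15N = 0.5
    iso = pd.DataFrame(
        [
            {"genotype": "HON01", "environment": "E1", "plot": 1,
             "delta15N": 0.5, "delta13C": -28.2, "is_reference": False},
            {"genotype": "HON02", "environment": "E1", "plot": 1,
             "delta15N": 1.5, "delta13C": -18.0, "is_reference": False},
            {"genotype": "R99", "environment": "E1", "plot": 1,
             "delta15N": 2.5, "delta13C": -22.0, "is_reference": True},
            {"genotype": "R99", "environment": "E1", "plot": 2,
             "delta15N": 3.5, "delta13C": -22.0, "is_reference": True},
        ]
    )
    paths["isotopes"] = out / "isotopes.tsv"
    iso.to_csv(paths["isotopes"], sep="\t", index=False)

    # additive distances from the tree ((A:1,B:2):1,(C:3,D:4))
    dm = pd.DataFrame(
        [
            [0.0, 3.0, 5.0, 6.0],
            [3.0, 0.0, 6.0, 7.0],
            [5.0, 6.0, 0.0, 7.0],
            [6.0, 7.0, 7.0, 0.0],
        ],
        index=list("ABCD"),
        columns=list("ABCD"),
    )
    paths["distances"] = out / "additive_distances.tsv"
    dm.to_csv(paths["distances"], sep="\t")
    return paths


def write_panel(
    g: GenotypeMatrix, pm: PopulationMap, out_dir: str | Path
) -> dict[str, Path]:
    """Write a simulated panel as VCF + population-map TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": out / "panel.vcf", "popmap": out / "popmap.tsv"}
    write_vcf(g, paths["vcf"])
    write_population_map(pm, paths["popmap"])
    return paths
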