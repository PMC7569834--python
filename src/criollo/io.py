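"""Readers and writers for the formats the pipeline touches.

VCF and GFF3 positions are 1-based inclusive at the file boundary; every
internal interval is 0-based half-open so that window and flank arithmetic
is unambiguous.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("criollo")

#: sentinel for a missing diploid genotype call
MISSING: int = -1


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed."""


class EmptyPanelError(ValueError):
    """Raised when filtering leaves no usable site."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_position(self, pos_1based: int) -> bool:
        """Whether a 1-based bp position falls inside the interval."""
        return self.start <= pos_1based - 1 < self.end


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a panel of diploid samples.

    ``dosage[i, s]`` is the alternate-allele count {0, 1, 2} of sample ``i``
    at site ``s``, or :data:`MISSING`. Sites are sorted by (chrom, pos) and
    strictly increasing within a chromosome.
    """

    sample_ids: list[str]
    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int64, 1-based
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray  # (n_samples, n_sites) int8
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if self.dosage.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError("dosage shape does not match samples x sites")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,MISSING}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = -1
        for c, p in zip(self.chrom, self.pos):
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"chromosome {c} appears in two blocks")
                seen.add(c)
                prev_chrom, prev_pos = c, -1
            if p <= prev_pos:
                raise ValueError(
                    f"positions not strictly increasing on {c} at {p}"
                )
            prev_pos = p

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return GenotypeMatrix(
            sample_ids=list(ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            dosage=self.dosage[idx, :].copy(),
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            dosage=self.dosage[:, mask],
        )

    # -- per-site summaries (computed over non-missing calls) ----------
    def alt_counts(self) -> np.ndarray:
        d = self.dosage
        return np.where(d == MISSING, 0, d).sum(axis=0).astype(np.int64)

    def n_chrom(self) -> np.ndarray:
        """Non-missing chromosome count per site (2 x typed diploids)."""
        return self.ploidy * (self.dosage != MISSING).sum(axis=0).astype(np.int64)

    def missingness(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency on non-missing chromosomes only."""
        nch = self.n_chrom()
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(nch > 0, self.alt_counts() / np.maximum(nch, 1), 0.0)
        return np.minimum(p, 1.0 - p)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out


@dataclass
class PopulationMap:
    """sample_id -> breeding-history group, plus non-fixing reference flags."""

    group: dict[str, str]
    is_reference: dict[str, bool] = field(default_factory=dict)

    def samples_in(self, label: str) -> list[str]:
        return [s for s, g in self.group.items() if g == label]

    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.group.values():
            if g not in seen:
                seen.append(g)
        return seen

    def reference_samples(self) -> list[str]:
        return [s for s, flag in self.is_reference.items() if flag]


def _is_snp(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref != "." and alt != "."


def read_vcf(
    path: str | Path,
    min_maf: float = 0.01,
    max_missing: float = 0.2,
) -> GenotypeMatrix:
    """Read a diploid VCF into a filtered :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped (count logged). Sites with
    minor-allele frequency <= ``min_maf`` (computed on non-missing
    chromosomes) or missingness > ``max_missing`` are removed, mirroring the
    MAF > 0.01 array-QC rule.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad input
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    n_dropped = 0
    try:
        for v in vcf:
            if len(v.ALT) != 1 or not _is_snp(v.REF, v.ALT[0]):
                n_dropped += 1
                continue
            d = v.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            d[d == 3] = MISSING
            chroms.append(v.CHROM)
            positions.append(v.POS)
            refs.append(v.REF)
            alts.append(v.ALT[0])
            cols.append(d)
    except Exception as exc:
        raise VcfParseError(f"malformed VCF record in {path}: {exc}") from exc
    if n_dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)
    if not cols:
        raise EmptyPanelError(f"no biallelic SNP records in {path}")

    dosage = np.stack(cols, axis=1)  # samples x sites
    chrom_arr = np.asarray(chroms, dtype=object)
    pos_arr = np.asarray(positions, dtype=np.int64)
    order = np.lexsort((pos_arr, chrom_arr.astype(str)))
    g = GenotypeMatrix(
        sample_ids=samples,
        chrom=chrom_arr[order],
        pos=pos_arr[order],
        ref=np.asarray(refs, dtype=object)[order],
        alt=np.asarray(alts, dtype=object)[order],
        dosage=dosage[:, order],
    )
    keep = (g.maf() > min_maf) & (g.missingness() <= max_missing)
    n_filtered = int((~keep).sum())
    if n_filtered:
        logger.info(
            "read_vcf: removed %d sites (MAF <= %g or missingness > %g)",
            n_filtered, min_maf, max_missing,
        )
    if not keep.any():
        raise EmptyPanelError(f"no sites survive filtering in {path}")
    return g.subset_sites(keep)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as a minimal VCF 4.2 with GT fields."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = ["##fileformat=VCFv4.2", "##source=criollo"]
    for c in g.chromosomes():
        length = int(g.pos[g.chrom == c].max())
        lines.append(f"##contig=<ID={c},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(g.sample_ids)
    )
    for s in range(g.n_sites):
        gts = "\t".join(gt_map[int(d)] for d in g.dosage[:, s])
        lines.append(
            f"{g.chrom[s]}\t{g.pos[s]}\t.\t{g.ref[s]}\t{g.alt[s]}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a TSV with header sample_id, group, is_reference."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "is_reference"}
    if not required.issubset(df.columns):
        raise ValueError(f"population map needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in population map: {dups}")
    truthy = {"true", "1", "yes", "t"}
    group = dict(zip(df["sample_id"], df["group"]))
    is_ref = {
        s: str(v).strip().lower() in truthy
        for s, v in zip(df["sample_id"], df["is_reference"])
    }
    logger.info("population map: %d samples, groups %s",
                len(group), sorted(set(group.values())))
    return PopulationMap(group=group, is_reference=is_ref)


def write_population_map(pm: PopulationMap, path: str | Path) -> None:
    rows = [
        {"sample_id": s, "group": g,
         "is_reference": str(pm.is_reference.get(s, False)).lower()}
        for s, g in pm.group.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED (0-based half-open) with optional name/score."""
    if names is not None and len(names) != len(intervals):
        raise ValueError("names length mismatch")
    if scores is not None and len(scores) != len(intervals):
        raise ValueError("scores length mismatch")
    records = list(zip(intervals, names or [""] * len(intervals),
                       scores if scores is not None else [None] * len(intervals)))
    try:
        records.sort(key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    except TypeError as exc:
        raise ValueError(f"unsortable chromosome labels: {exc}") from exc
    lines = ["#chrom\tstart\tend\tname\tscore"]
    for iv, name, score in records:
        score_s = "." if score is None else repr(float(score))
        lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name or '.'}\t{score_s}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str, float | None]]:
    out: list[tuple[GenomicInterval, str, float | None]] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("track"):
            continue
        parts = line.split("\t")
        iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
        name = parts[3] if len(parts) > 3 and parts[3] != "." else ""
        score = (
            float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
        )
        out.append((iv, name, score))
    return out


def read_gff3_genes(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Extract gene features from a GFF3 file.

    GFF coordinates are 1-based inclusive; the returned intervals are
    0-based half-open, so a gene at 101..200 becomes [100, 200).
    """
    out: list[tuple[GenomicInterval, str]] = []
    n_anon = 0
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9 or parts[2] != "gene":
            continue
        start, end = int(parts[3]), int(parts[4])
        if end < start:
            raise ValueError(f"GFF3 feature with end < start: {line}")
        attrs = dict(
            kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
        )
        gene_id = attrs.get("ID") or attrs.get("Name")
        if gene_id is None:
            n_anon += 1
            gene_id = f"gene{n_anon}"
        out.append((GenomicInterval(parts[0], start - 1, end), gene_id))
    out.sort(key=lambda r: (r[0].chrom, r[0].start))
    return out
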