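"""Panel structure: p-distances, neighbor-joining with bootstrap, PCA.

Distances are allele-sharing p-distances on dosages (the proportion of
differing alleles over jointly typed sites) — a transparent analogue of a
substitution distance for biallelic array data. The tree is built by the
classic Saitou-Nei neighbor-joining agglomeration with deterministic
tie-breaking and clamp-and-transfer handling of negative branch lengths.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("criollo")


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")


@dataclass
class TreeNode:
    """Node of an unrooted tree (represented with a trifurcating root)."""

    name: str | None = None
    length: float = 0.0  # branch to parent
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves() if l.name)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.3g}"
        return f"({inner}){label}:{self.length:.10g}"

    def to_newick(self, with_support: bool = True) -> str:
        inner = ",".join(c._newick(with_support) for c in self.children)
        return f"({inner});"

    def to_biopython(self):
        """The tree as a Bio.Phylo object (for plotting or conversion)."""
        from Bio import Phylo

        return Phylo.read(StringIO(self.to_newick()), "newick")


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, canonicalized to the side that does
    not contain the alphabetically first leaf."""
    all_leaves = tree.leaf_names()
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def pairwise_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing p-distance: sum |dosage_i - dosage_j| / 2 over jointly
    typed sites, divided by the number of such sites."""
    if g.n_samples < 2:
        raise ValueError("need >= 2 samples")
    x = g.dosage.astype(np.float64)
    typed = g.dosage != MISSING
    n = g.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        joint = typed[i] & typed[i + 1:]
        n_joint = joint.sum(axis=1)
        if (n_joint == 0).any():
            j = int(i + 1 + np.flatnonzero(n_joint == 0)[0])
            raise ValueError(
                f"samples {g.sample_ids[i]!r} and {g.sample_ids[j]!r} share "
                "no jointly typed site"
            )
        diff = np.where(joint, np.abs(x[i] - x[i + 1:]), 0.0).sum(axis=1) / 2.0
        d[i, i + 1:] = d[i + 1:, i] = diff / n_joint
    return DistanceMatrix(sample_ids=list(g.sample_ids), matrix=d)


def _clamp_transfer(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch length to 0, moving the deficit to its
    sibling edge."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; deterministic lexicographic tie-break.

    Returns the unrooted tree as a trifurcating root. Negative branch
    lengths are clamped to zero with the deficit added to the sibling edge.
    """
    n = len(d.sample_ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 samples")
    if not np.allclose(d.matrix, d.matrix.T):
        raise ValueError("distance matrix is not symmetric")
    dm = d.matrix.astype(np.float64).copy()
    nodes: list[TreeNode] = [TreeNode(name=s) for s in d.sample_ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = dm.sum(axis=1)
        q = (m - 2) * dm - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin = lexicographically first minimal (i, j) pair
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * dm[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dm[i, j] - li
        li, lj = _clamp_transfer(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        dk = 0.5 * (dm[i, :] + dm[j, :] - dm[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        dm_new = np.zeros((m - 1, m - 1))
        dm_new[:-1, :-1] = dm[np.ix_(keep, keep)]
        dm_new[-1, :-1] = dm_new[:-1, -1] = dk[keep]
        dm = dm_new
        nodes = [nodes[k] for k in keep] + [new]

    a, b, c = nodes
    dab, dac, dbc = dm[0, 1], dm[0, 2], dm[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return TreeNode(children=[a, b, c])


def bootstrap_support(
    g: GenotypeMatrix, replicates: int = 1000, seed: int = 0
) -> TreeNode:
    """NJ tree with per-edge bootstrap support (site resampling).

    Columns are resampled with replacement; the support of each internal
    bipartition of the full-data tree is the fraction of replicate trees
    containing it. Seeded and reproducible.
    """
    if replicates < 1:
        raise ValueError("need >= 1 replicate")
    tree = neighbor_joining(pairwise_distance(g))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(tree)}
    for _ in range(replicates):
        idx = rng.integers(0, g.n_sites, g.n_sites)
        boot = GenotypeMatrix(
            sample_ids=list(g.sample_ids),
            chrom=np.asarray([f"bs{k}" for k in range(g.n_sites)], dtype=object),
            pos=np.ones(g.n_sites, dtype=np.int64),
            ref=g.ref[idx],
            alt=g.alt[idx],
            dosage=g.dosage[:, idx],
        )
        rep_bps = bipartitions(neighbor_joining(pairwise_distance(boot)))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_leaves = tree.leaf_names()
    anchor = min(all_leaves)
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            node.support = counts[side] / replicates
    return tree


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x requested components
    variance_explained: np.ndarray  # over all components (sums to 1)


def genotype_pca(
    g: GenotypeMatrix, n_components: int = 2, scale: bool = False
) -> PcaResult:
    """PCA of the dosage matrix (sites mean-centered; missing -> site mean).

    ``scale=True`` additionally divides each site by sqrt(p(1-p)) of its
    allele frequency (frequency scaling); the default is centering only.
    """
    if g.n_samples < 3:
        raise ValueError("PCA needs >= 3 samples")
    x = g.dosage.astype(np.float64)
    typed = g.dosage != MISSING
    with np.errstate(invalid="ignore"):
        mean = np.where(
            typed.any(axis=0),
            np.where(typed, x, 0.0).sum(axis=0) / np.maximum(typed.sum(axis=0), 1),
            0.0,
        )
    x = np.where(typed, x, mean[None, :]) - mean[None, :]
    if scale:
        p = mean / 2.0
        denom = np.sqrt(np.maximum(p * (1.0 - p), 1e-12))
        x = x / denom[None, :]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    rank = int((s > s.max() * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        logger.info("genotype_pca: truncating %d requested components to rank %d",
                    n_components, rank)
        n_components = rank
    comps = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (u * s)[:, :n_components], index=g.sample_ids, columns=comps
    )
    return PcaResult(scores=scores, variance_explained=var / total)
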