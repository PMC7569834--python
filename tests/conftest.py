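import numpy as np
import pytest

from criollo import GenotypeMatrix, SimConfig, impute_missing, simulate_genotypes
from criollo.simulate import make_fixture_suite


def random_panel(
    rng: np.random.Generator,
    n_samples: int = 8,
    n_sites: int = 40,
    missing_rate: float = 0.05,
    n_chrom: int = 2,
    max_pos: int = 3_000_000,
) -> GenotypeMatrix:
    """Small random panel for oracle comparisons."""
    per = n_sites // n_chrom
    chroms, pos = [], []
    for k in range(n_chrom):
        n_here = per if k < n_chrom - 1 else n_sites - per * (n_chrom - 1)
        p = np.sort(rng.choice(np.arange(1, max_pos), n_here, replace=False))
        chroms += [f"C{k + 1}"] * n_here
        pos += list(p)
    dosage = rng.integers(0, 3, (n_samples, n_sites)).astype(np.int8)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = -1
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n_samples)],
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(["A"] * n_sites, dtype=object),
        alt=np.asarray(["T"] * n_sites, dtype=object),
        dosage=dosage,
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_suite(out)


@pytest.fixture(scope="session")
def default_panel():
    """One default synthetic panel shared across tests (seed 1)."""
    g, pm, truth = simulate_genotypes(SimConfig(seed=1))
    return g, pm, truth


@pytest.fixture(scope="session")
def filtered_panel(default_panel):
    g, pm, truth = default_panel
    kept = g.subset_sites(g.maf() > 0.01)
    return impute_missing(kept), pm, truth
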