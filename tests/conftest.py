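import hypothesis
import numpy as np
import pytest

from admixtide.genotype_io import GenotypeDataset, IndRecord, SnpRecord

hypothesis.settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25
)
hypothesis.settings.load_profile("suite")


def make_dataset(
    n_snps: int,
    n_inds: int,
    seed: int = 0,
    chroms: tuple[str, ...] = ("1", "2"),
    chrom_length_M: float = 1.0,
    pseudo_haploid_frac: float = 0.0,
    missing_rate: float = 0.0,
    group: str = "Pop",
) -> GenotypeDataset:
    """Random valid dataset for I/O and oracle tests."""
    rng = np.random.default_rng(seed)
    per = max(n_snps // len(chroms), 1)
    snps = []
    for c in chroms:
        pos = np.sort(rng.uniform(0, chrom_length_M, per))
        snps.extend(
            SnpRecord(f"rs{c}_{j}", c, float(p), int(p * 1e8) + 1)
            for j, p in enumerate(pos)
        )
    n_snps = len(snps)
    ph = rng.random(n_inds) < pseudo_haploid_frac
    calls = rng.integers(0, 3, size=(n_snps, n_inds)).astype(np.int8)
    calls[:, ph] = 2 * rng.integers(0, 2, size=(n_snps, int(ph.sum()))).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = -1
    inds = [
        IndRecord(f"ind{i}", "F" if i % 2 == 0 else "M", group) for i in range(n_inds)
    ]
    return GenotypeDataset(snps, inds, calls, ph)


@pytest.fixture(scope="session")
def small_scenario():
    """A modest three-way admixed scenario shared across qpAdm-level tests."""
    from admixtide.simulate import build_scenario

    ds, truth, meta = build_scenario("mtwapa-like", seed=1, n_snps=20000, n_admixed=100)
    return ds, truth, meta


@pytest.fixture(scope="session")
def small_blocks(small_scenario):
    from admixtide.genotype_io import assign_blocks

    ds, _, _ = small_scenario
    return assign_blocks(ds, 5.0, "autosomes")
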