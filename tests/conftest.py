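import pytest

from telandscape.synthetic_data import CopySpec, SimConfig, plant_genome


def small_sim_config(seed: int, nesting_prob: float = 0.3) -> SimConfig:
    """A compact two-chromosome genome used by most integration tests."""
    return SimConfig(
        seed=seed,
        chrom_lengths={"chr1": 500_000, "chr2": 300_000},
        sex_chroms=(),
        macro_threshold=400_000,
        copy_spec=[
            CopySpec("ERVK1", 8, ("burst", 1.0), structure="ltr_full"),
            CopySpec("LTR2", 6, ("uniform", 4.0, 18.0), structure="ltr_solo"),
            CopySpec("CR1L1", 25, ("uniform", 5.0, 25.0), truncate_5p=True),
            CopySpec("SINE1", 15, ("uniform", 3.0, 20.0)),
            CopySpec("hAT1", 8, ("uniform", 5.0, 22.0)),
        ],
        nesting_prob=nesting_prob,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One planted small genome shared across tests (seed fixed)."""
    return plant_genome(small_sim_config(11))


@pytest.fixture(scope="session")
def default_dataset():
    """The default-scale simulated genome (a few Mb, seven chromosomes)."""
    return plant_genome(SimConfig(seed=5))
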