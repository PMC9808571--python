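import pytest

from pirnaflow.synthetic_data import SimConfig, generate_cohort


def small_config(**overrides) -> SimConfig:
    """A reduced cohort for fast structural tests."""
    base = dict(
        seed=11,
        n_pirna_genes=40,
        n_biogenesis_genes=8,
        n_other_genes=16,
        n_pirnas_per_gene=10,
        class_counts={
            "TCFL5_dependent": 12,
            "AMYB_dependent": 10,
            "AMYB_dependent_biogenesis_defect": 6,
            "unassigned": 12,
        },
        n_planted_edges=4,
        n_reverse_edges=2,
        n_decoy_9pairs=2,
        n_decoy_broken_seed=2,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def cohort_noise_free():
    """The full-size noise-free cohort used for end-to-end recovery checks."""
    return generate_cohort(SimConfig(seed=1, count_noise="none"))


@pytest.fixture(scope="session")
def cohort_small():
    return generate_cohort(small_config())
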