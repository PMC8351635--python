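import hypothesis
import pytest

from fesurvey.simulate import (
    CohortConfig,
    GroupProfile,
    default_families,
)

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


ALPHA_FAMILIES = ["SufB", "SufC", "SufS", "FeoA", "FeoB", "SirA", "SirC", "Dsr"]
BETA_FAMILIES = ["AhbA", "AhbB", "AhbC", "AhbD", "VhoC", "HdrE", "KatG", "Fsr"]


def noise_free_config(
    n_per_group: int = 4,
    completeness: float = 1.0,
    rng_seed: int = 7,
    background: int = 30,
) -> CohortConfig:
    """Two groups with disjoint, certain (p=1) family profiles on a
    cysteine-free background: every downstream call is exactly predictable."""
    fams = default_families()
    alpha = GroupProfile(
        "alpha",
        {f: 1.0 for f in ALPHA_FAMILIES},
        planted_fes_fraction=0.08,
        target_identity={"SufB": 45.0, "FeoA": 50.0},
    )
    beta = GroupProfile(
        "beta",
        {f: 1.0 for f in BETA_FAMILIES},
        planted_fes_fraction=0.05,
        target_identity={"AhbB": 45.0},
    )
    return CohortConfig(
        groups=[alpha, beta],
        families=fams,
        n_genomes_per_group=n_per_group,
        background_proteins_per_genome=background,
        background_alphabet_policy="cysteine_free",
        completeness=completeness,
        rng_seed=rng_seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    from fesurvey.simulate import generate_cohort

    config = noise_free_config(n_per_group=3)
    proteomes, truth = generate_cohort(config)
    return config, proteomes, truth
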