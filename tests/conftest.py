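import pytest

from meiostates.io import design_from_community
from meiostates.synthetic_data import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One default-condition synthetic study, shared read-only."""
    return generate_study(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_design(default_study):
    return design_from_community(default_study.meiofauna.index)


def null_config(seed: int) -> GeneratorConfig:
    """A truly effect-free configuration: neutral multiplicative effects
    AND no structural state exclusivity (exclusive taxa/species are a real
    state effect, so a null study must drop them too)."""
    return GeneratorConfig(
        seed=seed,
        barren_effect_abundance=1.0,
        barren_effect_richness=1.0,
        barren_effect_biochem=1.0,
        exclusive_meadow_taxa=0,
        exclusive_meadow_species=0,
        exclusive_barren_species=0,
    )
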