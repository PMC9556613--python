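import pytest
from hypothesis import settings

from rxnaug.augment import default_fg_classes
from rxnaug.chem_core import parse_reaction_smiles
from rxnaug.synthetic_fixtures import GeneratorConfig, generate_with_recipes
from rxnaug.templates import default_templates

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# the complete reaction printed in the source material's attention-weight
# figure: Hiyama coupling of an aryl silane with an aryl bromide
FIG_REACTION = (
    "CC[Si](Cl)(Cl)c1ccc(C)cc1.N#Cc1ccc(Br)cc1.[F-].[K+]"
    ">>Cc1ccc(-c2ccc(C#N)cc2)cc1"
)

#: per-type default augmentation used across the tests
AUG_ROLES = {
    "hiyama": ("simultaneous", ("aryl_halide", "organosilicon")),
    "suzuki": ("simultaneous", ("aryl_halide", "organoboron")),
    "kumada": ("simultaneous", ("organyl_halide", "grignard")),
    "buchwald_hartwig": ("single", ("aryl_halide",)),
    "chan_lam": ("single", ("organoboron",)),
}


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def fg_classes():
    return default_fg_classes()


@pytest.fixture(scope="session")
def fig_record():
    return parse_reaction_smiles(FIG_REACTION)


@pytest.fixture(scope="session")
def hiyama_pairs():
    """25 Hiyama reactions with their textual recipes."""
    return generate_with_recipes(GeneratorConfig("hiyama", n_aryl=5, n_partner=5, seed=11))


@pytest.fixture(scope="session")
def all_type_pairs():
    """A small record+recipe sample for each of the five coupling classes."""
    out = {}
    for t in AUG_ROLES:
        out[t] = generate_with_recipes(GeneratorConfig(t, n_aryl=3, n_partner=3, seed=5))
    return out
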