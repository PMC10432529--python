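import numpy as np
import pytest

from phyllocomp import metabolic_overlap as mo
from phyllocomp import synthetic_data as sd

SMALL_INORGANICS = ("nh4", "pi", "so4")


@pytest.fixture(scope="session")
def toy_models():
    """Two toy species: a glucose+fructose generalist and a glucose specialist."""
    return sd.gen_toy_models(
        {"generalist": ["glucose", "fructose"], "specialist": ["glucose"]},
        inorganic_set=SMALL_INORGANICS,
    )


@pytest.fixture(scope="session")
def m5c_small():
    """M5C carbon sources over a three-compound inorganic base (keeps the
    exhaustive subset-search oracle cheap)."""
    return mo.media_presets("M5C", inorganics=SMALL_INORGANICS)


@pytest.fixture(scope="session")
def reference_tables():
    from phyllocomp import association_stats

    return association_stats.load_reference_tables()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
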