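import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from riboscreen.homology import ScoringScheme
from riboscreen.synthetic_data import GeneratorConfig, make_riboswitch_set


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def riboswitch_set():
    """The default synthetic WT riboswitch plus its seven point mutants."""
    return make_riboswitch_set(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def small_panel():
    """A 12-genome panel with 4 planted carriers (fast to screen)."""
    from riboscreen.synthetic_data import make_pangenome

    config = GeneratorConfig(seed=5, panel_size=12, n_carriers=4)
    return make_pangenome(config)
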