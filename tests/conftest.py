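import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pbutkin.strategies import build_strategy_catalogue
from pbutkin.study import SOLUTES, reference_c_pre, reference_kinetics


@pytest.fixture(scope="session")
def catalogue():
    return build_strategy_catalogue()


@pytest.fixture(scope="session")
def reference_bundles():
    """Canonical per-solute parameter bundles (central published values)."""
    return {s: reference_kinetics(s) for s in SOLUTES}


@pytest.fixture(scope="session")
def reference_cpre():
    return {s: reference_c_pre(s) for s in SOLUTES}


@pytest.fixture(scope="session")
def adequacy_grid(reference_bundles, catalogue):
    """Full 6-solute x 7-strategy adequacy comparison (shared; ~5 s)."""
    from pbutkin.strategies import compare_strategies

    return compare_strategies(reference_bundles, catalogue)
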