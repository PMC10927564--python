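import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from combasm import fixtures as fx
from combasm import representation as rp


@pytest.fixture(scope="session")
def tree_fixture():
    """Hetero tree of 6 unique subunits with decoys, plus its unified inputs."""
    spec = fx.ToyComplexSpec(
        topology="tree",
        subunit_specs=tuple((c, 15 + 2 * i, 1) for i, c in enumerate("ABCDEF")),
        seed=3,
        n_decoys=5,
    )
    gt, models = fx.fabricate_predictions(spec)
    reps = rp.select_representatives(models)
    library = rp.build_transform_library(models, reps)
    return gt, models, reps, library


@pytest.fixture(scope="session")
def small_ring_fixture():
    """6-copy homomeric ring with decoys (fast assembly fixture)."""
    spec = fx.ToyComplexSpec(
        topology="ring", subunit_specs=(("A", 20, 6),), seed=1, n_decoys=2
    )
    gt, models = fx.fabricate_predictions(spec)
    reps = rp.select_representatives(models)
    library = rp.build_transform_library(models, reps)
    return gt, models, reps, library


@pytest.fixture(scope="session")
def chain_fixture():
    """Hetero chain A-B-C, no decoys."""
    spec = fx.ToyComplexSpec(
        topology="chain",
        subunit_specs=(("A", 20, 1), ("B", 18, 1), ("C", 16, 1)),
        seed=2,
    )
    gt, models = fx.fabricate_predictions(spec)
    reps = rp.select_representatives(models)
    library = rp.build_transform_library(models, reps)
    return gt, models, reps, library
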