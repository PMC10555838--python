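import numpy as np
import pytest

from axocarto import synthgen
from axocarto.volio import AnnotationCube


@pytest.fixture(scope="session")
def axon_pair():
    """A deterministic sparse axon cube with exact ground truth."""
    return synthgen.make_axon_cube(extent=64, n_trees=1, radius_vox=2.0,
                                   snr=10.0, seed=0)


@pytest.fixture(scope="session")
def axon_pool():
    return [synthgen.make_axon_cube(extent=32, n_trees=1, radius_vox=1.5,
                                    snr=10.0, seed=s) for s in range(4)]


@pytest.fixture(scope="session")
def artifact_pool():
    kinds = ("vessel", "bright_spot", "edge")
    out = []
    for s in range(4):
        cube = synthgen.make_artifact_cube(extent=32, kind=kinds[s % 3], seed=100 + s)
        out.append(synthgen.CubePair(cube, AnnotationCube(np.zeros(cube.shape, np.uint8))))
    return out


@pytest.fixture(scope="session")
def phantom():
    """A six-region phantom at the coarse registration scale."""
    return synthgen.make_phantom_brain(shape=(40, 57, 66), n_regions=6, seed=7)
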