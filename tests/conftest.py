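import numpy as np
import pytest

from redoxdmri.io import GradientScheme
from redoxdmri.simulate import sphere_directions
from redoxdmri.skeleton import skeleton_template


def small_b_scheme(scale: float, ndir: int = 60, nb0: int = 1) -> GradientScheme:
    """Shells at b = {0, s, 2s, 3s} s/mm^2 — the cumulant-regime scheme used
    by the small-b DKI-fit oracles (fit bias vanishes as s -> 0)."""
    bv = np.concatenate([np.zeros(nb0)] + [np.full(ndir, k * scale) for k in (1, 2, 3)])
    gv = np.concatenate([np.zeros((nb0, 3))] + [sphere_directions(ndir)] * 3)
    return GradientScheme(bvals=bv, bvecs=gv, shell_tolerance=min(10.0, scale / 3))


@pytest.fixture(scope="session")
def small_template():
    """~1.8k-voxel spherical-shell skeleton (reduced size for permutation runs)."""
    return skeleton_template(radius=12)


@pytest.fixture(scope="session")
def tiny_template():
    return skeleton_template(radius=5)
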