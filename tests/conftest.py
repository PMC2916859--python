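import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import quartersite as qs


@pytest.fixture(scope="session")
def template():
    """Synthetic half-site template for the 14-3-3σ first half site."""
    return qs.build_template("AGGCATGTGC", name="14-3-3sigma-h1")


@pytest.fixture(scope="session")
def small_ensemble(template):
    """A 20-frame default-truth ensemble for exact brute-force oracle checks."""
    truth = qs.default_truth(20)
    return qs.generate(template, truth, seed=7)


def random_rigid(rng):
    """A random proper rotation + translation."""
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-20, 20, 3)
    return rot, trans


def apply_rigid(coords, rot, trans):
    """Apply one rigid transform to every frame of an (m, n, 3) array."""
    return coords @ rot.T + trans
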