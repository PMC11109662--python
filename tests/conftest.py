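import numpy as np
import pytest

from funnelmd.colvars import StructureModel


@pytest.fixture
def make_structure():
    """Factory for small synthetic atom tables (coordinates in nm)."""

    def _make(coords, resids, names=None, elements=None):
        coords = np.asarray(coords, dtype=float)
        n = coords.shape[0]
        resids = np.asarray(resids, dtype=int)
        return StructureModel(
            serial=np.arange(1, n + 1),
            name=np.array(names if names is not None else ["X"] * n,
                          dtype=object),
            resname=np.array(["ALA"] * n, dtype=object),
            resid=resids,
            chain=np.array(["A"] * n, dtype=object),
            element=np.array(elements if elements is not None else ["C"] * n,
                             dtype=object),
            coords=coords,
            source="synthetic test structure",
        )

    return _make


@pytest.fixture
def random_rigid_transform():
    """Factory drawing a uniformly random rotation + translation."""

    def _draw(rng):
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        trans = rng.uniform(-3.0, 3.0, 3)
        return rot, trans

    return _draw
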