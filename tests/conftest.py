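import numpy as np
import pytest

from optotract.config import RunConfig
from optotract.surface import LabeledSurface
from optotract.synthetic import (
    TractGroundTruth,
    make_labeled_surface,
    make_tractogram,
)


def flat_sheet(extent: float = 10.0, res: int = 11, label: int = 1) -> LabeledSurface:
    """Plane z = 0 with outward normal +z (analytic reference surface)."""
    xs = np.linspace(-extent / 2, extent / 2, res)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    vertices = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(res * res)])
    tris = []
    for i in range(res - 1):
        for j in range(res - 1):
            v00 = i * res + j
            v10 = (i + 1) * res + j
            v01 = i * res + j + 1
            v11 = (i + 1) * res + j + 1
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    return LabeledSurface(
        vertices, np.array(tris), np.full(res * res, label, dtype=int)
    )


@pytest.fixture(scope="session")
def sheet():
    return flat_sheet()


@pytest.fixture(scope="session")
def folded_surface():
    return make_labeled_surface(n_regions=3, mesh_resolution=20, rng_seed=7)


@pytest.fixture(scope="session")
def planted_tractogram(folded_surface):
    truth = TractGroundTruth(n_true=20, n_decoy=12)
    tractogram, annotations = make_tractogram(folded_surface, truth, rng_seed=11)
    return tractogram, annotations, truth


@pytest.fixture()
def config():
    return RunConfig()
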