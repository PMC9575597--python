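import numpy as np
import pytest

from subshape import make_template_atlas, simulate_cohort
from subshape.fdr import build_neighborhoods


@pytest.fixture(scope="session")
def atlas():
    return make_template_atlas()


@pytest.fixture(scope="session")
def neighborhoods(atlas):
    return build_neighborhoods(atlas)


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(seed=20240915)


def capped_cylinder(radius=5.0, length=30.0, rows=24, cols=16):
    """Closed cylinder-like tube along z with hemispherical-ish caps,
    built on the same pole-capped UV topology as the atlas meshes."""
    theta = np.linspace(0.0, np.pi, rows + 2)[1:-1]
    t = np.cos(theta)
    # near-constant radius over the shaft, shrinking only near poles
    rho = radius * np.sqrt(np.maximum(1 - t**8, 0.0))
    z = 0.5 * length * t
    phi = np.linspace(0, 2 * np.pi, cols, endpoint=False)
    rings = np.stack(
        [
            np.outer(rho, np.cos(phi)),
            np.outer(rho, np.sin(phi)),
            np.repeat(z[:, None], cols, axis=1),
        ],
        axis=2,
    )
    verts = np.concatenate(
        [[[0, 0, 0.5 * length]], rings.reshape(-1, 3), [[0, 0, -0.5 * length]]]
    )
    faces = []
    top, bottom = 0, rows * cols + 1

    def rid(i, j):
        return 1 + i * cols + (j % cols)

    for j in range(cols):
        faces.append([top, rid(0, j + 1), rid(0, j)])
    for i in range(rows - 1):
        for j in range(cols):
            faces.append([rid(i, j), rid(i, j + 1), rid(i + 1, j + 1)])
            faces.append([rid(i, j), rid(i + 1, j + 1), rid(i + 1, j)])
    for j in range(cols):
        faces.append([bottom, rid(rows - 1, j), rid(rows - 1, j + 1)])
    return verts, np.asarray(faces)
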