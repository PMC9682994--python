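import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: master seed of the synthetic study population used by the end-to-end tests
STUDY_SEED = 11
STUDY_COUNTS = {"ring": 60, "cage_sphere": 60, "cage_polyhedron": 60,
                "grid": 60, "chain": 60}


@pytest.fixture(scope="session")
def study_dataset():
    """300 synthetic shapes (5 families × 60) fingerprinted once per session."""
    from cagetda.shapes import make_labeled_dataset

    X, families, coarse, specs = make_labeled_dataset(
        STUDY_COUNTS, sigma=0.01, seed=STUDY_SEED
    )
    binary = ["cage" if c in ("cage", "ring") else "non_cage" for c in coarse]
    return {"X": X, "families": families, "coarse": coarse,
            "binary": binary, "specs": specs}


@pytest.fixture()
def square_cloud():
    from cagetda.structure import PointCloud

    return PointCloud(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float))


@pytest.fixture()
def octahedron_cloud():
    from cagetda.structure import PointCloud

    return PointCloud(
        np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
                 float)
    )
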