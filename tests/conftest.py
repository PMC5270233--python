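import numpy as np
import pytest

import metasvm as ms


@pytest.fixture(scope="session")
def sim01():
    """One simulated 3-study dataset at low variance (R=0.1)."""
    return ms.generate(ms.SimulationSpec(R=0.1, seed=11))


@pytest.fixture()
def toy_dataset():
    """Two small studies with a planted 2-feature signal."""
    rng = np.random.default_rng(5)
    studies = []
    for m in range(2):
        X = rng.normal(size=(12, 4))
        y = np.repeat([-1.0, 1.0], 6)
        X[y > 0, :2] += 1.5
        studies.append(ms.StudyData(X, y, name=f"toy{m + 1}"))
    return ms.MetaDataset(studies, [f"f{i + 1}" for i in range(4)])


@pytest.fixture()
def separable_study():
    """Four points in 2-D, linearly separable with margin > 1."""
    X = np.array([[2.0, 2.0], [3.0, 1.0], [-2.0, -2.0], [-1.0, -3.0]])
    y = np.array([1.0, 1.0, -1.0, -1.0])
    return ms.MetaDataset(
        [ms.StudyData(X, y, name="sep")], ["a", "b"]
    )
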