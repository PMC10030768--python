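import pytest

from spinanneal import (
    AnnealingParams,
    AssignmentProblem,
    ResidueTypeStats,
    generate_dataset,
    predictions_from_truth,
)


@pytest.fixture(scope="session")
def stats():
    return ResidueTypeStats.packaged()


@pytest.fixture(scope="session")
def fast_params():
    """Annealing parameters with small equilibration samples for test speed."""
    return AnnealingParams(sample_floor=300, sample_ceiling=2000)


@pytest.fixture(scope="session")
def truth20():
    """Noise-free 20-residue synthetic dataset."""
    return generate_dataset(length=20, seed=3, noise=0)


@pytest.fixture(scope="session")
def problem20(truth20):
    preds = predictions_from_truth(truth20)
    return AssignmentProblem.from_peaks(truth20.all_peaks, truth20.sequence, preds)


@pytest.fixture(scope="session")
def truth30():
    """30-residue synthetic dataset at the default noise levels."""
    return generate_dataset(length=30, seed=5)


@pytest.fixture(scope="session")
def problem30(truth30):
    preds = predictions_from_truth(truth30)
    return AssignmentProblem.from_peaks(truth30.all_peaks, truth30.sequence, preds)
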