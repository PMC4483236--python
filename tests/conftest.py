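import numpy as np
import pytest

from hilldeg import DegradationParams, stationary_pmf
from hilldeg.preprocess import write_records
from hilldeg.synthetic import StudyDesign, generate_study


@pytest.fixture(scope="session")
def nb_pmf():
    """Negative binomial (alpha=1) stationary pmf with a small mean."""
    return stationary_pmf(DegradationParams(1.0, 10.0, 0.6), 300)


@pytest.fixture(scope="session")
def gnb_pmf():
    """Cooperative (alpha=2) stationary pmf at the reference parameters."""
    return stationary_pmf(DegradationParams(2.0, 250.0, 0.8), 1000)


@pytest.fixture(scope="session")
def small_study():
    """Three-passage, two-replica synthetic study kept small for speed."""
    design = StudyDesign(
        passages=(3, 8, 13),
        n_per_passage=(150, 120, 150),
        gamma_by_passage=(0.2, 0.5, 0.85),
        theta=200.0,
        experiments_by_passage={
            3: ("exp1", "exp2"), 8: ("exp1", "exp2"), 13: ("exp1", "exp2")
        },
        seed=42,
    )
    return generate_study(design)


@pytest.fixture()
def study_csv(tmp_path, small_study):
    records, _ = small_study
    path = tmp_path / "study.csv"
    write_records(records, path)
    return path
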