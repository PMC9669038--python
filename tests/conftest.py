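import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sarcopipe.cohort import load_manifest
from sarcopipe.phantoms import CohortConfig, generate_cohort

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A small noiseless three-sequence cohort rendered once per session."""
    d = tmp_path_factory.mktemp("cohort")
    cfg = CohortConfig(
        n_sarcoma=8,
        n_leiomyoma=12,
        sequence_availability={"T2axi": 1.0, "DWI": 0.8, "ADC": 0.7},
        slices_per_series=(2, 3),
        extra_studies_per_sarcoma=(0, 1),
        canvas=64,
        noise_sd=0.0,
        seed=7,
    )
    generate_cohort(cfg, d)
    return d


@pytest.fixture(scope="session")
def small_records(small_cohort_dir):
    return load_manifest(small_cohort_dir / "manifest.csv")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
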