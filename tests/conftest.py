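import numpy as np
import pytest

from difnet.model import (
    DifnetConfig,
    FusionConfig,
    MultiscaleConfig,
    TCNConfig,
    TransformerConfig,
)
from difnet.preprocess import epoch_recording, standardize
from difnet.synthetic import (
    SubjectProfile,
    SyntheticCohortConfig,
    generate_cohort,
    generate_subject,
)
from difnet.preprocess import concat_epochs


def tiny_config(indicators: str = "N", module_order: str = "T1T2",
                n_channels: int = 4, n_samples: int = 500) -> DifnetConfig:
    """Minimal architecture for fast training in tests: same topology as the
    full model, a handful of filters."""
    return DifnetConfig(
        multiscale=MultiscaleConfig(kernel_sizes=(31, 15, 7),
                                    temporal_filters=2,
                                    n_channels=n_channels,
                                    dropout=0.1),
        transformer=TransformerConfig(n_layers=1, n_heads=2, head_dim=6,
                                      dropout=0.1),
        tcn=TCNConfig(filters=8, kernel=3, dropout=0.1),
        fusion=FusionConfig(indicators=indicators),
        module_order=module_order,
        n_samples=n_samples,
    )


@pytest.fixture()
def profile():
    return SubjectProfile(subject_id="sub-001", label="HC", age=30, sex=0,
                          education_years=12)


@pytest.fixture()
def mdd_profile():
    return SubjectProfile(subject_id="sub-002", label="MDD", age=40, sex=1,
                          education_years=16)


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects, 4 channels, 12 s each: enough epochs for fold tests."""
    cfg = SyntheticCohortConfig(
        n_mdd=2, n_hc=2, duration=12.0,
        channel_names=("Fp1", "Fp2", "O1", "O2"), seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_epochs(small_cohort):
    recordings, _ = small_cohort
    per = [standardize(epoch_recording(r, window=2.0, overlap=0.5))
           for r in recordings]
    return concat_epochs(per)
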