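import numpy as np
import pytest

from metricbounds import (
    CalibrationRecord,
    GeneratorConfig,
    MetricEnsemble,
    MiscoverageRates,
    generate_metric_pool,
)


@pytest.fixture
def rates10() -> MiscoverageRates:
    return MiscoverageRates(alpha_lo=0.1, alpha_hi=0.1)


@pytest.fixture
def rates05() -> MiscoverageRates:
    return MiscoverageRates(alpha_lo=0.05, alpha_hi=0.05)


@pytest.fixture
def small_pool() -> list[CalibrationRecord]:
    """A 40-subject exchangeable pool, mildly biased and over-dispersed."""
    return generate_metric_pool(
        GeneratorConfig(n_subjects=40, ns=50, bias=2.0, noise_sd=5.0,
                        dispersion_factor=1.2, seed=11)
    )


def make_record(values, truth, subject_id="s") -> CalibrationRecord:
    return CalibrationRecord(
        ensemble=MetricEnsemble(subject_id=subject_id, values=np.asarray(values, float)),
        truth=float(truth),
    )
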