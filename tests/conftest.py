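import numpy as np
import pytest

from flavotarget.study import ExpressionStudy
from flavotarget.synth import SyntheticConfig, generate_cohorts


@pytest.fixture(scope="session")
def planted_study():
    """Two-cohort study with a strong planted signal and mild batch effects."""
    cfg = SyntheticConfig(
        n_cohorts=2,
        samples_per_cohort=((20, 20), (20, 20)),
        n_genes=400,
        n_informative=5,
        effect_size=2.0,
        batch_shift_sd=0.8,
        batch_scale_sd=0.2,
        noise_sd=1.0,
        seed=11,
    )
    return generate_cohorts(cfg)


@pytest.fixture(scope="session")
def null_study():
    """No signal, no batch structure: pure Gaussian noise around baselines."""
    cfg = SyntheticConfig(
        n_cohorts=2,
        samples_per_cohort=((15, 15), (15, 15)),
        n_genes=500,
        n_informative=0,
        effect_size=0.0,
        batch_shift_sd=0.0,
        batch_scale_sd=0.0,
        noise_sd=1.0,
        seed=5,
    )
    study, _ = generate_cohorts(cfg)
    return study


def make_study(values, n_disease, n_control, cohorts=None, genes=None):
    """Hand-build a study from a genes x samples array."""
    values = np.asarray(values, dtype=float)
    n = n_disease + n_control
    assert values.shape[1] == n
    genes = genes or [f"G{i:03d}" for i in range(values.shape[0])]
    samples = [f"S{i:03d}" for i in range(n)]
    cohorts = cohorts or ["C1"] * n
    cohort = dict(zip(samples, cohorts))
    condition = {
        s: ("disease" if i < n_disease else "control")
        for i, s in enumerate(samples)
    }
    return ExpressionStudy(genes, samples, values, cohort, condition)
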