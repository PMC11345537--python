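import numpy as np
import pytest

from glioslide.synthcohort import (LatentPatient, SubtypeMixture, SynthConfig,
                                   generate_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale generator configuration shared across unit tests."""
    return SynthConfig.test_profile(seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """Eight rendered patients with CD8/CD68 marker maps."""
    from dataclasses import replace

    cfg = replace(small_cfg, n_patients=8)
    return generate_cohort(cfg, markers=("CD8", "CD68"))


def pure_patient(subtype_index: int, risk: float = 0.0,
                 pid: str = "PURE") -> LatentPatient:
    v = [0.0, 0.0, 0.0]
    v[subtype_index] = 1.0
    return LatentPatient(patient_id=pid, mixture=SubtypeMixture(*v),
                         latent_risk=risk, age_years=60.0, sex="female",
                         tmz=False, surv_time_years=1.0, event=True)
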