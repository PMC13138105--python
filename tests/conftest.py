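import numpy as np
import pytest

import refkin

K1_REF = 0.17
K2PRIME = 0.059


@pytest.fixture(scope="session")
def schedule():
    return refkin.default_schedule()


@pytest.fixture(scope="session")
def aif():
    return refkin.default_input()


@pytest.fixture(scope="session")
def ref_tac(aif, schedule):
    """Noise-free white-matter reference TAC (K1'=0.17, k2'=0.059)."""
    return refkin.simulate_1tc_tac(aif, K1_REF, K2PRIME, schedule, region_id="centrum_semiovale")


def make_target(aif, schedule, R1, bp, k2prime=K2PRIME, name="target"):
    """Noise-free target TAC consistent with the reference kinetics."""
    k2 = R1 * k2prime
    k2a = k2 / (1.0 + bp)
    return refkin.simulate_1tc_tac(aif, R1 * K1_REF, k2a, schedule, region_id=name)


@pytest.fixture(scope="session")
def target_tac(aif, schedule):
    """High-binding gray-matter target: R1=1.6, BP_ND=3."""
    return make_target(aif, schedule, 1.6, 3.0)


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noise-free, jitter-free cohort for deterministic pipeline tests.

    ref_sd=0 keeps every subject's true reference clearance at the
    population value, so SRTM2 fixed at that k2' is exactly correct.
    """
    cfg = refkin.CohortConfig(
        n_subjects=3, n_retest=2, noise_scale=0.0, jitter_sd=0.0, ref_sd=0.0
    )
    return refkin.simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-noise cohort (full design) shared across tests."""
    return refkin.simulate_cohort(refkin.CohortConfig(), seed=23)
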