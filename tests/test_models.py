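"""Kinetic model fits: recovery, consistency, uncertainty bookkeeping."""

import numpy as np
import pytest

import refkin
from refkin import (
    CEREBELLUM_K2PRIME,
    CS_K2PRIME,
    TimeActivityCurve,
    compute_aic,
    fit_1tc,
    fit_srtm,
    fit_srtm2,
    fit_srtmc,
    population_k2prime,
)
from refkin.models import SRTM2, compute_weights

from conftest import K1_REF, K2PRIME, make_target


# --------------------------------------------------------------------- AIC


def test_aic_formula_and_errors():
    assert compute_aic(27.0, 27, 2) == pytest.approx(4.0)
    # equal misfit, one extra parameter -> AIC penalty of exactly 2
    assert compute_aic(5.0, 27, 3) - compute_aic(5.0, 27, 2) == pytest.approx(2.0)
    with pytest.raises(ValueError, match="positive"):
        compute_aic(0.0, 27, 2)
    with pytest.raises(ValueError, match="n > p"):
        compute_aic(1.0, 2, 2)


def test_reported_aic_recomputable_from_wrss(ref_tac, schedule, aif):
    tac = make_target(aif, schedule, 1.5, 2.0)
    noisy = refkin.add_noise(tac, schedule, refkin.NoiseModel(scale=1.0), seed=3)
    f3 = fit_srtm(noisy, ref_tac, schedule)
    f2 = fit_srtm2(noisy, ref_tac, K2PRIME, schedule)
    n = schedule.n_frames
    assert f3.aic == pytest.approx(n * np.log(f3.wrss / n) + 6)
    assert f2.aic == pytest.approx(n * np.log(f2.wrss / n) + 4)


def test_population_k2prime_is_arithmetic_mean():
    assert population_k2prime([0.059]) == pytest.approx(0.059)
    assert population_k2prime([0.05, 0.07]) == pytest.approx(0.06)
    with pytest.raises(ValueError):
        population_k2prime([])
    # named population defaults for the two reference regions
    assert CS_K2PRIME == 0.059 and CEREBELLUM_K2PRIME == 0.052


# --------------------------------------------------------------- recovery


@pytest.mark.parametrize("R1,bp", [(0.8, 0.8), (1.2, 2.0), (1.6, 3.8)])
def test_noise_free_srtm_recovery(ref_tac, schedule, aif, R1, bp):
    tac = make_target(aif, schedule, R1, bp)
    f = fit_srtm(tac, ref_tac, schedule)
    assert f.converged
    assert f.params["R1"] == pytest.approx(R1, rel=5e-3)
    assert f.params["BP_ND"] == pytest.approx(bp, rel=5e-3)
    assert f.params["k2"] == pytest.approx(R1 * K2PRIME, rel=5e-3)
    assert f.params["k2prime"] == pytest.approx(K2PRIME, rel=5e-3)


@pytest.mark.parametrize("R1,bp", [(0.8, 0.8), (1.6, 3.8)])
def test_noise_free_srtm2_recovery_at_true_k2prime(ref_tac, schedule, aif, R1, bp):
    tac = make_target(aif, schedule, R1, bp)
    f = fit_srtm2(tac, ref_tac, K2PRIME, schedule)
    assert f.converged
    assert f.params["R1"] == pytest.approx(R1, rel=5e-3)
    assert f.params["BP_ND"] == pytest.approx(bp, rel=5e-3)


def test_noise_free_1tc_recovery(aif, schedule):
    K1, k2 = 0.3, 0.10
    tac = refkin.simulate_1tc_tac(aif, K1, k2, schedule)
    f = fit_1tc(tac, aif, schedule)
    assert f.converged
    assert f.params["K1"] == pytest.approx(K1, rel=1e-3)
    assert f.params["k2"] == pytest.approx(k2, rel=1e-3)


def test_1tc_is_linear_in_delivery(aif, schedule):
    tac = refkin.simulate_1tc_tac(aif, 0.25, 0.08, schedule)
    doubled = tac.with_values(2.0 * tac.values)
    f1 = fit_1tc(tac, aif, schedule)
    f2 = fit_1tc(doubled, aif, schedule)
    assert f2.params["K1"] == pytest.approx(2.0 * f1.params["K1"], rel=1e-4)
    assert f2.params["k2"] == pytest.approx(f1.params["k2"], rel=1e-4)


def test_1tc_flat_zero_tac_flagged(aif, schedule):
    zero = TimeActivityCurve("z", np.zeros(schedule.n_frames), schedule)
    f = fit_1tc(zero, aif, schedule)
    assert not f.converged  # K1 pinned at its lower bound


def test_srtm_on_reference_itself_gives_unity_r1_zero_bp(ref_tac, schedule):
    f = fit_srtm(ref_tac, ref_tac, schedule)
    assert f.params["R1"] == pytest.approx(1.0, abs=1e-3)
    assert f.params["BP_ND"] == pytest.approx(0.0, abs=1e-3)
    f2 = fit_srtm2(ref_tac, ref_tac, K2PRIME, schedule)
    assert f2.params["R1"] == pytest.approx(1.0, abs=1e-3)
    assert f2.params["BP_ND"] == pytest.approx(0.0, abs=1e-3)


def test_zero_reference_rejected(schedule, target_tac):
    zero = TimeActivityCurve("z", np.zeros(schedule.n_frames), schedule)
    with pytest.raises(ValueError, match="zero"):
        fit_srtm(target_tac, zero, schedule)


def test_srtm2_requires_positive_k2prime(ref_tac, target_tac, schedule):
    with pytest.raises(ValueError, match="positive"):
        fit_srtm2(target_tac, ref_tac, 0.0, schedule)


# ------------------------------------------------------------------ SRTMC


def test_srtmc_recovers_shared_clearance(ref_tac, schedule, aif):
    specs = [(1.0, 1.0), (1.3, 2.0), (1.6, 3.0), (1.8, 3.8)]
    tacs = [make_target(aif, schedule, r, b, name=f"r{i}") for i, (r, b) in enumerate(specs)]
    joint = fit_srtmc(tacs, ref_tac, schedule)
    assert joint.converged
    assert joint.k2prime == pytest.approx(K2PRIME, rel=1e-3)
    for res, (r, b) in zip(joint.results, specs):
        assert res.params["R1"] == pytest.approx(r, rel=5e-3)
        assert res.params["BP_ND"] == pytest.approx(b, rel=5e-3)


def test_srtmc_identical_regions_get_identical_estimates(ref_tac, schedule, aif):
    tac = make_target(aif, schedule, 1.4, 2.5)
    twin = TimeActivityCurve("twin", tac.values.copy(), schedule)
    joint = fit_srtmc([tac, twin], ref_tac, schedule)
    a, b = joint.results
    assert a.params["R1"] == pytest.approx(b.params["R1"], rel=1e-6)
    assert a.params["BP_ND"] == pytest.approx(b.params["BP_ND"], rel=1e-6)


def test_srtmc_joint_optimum_matches_decoupled_srtm2(ref_tac, schedule, aif):
    """At the jointly fitted k2' the coupled problem decouples, so the
    summed WRSS of SRTM2 fits at that k2' equals the joint WRSS."""
    tacs = [make_target(aif, schedule, r, b, name=f"r{r}")
            for r, b in [(1.1, 1.5), (1.5, 3.0)]]
    noisy = [refkin.add_noise(t, schedule, refkin.NoiseModel(scale=0.8), seed=i)
             for i, t in enumerate(tacs)]
    joint = fit_srtmc(noisy, ref_tac, schedule)
    decoupled = sum(
        fit_srtm2(t, ref_tac, joint.k2prime, schedule).wrss for t in noisy
    )
    assert joint.total_wrss == pytest.approx(decoupled, rel=1e-6)
    assert joint.total_wrss <= decoupled * (1.0 + 1e-9)


def test_srtmc_needs_at_least_two_regions(ref_tac, target_tac, schedule):
    with pytest.raises(ValueError, match="two target regions"):
        fit_srtmc([target_tac], ref_tac, schedule)


# ----------------------------------------------------------- consistency


def test_srtm2_reproduces_srtm_at_its_derived_clearance(ref_tac, schedule, aif):
    tac = make_target(aif, schedule, 1.4, 2.2)
    f3 = fit_srtm(tac, ref_tac, schedule)
    assert f3.converged
    f2 = fit_srtm2(tac, ref_tac, f3.params["k2prime"], schedule)
    assert f2.params["BP_ND"] == pytest.approx(f3.params["BP_ND"], rel=1e-3)


def test_weight_scale_invariance(ref_tac, schedule, aif):
    tac = make_target(aif, schedule, 1.3, 1.8)
    noisy = refkin.add_noise(tac, schedule, refkin.NoiseModel(scale=1.0), seed=5)
    w = compute_weights(schedule, "duration")
    a = SRTM2(noisy, ref_tac, K2PRIME, schedule, w).fit()
    b = SRTM2(noisy, ref_tac, K2PRIME, schedule, 5.0 * w).fit()
    for k in a.params:
        assert a.params[k] == pytest.approx(b.params[k], rel=1e-8)
        assert a.rse[k] == pytest.approx(b.rse[k], rel=1e-6)


def test_rse_definition(ref_tac, schedule, aif):
    tac = make_target(aif, schedule, 1.5, 2.5)
    noisy = refkin.add_noise(tac, schedule, refkin.NoiseModel(scale=1.0), seed=9)
    f = fit_srtm2(noisy, ref_tac, K2PRIME, schedule)
    for k, se in f.bse.items():
        assert f.rse[k] == pytest.approx(100.0 * se / abs(f.params[k]))


def test_fitted_k2_bias_increases_with_imposed_k2prime_bias(ref_tac, schedule, aif):
    """Fixing k2' away from truth drags the derived k2 = R1*k2' with it."""
    tac = make_target(aif, schedule, 1.5, 2.5)
    k2_true = 1.5 * K2PRIME
    biases = np.array([-0.2, -0.1, 0.0, 0.1, 0.2])
    k2_bias = []
    for b in biases:
        f = fit_srtm2(tac, ref_tac, K2PRIME * (1.0 + b), schedule)
        k2_bias.append(f.params["k2"] / k2_true - 1.0)
    assert np.all(np.diff(k2_bias) > 0)


def test_summary_renders(ref_tac, schedule, target_tac):
    f = fit_srtm2(target_tac, ref_tac, K2PRIME, schedule)
    text = f.summary()
    assert "SRTM2" in text and "BP_ND" in text and "rSE" in text
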