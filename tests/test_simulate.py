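"""Simulator: forward model, noise model, cohort generation."""

import numpy as np
import pytest
from scipy.integrate import simpson, solve_ivp

import refkin
from refkin import (
    CohortConfig,
    NoiseModel,
    RegionKinetics,
    TrueKinetics,
    add_noise,
    simulate_1tc_tac,
    simulate_cohort,
    simulate_reference_and_targets,
)


def ode_frame_averages(aif, K1, k2, schedule):
    """Independent oracle: stiff ODE solve of dC/dt = K1*Cp - k2*C, then
    per-frame Simpson averaging of the dense solution."""
    sol = solve_ivp(
        lambda t, y: [K1 * float(aif(t)) - k2 * y[0]],
        (0.0, schedule.t_end), [0.0],
        method="Radau", rtol=1e-10, atol=1e-12, dense_output=True,
    )
    out = []
    for s, e in zip(schedule.start, schedule.end):
        tt = np.linspace(s, e, 201)
        out.append(simpson(sol.sol(tt)[0], x=tt) / (e - s))
    return np.asarray(out)


def test_forward_model_matches_ode_oracle(aif, schedule):
    tac = simulate_1tc_tac(aif, 0.3, 0.06, schedule)
    oracle = ode_frame_averages(aif, 0.3, 0.06, schedule)
    np.testing.assert_allclose(tac.values, oracle, rtol=1e-3, atol=1e-9)


def test_zero_delivery_gives_zero_tac(aif, schedule):
    tac = simulate_1tc_tac(aif, 0.0, 0.1, schedule)
    assert np.all(tac.values == 0.0)


def test_fast_efflux_reaches_equilibrium_with_plasma(aif, schedule):
    # for large k2 the tissue tracks (K1/k2)*Cp; exact only past the bolus
    K1, k2 = 0.5, 10.0
    tac = simulate_1tc_tac(aif, K1, k2, schedule)
    late = schedule.mid > 3.0
    target = (K1 / k2) * aif(schedule.mid[late])
    np.testing.assert_allclose(tac.values[late], target, rtol=1e-2)


def test_invalid_simulation_parameters_rejected(aif, schedule):
    with pytest.raises(ValueError, match="positive"):
        simulate_1tc_tac(aif, -0.1, 0.05, schedule)
    with pytest.raises(ValueError, match="vB"):
        simulate_1tc_tac(aif, 0.3, 0.05, schedule, vB=0.5)


def test_blood_volume_adds_plasma_signal(aif, schedule):
    pure = simulate_1tc_tac(aif, 0.3, 0.06, schedule)
    mixed = simulate_1tc_tac(aif, 0.3, 0.06, schedule, vB=0.05)
    # during the bolus peak plasma dominates tissue
    assert mixed.values[1] > pure.values[1]


def test_reference_kinetics_target_equals_reference(aif, schedule):
    truth = TrueKinetics((
        RegionKinetics("ref", 0.17, 0.059, is_reference=True),
        RegionKinetics("twin", 0.17, 0.059),
    ))
    ref, twin = simulate_reference_and_targets(truth, aif, schedule)
    np.testing.assert_array_equal(ref.values, twin.values)


def test_low_clearance_reference_peaks_later_and_lower(aif, schedule):
    truth = TrueKinetics((
        RegionKinetics("cs", 0.17, 0.059, is_reference=True),
        RegionKinetics("gm", 0.45, 0.030),
    ))
    ref, gm = simulate_reference_and_targets(truth, aif, schedule)
    assert ref.values.max() < gm.values.max()
    assert np.argmax(ref.values) <= np.argmax(gm.values)


def test_reference_region_required():
    with pytest.raises(ValueError, match="reference"):
        TrueKinetics((RegionKinetics("a", 0.3, 0.05),))


def test_noise_scale_zero_is_identity(aif, schedule):
    tac = simulate_1tc_tac(aif, 0.3, 0.06, schedule)
    out = add_noise(tac, schedule, NoiseModel(scale=0.0), seed=1)
    assert np.array_equal(out.values, tac.values)


def test_noise_is_deterministic_given_seed(aif, schedule):
    tac = simulate_1tc_tac(aif, 0.3, 0.06, schedule)
    nm = NoiseModel(scale=1.0)
    a = add_noise(tac, schedule, nm, seed=42)
    b = add_noise(tac, schedule, nm, seed=42)
    c = add_noise(tac, schedule, nm, seed=43)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_negative_noise_scale_rejected():
    with pytest.raises(ValueError, match=">= 0"):
        NoiseModel(scale=-1.0)


def test_empirical_frame_sd_matches_noise_model(aif, schedule):
    tac = simulate_1tc_tac(aif, 0.3, 0.06, schedule)
    nm = NoiseModel(scale=1.0)
    rng = np.random.default_rng(7)
    reps = np.stack([
        add_noise(tac, schedule, nm, rng).values - tac.values for _ in range(1000)
    ])
    emp_sd = reps.std(axis=0, ddof=1)
    np.testing.assert_allclose(emp_sd, nm.sigma(tac.values, schedule), rtol=0.10)


def test_default_cohort_matches_study_design():
    cohort = simulate_cohort(CohortConfig(), seed=1)
    assert len(cohort.scans) == 14  # 9 subjects, 5 rescanned
    assert len({s.subject for s in cohort.scans}) == 9
    assert len(cohort.regions) == 15
    refs = cohort.reference_regions
    assert refs["bpnd"] == "centrum_semiovale" and refs["dvr"] == "cerebellum"
    for scan in cohort.scans:
        assert set(cohort.regions) <= set(scan.curves)
        assert "centrum_semiovale" in scan.curves


def test_retest_subset_cannot_exceed_cohort():
    with pytest.raises(ValueError, match="retest"):
        CohortConfig(n_subjects=3, n_retest=4)


def test_zero_jitter_zero_noise_sessions_identical():
    cohort = simulate_cohort(CohortConfig(noise_scale=0.0, jitter_sd=0.0), seed=2)
    a = cohort.scan("sub01", "test")
    b = cohort.scan("sub01", "retest")
    for region in a.curves:
        assert np.array_equal(a.curves[region].values, b.curves[region].values)


def test_ground_truth_binding_potentials_within_configured_range():
    cfg = CohortConfig(bp_range=(0.5, 4.0))
    cohort = simulate_cohort(cfg, seed=3)
    targets = cohort.truth[~cohort.truth["is_reference"]]
    assert targets["BP_ND"].between(0.5, 4.0).all()


def test_cohort_regeneration_is_byte_identical(tmp_path):
    import filecmp

    cfg = CohortConfig(n_subjects=2, n_retest=1)
    refkin.generate_cohort(cfg, seed=9, outdir=tmp_path / "a")
    refkin.generate_cohort(cfg, seed=9, outdir=tmp_path / "b")
    cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")
    assert not cmp.diff_files
    sub = filecmp.dircmp(tmp_path / "a" / "tacs", tmp_path / "b" / "tacs")
    assert not sub.diff_files and len(sub.common_files) == 3
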