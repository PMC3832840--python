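"""Phantom generator: trajectories, cohort sampling, signal model."""

import numpy as np
import pytest

import adchist as a
from adchist.phantom import FAST_HEAD_SHARE


@pytest.mark.parametrize(
    "coeffs, age, expected",
    [
        ((83.5, -0.068, -0.0027), 0.0, 83.5),
        ((50.0, 0.0, 0.0), 42.0, 50.0),
        ((83.5, -0.068, -0.0027), 80.0, 60.78),
    ],
)
def test_true_fraction_evaluates_the_quadratic(coeffs, age, expected):
    traj = a.AgeTrajectory(*coeffs)
    assert a.true_fraction(traj, age) == pytest.approx(expected, abs=1e-12)


def test_trajectory_rejects_invalid_parameters():
    with pytest.raises(ValueError):
        a.AgeTrajectory(80.0, 0.0, 0.0, subject_sd=-1.0)
    with pytest.raises(ValueError):
        a.AgeTrajectory(50.0, 1.0, 0.0)  # exceeds 100% before age 90


def test_constant_trajectory_gives_exact_fraction():
    traj = a.AgeTrajectory(80.0)
    manifest = a.sample_cohort(1, (5.0, 85.0), traj, seed=3)
    assert manifest.subjects[0].true_brain_fraction == pytest.approx(80.0)


def test_sample_cohort_is_deterministic(aging_trajectory):
    m1 = a.sample_cohort(12, (5.0, 85.0), aging_trajectory, seed=7)
    m2 = a.sample_cohort(12, (5.0, 85.0), aging_trajectory, seed=7)
    assert m1.to_frame().equals(m2.to_frame())


def test_sample_cohort_rejects_bad_inputs(aging_trajectory):
    with pytest.raises(ValueError):
        a.sample_cohort(0, (5.0, 85.0), aging_trajectory, seed=1)
    with pytest.raises(ValueError):
        a.sample_cohort(5, (60.0, 60.0), aging_trajectory, seed=1)
    with pytest.raises(ValueError):
        a.sample_cohort(5, (5.0, 95.0), aging_trajectory, seed=1)


def test_cohort_mean_fraction_matches_monte_carlo(aging_trajectory):
    """Sampled fractions agree with a brute-force Monte-Carlo average."""
    n = 60
    manifest = a.sample_cohort(n, (5.0, 85.0), aging_trajectory, seed=1)
    sample_mean = np.mean([s.true_brain_fraction for s in manifest])

    rng = np.random.default_rng(123456)
    ages = rng.uniform(5.0, 85.0, 1_000_000)
    draws = aging_trajectory(ages) + rng.normal(
        0.0, aging_trajectory.subject_sd, ages.size
    )
    mc_mean, mc_sd = draws.mean(), draws.std()
    assert abs(sample_mean - mc_mean) < 3 * mc_sd / np.sqrt(n)


def test_noise_free_signal_model_is_exactly_invertible(subject_70):
    """ln(b0/dw)/b recovers the assigned ADC; includes exp(-0.75) check."""
    sub, _, _ = subject_70
    cfg = a.PhantomConfig(grid_shape=(64, 64, 12), noise_sigma=0.0)
    pair, truth = a.synthesize_with_truth(sub, cfg)
    head = truth["head"]
    recovered = np.log(pair.b0[head] / pair.dw[head]) / cfg.b_value
    assert np.max(np.abs(recovered - truth["adc"][head])) <= 1e-12
    # ratio for a pure tissue voxel at the compartment-mean ADC
    ratios = pair.dw[truth["tissue"]] / pair.b0[truth["tissue"]]
    expected = np.exp(-cfg.b_value * truth["adc"][truth["tissue"]])
    assert np.allclose(ratios, expected, rtol=1e-12)


def test_pure_tissue_share_matches_requested_fraction(subject_70):
    _, _, truth = subject_70
    share = truth["tissue"].sum() / truth["head"].sum()
    assert 0.695 <= share <= 0.705


def test_fast_mode_tissue_share_matches_requested_fraction():
    sub = a.SubjectGroundTruth("f70", 40.0, "male", 70.0, seed=5)
    _, truth = a.synthesize_with_truth(sub, a.PhantomConfig(), fast=True)
    share = truth["tissue"].sum() / truth["head"].sum()
    assert 0.695 <= share <= 0.705
    assert truth["head"].sum() == round(FAST_HEAD_SHARE * 60_000)


def test_volumes_are_bit_identical_across_calls(small_config):
    sub = a.SubjectGroundTruth("det", 30.0, "male", 75.0, seed=99)
    p1 = a.synthesize_volumes(sub, small_config)
    p2 = a.synthesize_volumes(sub, small_config)
    assert np.array_equal(p1.b0, p2.b0) and np.array_equal(p1.dw, p2.dw)


def test_phantom_config_validation():
    with pytest.raises(ValueError):
        a.PhantomConfig(noise_sigma=-1.0)
    with pytest.raises(ValueError):
        a.PhantomConfig(csf_adc_mean=0.5e-3)  # below tissue ADC
    with pytest.raises(ValueError):
        a.PhantomConfig(s0_csf=100.0)  # not brighter than tissue
    with pytest.raises(ValueError):
        a.PhantomConfig(grid_shape=(0, 10, 10))


def test_generator_analyzer_consistency_without_partial_volume():
    """Zero noise + no shell: pipeline fraction equals the label count."""
    cfg = a.PhantomConfig(grid_shape=(64, 64, 12), noise_sigma=0.0,
                          partial_volume_shell=0)
    sub = a.SubjectGroundTruth("cons", 50.0, "female", 72.0, seed=21)
    pair, truth = a.synthesize_with_truth(sub, cfg)
    res = a.analyze_cohort(
        [({"subject_id": "cons", "age": 50.0, "sex": "female"}, pair)],
        fit=False,
    )
    true_share = 100.0 * truth["tissue"].sum() / truth["head"].sum()
    assert res.subject_results[0].brain_fraction == pytest.approx(
        true_share, abs=0.5
    )


def test_lower_tissue_fraction_lowers_measured_fraction(small_config):
    """Monotonicity of the downstream statistic in the generated truth."""
    cfg = a.PhantomConfig(grid_shape=(64, 64, 12), noise_sigma=0.0)
    measured = []
    for frac in (55.0, 70.0, 85.0):
        sub = a.SubjectGroundTruth(f"m{frac}", 40.0, "male", frac, seed=31)
        pair = a.synthesize_volumes(sub, cfg)
        res = a.analyze_cohort(
            [({"subject_id": sub.subject_id, "age": 40.0, "sex": "male"},
              pair)],
            fit=False,
        )
        measured.append(res.subject_results[0].brain_fraction)
    assert measured[0] < measured[1] < measured[2]


def test_manifest_roundtrip(tmp_path, aging_trajectory):
    manifest = a.sample_cohort(5, (10.0, 80.0), aging_trajectory, seed=4)
    for s in manifest:
        s.b0_path, s.dw_path = f"{s.subject_id}_b0.nii", f"{s.subject_id}_dw.nii"
    path = tmp_path / "manifest.csv"
    manifest.to_csv(path)
    loaded = a.CohortManifest.from_csv(path)
    assert loaded.to_frame().equals(manifest.to_frame())
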