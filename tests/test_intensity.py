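"""Window features, normalization, fusion, level mapping and controller."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

from splashquant.detection import Box, Detection
from splashquant.intensity import (ControllerConfig, DetectionFrame,
                                   FusionWeights, LevelThresholds,
                                   NormalizedFeatures, calibrate_weights,
                                   cohen_kappa, compute_window_features,
                                   detrend, feeding_controller, fuse_score,
                                   map_levels, minmax_normalize,
                                   normalize_features, texture_energy)


def _det(x1, y1, x2, y2, score=0.9):
    return Detection(Box(x1, y1, x2, y2), score)


# ---------------------------------------------------------------------------
# window features
# ---------------------------------------------------------------------------

def test_count_and_mean_area():
    dets = [_det(0, 0, 10, a / 10) for a in (100, 200, 300, 400, 500)]
    frames = [DetectionFrame(0.0, dets)]
    w = compute_window_features(frames, 1.0)[0]
    assert (w.f, w.area) == (5, 300.0)


def test_empty_window_is_all_zero():
    frames = [DetectionFrame(0.0, []), DetectionFrame(1.0, [])]
    ws = compute_window_features(frames, 1.0)
    assert all((w.f, w.area, w.energy) == (0, 0.0, 0.0) for w in ws)


def test_unsorted_timestamps_rejected():
    frames = [DetectionFrame(1.0, []), DetectionFrame(0.5, [])]
    with pytest.raises(ValueError):
        compute_window_features(frames)


def test_poisson_rate_recovery():
    rng = np.random.default_rng(0)
    lam = 6.0
    frames = [
        DetectionFrame(float(t), [_det(0, 0, 5, 5)] * int(rng.poisson(lam)))
        for t in range(500)
    ]
    ws = compute_window_features(frames, 1.0)
    mean_f = np.mean([w.f for w in ws])
    se = np.sqrt(lam / 500)
    assert abs(mean_f - lam) < 3 * se


# ---------------------------------------------------------------------------
# texture energy
# ---------------------------------------------------------------------------

def test_texture_energy_constant_region_zero():
    img = np.full((32, 32), 7.0)
    assert texture_energy(img, [Box(4, 4, 20, 20)]) == 0.0


def test_texture_energy_step_edge_matches_convolution_oracle():
    img = np.zeros((20, 20))
    img[:, 10:] = 1.0  # vertical unit step
    box = Box(4, 4, 16, 16)
    got = texture_energy(img, [box])
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
    gx = ndimage.correlate(img, kx, mode="reflect")
    gy = ndimage.correlate(img, kx.T, mode="reflect")
    mask = np.zeros_like(img, bool)
    mask[4:16, 4:16] = True
    assert got == pytest.approx(((gx ** 2 + gy ** 2)[mask]).mean())
    assert got > 0


def test_texture_energy_union_semantics_no_double_count(rng):
    img = rng.uniform(0, 1, (40, 40))
    overlapping = [Box(5, 5, 25, 25), Box(15, 15, 35, 35)]
    explicit_union = [Box(5, 5, 25, 25), Box(15, 15, 35, 35),
                      Box(15, 15, 25, 25)]  # duplicates the overlap region
    assert texture_energy(img, overlapping) == pytest.approx(
        texture_energy(img, explicit_union))


def test_texture_energy_out_of_bounds_box_rejected():
    with pytest.raises(ValueError):
        texture_energy(np.zeros((10, 10)), [Box(5, 5, 20, 20)])


def test_texture_energy_empty_boxes_zero():
    assert texture_energy(np.ones((8, 8)), []) == 0.0


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_detrend_removes_linear_ramp_and_constant():
    np.testing.assert_allclose(detrend(np.arange(10.0)), 0, atol=1e-10)
    np.testing.assert_allclose(detrend(np.full(10, 3.0)), 0, atol=1e-10)


def test_detrend_ramp_plus_sinusoid_closed_form():
    t = np.arange(100.0)
    sin = np.sin(2 * np.pi * t / 25)
    series = 0.3 * t + 2.0 + sin
    # normal-equations fit of the sinusoid's own linear component
    x = np.vstack([t, np.ones_like(t)]).T
    coef = np.linalg.solve(x.T @ x, x.T @ sin)
    expect = sin - x @ coef
    np.testing.assert_allclose(detrend(series), expect, atol=1e-8)


def test_detrend_too_short_rejected():
    with pytest.raises(ValueError):
        detrend([1.0])


def test_minmax_examples():
    np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])
    np.testing.assert_allclose(minmax_normalize([5, 5, 5]), [0, 0, 0])


@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
def test_minmax_range_property(xs):
    out = minmax_normalize(xs)
    if np.ptp(xs) > 0:
        assert out.min() == 0 and out.max() == pytest.approx(1)
    assert np.all((out >= 0) & (out <= 1))


def test_fusion_affine_invariance(rng):
    """A common affine rescale before min-max normalization is absorbed."""
    f = rng.uniform(0, 10, 50)
    nf1 = minmax_normalize(f)
    nf2 = minmax_normalize(3.5 * f + 20)
    np.testing.assert_allclose(nf1, nf2, atol=1e-12)


# ---------------------------------------------------------------------------
# fusion and calibration
# ---------------------------------------------------------------------------

def test_fuse_score_examples():
    nf = NormalizedFeatures(np.array([1.0]), np.array([1.0]), np.array([1.0]))
    assert fuse_score(nf, FusionWeights(1 / 3, 1 / 3, 1 / 3))[0] == pytest.approx(1.0)
    nf2 = NormalizedFeatures(np.array([1.0]), np.array([0.0]), np.array([0.0]))
    assert fuse_score(nf2, FusionWeights(0.5, 0.3, 0.2))[0] == pytest.approx(0.5)


def test_fuse_weights_validated():
    with pytest.raises(ValueError):
        FusionWeights(0.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        FusionWeights(-0.1, 0.6, 0.5)


def test_fuse_score_monotone_in_each_feature(rng):
    w = FusionWeights(0.4, 0.35, 0.25)
    base = NormalizedFeatures(rng.uniform(0, 1, 20), rng.uniform(0, 1, 20),
                              rng.uniform(0, 1, 20))
    s0 = fuse_score(base, w)
    for attr in ("f", "area", "energy"):
        bumped = NormalizedFeatures(base.f.copy(), base.area.copy(),
                                    base.energy.copy())
        setattr(bumped, attr, np.minimum(getattr(base, attr) + 0.1, 1.0))
        assert np.all(fuse_score(bumped, w) >= s0 - 1e-12)


def test_calibration_recovers_planted_weights(rng):
    nf = NormalizedFeatures(rng.uniform(0, 1, 600), rng.uniform(0, 1, 600),
                            rng.uniform(0, 1, 600))
    s_true = fuse_score(nf, FusionWeights(0.5, 0.3, 0.2))
    cuts = [np.quantile(s_true, q) for q in (0.3, 0.6, 0.85)]
    labels = map_levels(s_true, LevelThresholds(*cuts), as_indices=True)
    w, th = calibrate_weights(nf, labels, objective="kappa", grid_step=0.05)
    assert abs(w.alpha - 0.5) <= 0.05 + 1e-9
    assert abs(w.beta - 0.3) <= 0.05 + 1e-9
    assert abs(w.gamma - 0.2) <= 0.05 + 1e-9
    assert th.t0 < th.t1 < th.t2


def test_calibration_degenerate_single_driver(rng):
    nf = NormalizedFeatures(rng.uniform(0, 1, 400), rng.uniform(0, 1, 400),
                            rng.uniform(0, 1, 400))
    labels = (nf.f > 0.5).astype(int)  # determined solely by f
    w, _ = calibrate_weights(nf, labels, objective="spearman", grid_step=0.05)
    assert w.alpha >= 0.95 - 1e-9


def test_calibration_is_exhaustive_argmax(rng):
    from scipy import stats

    nf = NormalizedFeatures(rng.uniform(0, 1, 200), rng.uniform(0, 1, 200),
                            rng.uniform(0, 1, 200))
    labels = (nf.f + nf.area > 1.0).astype(int)
    w, _ = calibrate_weights(nf, labels, objective="spearman", grid_step=0.25)
    best = stats.spearmanr(fuse_score(nf, w), labels).statistic
    n = 4
    for i in range(n + 1):
        for j in range(n + 1 - i):
            cand = FusionWeights(i / n, j / n, (n - i - j) / n)
            obj = stats.spearmanr(fuse_score(nf, cand), labels).statistic
            assert best >= obj - 1e-12


def test_calibration_single_label_rejected(rng):
    nf = NormalizedFeatures(rng.uniform(0, 1, 30), rng.uniform(0, 1, 30),
                            rng.uniform(0, 1, 30))
    with pytest.raises(ValueError):
        calibrate_weights(nf, np.zeros(30, int))


def test_cohen_kappa_agrees_with_sklearn(rng):
    from sklearn.metrics import cohen_kappa_score

    a = rng.integers(0, 4, 200)
    b = np.where(rng.uniform(size=200) < 0.7, a, rng.integers(0, 4, 200))
    assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))


# ---------------------------------------------------------------------------
# level mapping
# ---------------------------------------------------------------------------

def test_map_levels_bins():
    th = LevelThresholds(0.2, 0.5, 0.8)
    assert map_levels([0.1, 0.3, 0.6, 0.9], th) == [
        "none", "weak", "moderate", "strong"]


def test_dwell_suppresses_single_window_flip():
    th = LevelThresholds(0.2, 0.5, 0.8, dwell=3)
    s = [0.3] * 5 + [0.9] + [0.3] * 5
    assert "strong" not in map_levels(s, th)


def test_zero_dwell_equals_instantaneous(rng):
    th0 = LevelThresholds(0.2, 0.5, 0.8, dwell=0)
    s = rng.uniform(0, 1, 100)
    inst = np.digitize(s, [0.2, 0.5, 0.8])
    np.testing.assert_array_equal(map_levels(s, th0, as_indices=True), inst)


@pytest.mark.parametrize("tau", [1, 3, 5])
def test_no_emitted_run_shorter_than_dwell(rng, tau):
    th = LevelThresholds(0.25, 0.5, 0.75, dwell=tau)
    s = rng.uniform(0, 1, 300)
    out = map_levels(s, th, as_indices=True)
    runs = np.diff(np.flatnonzero(np.r_[1, np.diff(out) != 0, 1]))
    assert all(r >= tau for r in runs[:-1])


def test_threshold_ordering_enforced():
    with pytest.raises(ValueError):
        LevelThresholds(0.5, 0.5, 0.8)


# ---------------------------------------------------------------------------
# controller
# ---------------------------------------------------------------------------

CC = ControllerConfig(s_star=0.2, tau_stop=3, s_recover=0.25, eta=0.5)


def test_controller_pause_then_stop_on_flat_zero():
    states, events = feeding_controller(np.zeros(12), CC)
    assert states[3] == "PAUSED"          # first window after 3 sub-threshold
    assert states[:3] == ["FEEDING"] * 3
    assert "STOPPED" in states
    assert [e["event"] for e in events] == ["pause", "stop"]
    # stopped is absorbing
    assert all(s == "STOPPED" for s in states[states.index("STOPPED"):])


def test_controller_resume_on_rebound():
    s = np.r_[np.full(4, 0.5), np.zeros(4), [0.4], np.full(4, 0.5)]
    states, events = feeding_controller(s, CC)
    assert [e["event"] for e in events] == ["pause", "resume"]
    assert "RESUMED" in states and "STOPPED" not in states


def test_controller_hysteresis_band_never_resumes():
    """Oscillation inside (S*, S_re) after a pause must not resume."""
    s = np.r_[np.full(4, 0.5), np.zeros(4), [0.22, 0.21, 0.23, 0.24, 0.22]]
    states, events = feeding_controller(s, CC)
    assert "RESUMED" not in states
    assert [e["event"] for e in events] == ["pause", "stop"]


def test_controller_single_outcome_per_pause(rng):
    s = rng.uniform(0, 1, 500)
    states, events = feeding_controller(s, ControllerConfig(0.4, 2, 0.45, 0.6))
    kinds = [e["event"] for e in events]
    # between consecutive pauses there is exactly one resume-or-stop
    pauses = [i for i, k in enumerate(kinds) if k == "pause"]
    for n, (a, b) in enumerate(zip(pauses, pauses[1:] + [len(kinds)])):
        between = kinds[a + 1:b]
        assert all(k in ("resume", "stop") for k in between)
        if b < len(kinds) or n < len(pauses) - 1:
            assert len(between) == 1
        else:  # final episode may be truncated by session end
            assert len(between) <= 1


def test_controller_config_validation():
    with pytest.raises(ValueError):
        ControllerConfig(s_star=0.3, tau_stop=3, s_recover=0.2, eta=0.5)
    with pytest.raises(ValueError):
        ControllerConfig(s_star=0.1, tau_stop=0, s_recover=0.2, eta=0.5)
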