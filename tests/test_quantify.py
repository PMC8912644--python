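"""Quantification: decay correction, region growing, TACs, fractions."""

import dataclasses
from collections import deque

import numpy as np
import pytest
from scipy.integrate import quad

import rhizopet as rp
from rhizopet import acquisition, quantify
from rhizopet.acquisition import LOWER, UPPER
from rhizopet.kinetics import StructureKinetics
from rhizopet.quantify import QuantifyError

from conftest import single_voxel_phantom

LAM = rp.LAMBDA_C11


# ---------------------------------------------------------------------------
# decay correction


def test_point_correction_doubles_after_one_half_life():
    assert rp.decay_correct(100.0, 20.4, lam=LAM) == pytest.approx(200.0, rel=1e-12)


def test_point_correction_identity_at_time_zero():
    assert rp.decay_correct(123.4, 0.0, lam=LAM) == 123.4


def test_frame_correction_matches_quadrature_oracle():
    # frame factor = dt / int_a^b e^{-lam t} dt
    for a, b in [(0.0, 5.0), (70.0, 75.0), (100.0, 105.0)]:
        integral, _ = quad(lambda t: np.exp(-LAM * t), a, b)
        oracle = (b - a) / integral
        got = rp.decay_correct(1.0, a, b, lam=LAM)
        assert got == pytest.approx(oracle, abs=1e-9)


def test_decay_correct_rejects_bad_lambda():
    with pytest.raises(QuantifyError):
        rp.decay_correct(1.0, 0.0, 5.0, lam=0.0)


# ---------------------------------------------------------------------------
# region growing


def flood_fill_oracle(volume, seed, rel_threshold):
    """Exhaustive BFS flood fill, 26-connectivity, same threshold rule."""
    lo = tuple(max(i - 1, 0) for i in seed)
    hi = tuple(min(i + 2, n) for i, n in zip(seed, volume.shape))
    thr = rel_threshold * volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].max()
    mask = np.zeros(volume.shape, dtype=bool)
    if volume[seed] < thr:
        mask[seed] = True
        return mask
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    queue = deque([seed])
    mask[seed] = True
    while queue:
        p = queue.popleft()
        for o in offsets:
            q = tuple(p[i] + o[i] for i in range(3))
            if any(x < 0 or x >= n for x, n in zip(q, volume.shape)):
                continue
            if not mask[q] and volume[q] >= thr:
                mask[q] = True
                queue.append(q)
    return mask


def test_region_grow_isolated_voxel():
    vol = np.zeros((5, 5, 5))
    vol[2, 2, 2] = 10.0
    mask = rp.region_grow(vol, (2, 2, 2), 0.5)
    assert mask.sum() == 1 and mask[2, 2, 2]


def test_region_grow_uniform_plateau_fills_everything():
    vol = np.ones((4, 4, 4))
    mask = rp.region_grow(vol, (0, 0, 0), 0.5)
    assert mask.all()


def test_region_grow_two_blobs_takes_only_seeded_one():
    vol = np.zeros((7, 7, 7))
    vol[1:3, 1:3, 1:3] = 1.0
    vol[4:6, 4:6, 4:6] = 1.0
    mask = rp.region_grow(vol, (1, 1, 1), 0.5)
    assert np.array_equal(mask, flood_fill_oracle(vol, (1, 1, 1), 0.5))
    assert mask[1, 1, 1] and not mask[5, 5, 5]


def test_region_grow_seed_below_threshold_returns_single_voxel():
    vol = np.zeros((5, 5, 5))
    vol[2, 2, 2] = 0.1
    vol[2, 2, 3] = 10.0  # neighborhood max dominates
    with pytest.warns(UserWarning, match="below"):
        mask = rp.region_grow(vol, (2, 2, 2), 0.5)
    assert mask.sum() == 1 and mask[2, 2, 2]


@pytest.mark.parametrize("shape,n_cases", [((3, 3, 3), 200), ((8, 8, 8), 60)])
def test_region_grow_matches_flood_fill_oracle(shape, n_cases):
    rng = np.random.default_rng(2024)
    for case in range(n_cases):
        vol = rng.random(shape) if case % 2 else (rng.random(shape) > 0.4).astype(float)
        seed = tuple(rng.integers(0, s) for s in shape)
        thr = float(rng.uniform(0.2, 0.9))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = rp.region_grow(vol, seed, thr)
        oracle = flood_fill_oracle(vol, seed, thr)
        assert np.array_equal(got, oracle), f"case {case}, seed {seed}, thr {thr}"


# ---------------------------------------------------------------------------
# TAC extraction


def make_noise_free_session(ph, model, cfg):
    cfg = dataclasses.replace(cfg, noise=False, psf_fwhm_mm=0.0)
    return acquisition.simulate_session(ph, model, 1, cfg), cfg


def test_extract_tac_has_11_points_for_default_schedule():
    ph = single_voxel_phantom()
    model = rp.KineticModel(
        structures={1: StructureKinetics(weight=1.0, k=0.06, d=0.0, kind=rp.NODULE)},
        session_scales=np.array([1000.0]),
    )
    cfg = rp.AcquisitionConfig(window_voxels=10, offset_voxels=0, noise=False, psf_fwhm_mm=0.0)
    frames = acquisition.simulate_session(ph, model, 1, cfg)
    mask = np.zeros((5, 5, 10), dtype=bool)
    mask[2, 2, 2] = True
    roi = quantify.ROI("nodule_1", (2, 2, 2), LOWER, mask, rp.NODULE)
    tac = rp.extract_tac(frames, roi, LAM)
    assert len(tac) == 11
    assert np.all(np.diff(tac.t_mid) > 0)


def test_extract_tac_matches_kinetics_closed_form():
    ph = single_voxel_phantom()
    model = rp.KineticModel(
        structures={1: StructureKinetics(weight=1.0, k=0.08, d=1.5, kind=rp.NODULE)},
        session_scales=np.array([500.0]),
    )
    cfg = rp.AcquisitionConfig(window_voxels=10, offset_voxels=0, noise=False, psf_fwhm_mm=0.0)
    frames = acquisition.simulate_session(ph, model, 1, cfg)
    mask = np.ones((5, 5, 10), dtype=bool)
    roi = quantify.ROI("whole", (2, 2, 2), LOWER, mask, quantify.WHOLE_ROOT)
    tac = rp.extract_tac(frames, roi, LAM)
    for ts, value in zip(tac.t_start, tac.value):
        integral = model.activity_integral(1, ts, ts + 5.0, 1)
        expected = rp.decay_correct(cfg.count_scale * integral, ts, ts + 5.0, lam=LAM)
        assert value == pytest.approx(expected, rel=1e-6)


def test_extract_tac_zero_frames_gives_zero_curve(small_phantom, small_acq_cfg):
    specs = rp.make_schedule(small_acq_cfg)
    zero = acquisition.FrameSeries(
        volumes=[np.zeros((25, 25, 35)) for _ in specs], specs=specs
    )
    mask = np.ones((25, 25, 35), dtype=bool)
    roi = quantify.ROI("whole", (0, 0, 0), LOWER, mask, quantify.WHOLE_ROOT)
    tac = rp.extract_tac(zero, roi, LAM)
    assert np.all(tac.value == 0)


# ---------------------------------------------------------------------------
# interpolation


def test_quadratic_interpolation_is_exact_on_quadratics():
    t = np.arange(5.0, 110.0, 10.0)
    curve = quantify.TimeActivityCurve("total", LOWER, t - 2.5, t, t**2)
    assert rp.interp_total(curve, 10.0) == pytest.approx(100.0, abs=1e-9)
    q = np.array([7.3, 33.0, 104.9])
    assert rp.interp_total(curve, q) == pytest.approx(q**2, rel=1e-12)


def test_interpolation_constant_series():
    t = np.arange(5.0, 60.0, 10.0)
    curve = quantify.TimeActivityCurve("total", LOWER, t - 2.5, t, np.full_like(t, 3.3))
    assert rp.interp_total(curve, 23.7) == pytest.approx(3.3, rel=1e-12)


def test_interpolation_matches_local_polynomial_oracle():
    t = np.arange(5.0, 110.0, 10.0)
    y = np.sin(t / 20.0)
    curve = quantify.TimeActivityCurve("total", LOWER, t - 2.5, t, y)
    for q in [10.0, 42.0, 77.7, 2.0, 108.0]:
        j = int(np.argmin(np.abs(t - q)))
        j0 = min(max(j - 1, 0), len(t) - 3)
        coef = np.polyfit(t[j0:j0 + 3], y[j0:j0 + 3], 2)  # oracle fit
        assert rp.interp_total(curve, q) == pytest.approx(np.polyval(coef, q), abs=1e-12)


def test_interpolation_needs_three_points():
    t = np.array([5.0, 15.0])
    curve = quantify.TimeActivityCurve("total", LOWER, t - 2.5, t, t)
    with pytest.raises(QuantifyError):
        rp.interp_total(curve, 10.0)


# ---------------------------------------------------------------------------
# fractions


def test_whole_root_fraction_is_one_when_other_total_is_zero():
    t = np.arange(2.5, 110.0, 10.0)
    total = quantify.TimeActivityCurve("whole_root_lower", LOWER, t - 2.5, t, 100 + t)
    fc = rp.fraction_curve(total, total, None)
    assert np.allclose(fc.fraction, 1.0)


def test_fractions_invariant_under_count_scaling():
    t = np.arange(2.5, 110.0, 10.0)
    roi = quantify.TimeActivityCurve("nodule_1", LOWER, t - 2.5, t, 5 + 0.01 * t)
    tot = quantify.TimeActivityCurve("whole_root_lower", LOWER, t - 2.5, t, 100 + t)
    oth = quantify.TimeActivityCurve("whole_root_upper", UPPER, t - 2.5 + 5, t + 5, 50 + t)
    a = rp.fraction_curve(roi, tot, oth)
    scale = lambda c, f: quantify.TimeActivityCurve(c.roi_id, c.position, c.t_start, c.t_mid, c.value * f)
    b = rp.fraction_curve(scale(roi, 10), scale(tot, 10), scale(oth, 10))
    assert np.allclose(a.fraction, b.fraction, rtol=1e-12)


def test_fractions_do_not_require_decay_correction():
    # corrected and uncorrected counts give identical fractions (1e-12)
    # for the same-position component
    t_start = np.arange(0.0, 110.0, 10.0)
    t_mid = t_start + 2.5
    raw_roi = 5.0 + 0.1 * t_mid
    raw_tot = 120.0 + t_mid
    factor = np.array([rp.decay_correct(1.0, a, a + 5.0, lam=LAM) for a in t_start])
    mk = lambda rid, v: quantify.TimeActivityCurve(rid, LOWER, t_start, t_mid, v)
    f_raw = rp.fraction_curve(mk("nodule_1", raw_roi), mk("whole_root_lower", raw_tot), None)
    f_cor = rp.fraction_curve(mk("nodule_1", raw_roi * factor), mk("whole_root_lower", raw_tot * factor), None)
    assert np.allclose(f_raw.fraction, f_cor.fraction, rtol=0, atol=1e-12)


def test_fraction_curve_rejects_nonpositive_total():
    t = np.arange(2.5, 30.0, 10.0)
    roi = quantify.TimeActivityCurve("nodule_1", LOWER, t - 2.5, t, np.ones_like(t))
    tot = quantify.TimeActivityCurve("whole_root_lower", LOWER, t - 2.5, t, np.zeros_like(t))
    with pytest.raises(QuantifyError):
        rp.fraction_curve(roi, tot, None)


def test_noise_free_nodule_fraction_recovers_allocation_share(small_phantom, small_acq_cfg):
    # uniform kinetics, no noise/blur: fraction(t) = w_i exactly (weights
    # sum to 1 over the belowground volume)
    model = rp.build_kinetics(
        small_phantom, rp.KineticsConfig(k_jitter=0.0, d_jitter=0.0, nodule_k=0.06, root_k=0.06), seed=7
    )
    frames, cfg = make_noise_free_session(small_phantom, model, small_acq_cfg)
    totals_rois = quantify.whole_root_rois(small_phantom, cfg)
    totals = {p: rp.extract_tac(frames, totals_rois[p], LAM) for p in (LOWER, UPPER)}
    for s in small_phantom.nodules:
        position = quantify.nodule_position(small_phantom, s.id, cfg)
        z_lo, _ = acquisition.window_bounds(cfg, position)
        vox = small_phantom.voxel_indices(s.id)
        mask = np.zeros((25, 25, 35), dtype=bool)
        mask[vox[:, 0], vox[:, 1], vox[:, 2] - z_lo] = True
        seed_vox = tuple(vox[0]) if vox[0, 2] < 35 and position == LOWER else tuple(vox[0] - [0, 0, z_lo])
        roi = quantify.ROI(f"nodule_{s.id}", tuple(np.array(vox[0]) - [0, 0, z_lo]), position, mask, rp.NODULE)
        tac = rp.extract_tac(frames, roi, LAM)
        other = UPPER if position == LOWER else LOWER
        fc = rp.fraction_curve(tac, totals[position], totals[other])
        late = fc.fraction[-4:]
        assert np.all(np.abs(late / s.allocation_weight - 1.0) < 0.01)


def test_disjoint_nodule_fractions_sum_below_one(small_phantom, small_model, small_acq_cfg, small_session):
    rois = quantify.nodule_rois_from_truth(small_phantom, small_session, small_acq_cfg)
    totals_rois = quantify.whole_root_rois(small_phantom, small_acq_cfg)
    totals = {p: rp.extract_tac(small_session, totals_rois[p], LAM) for p in (LOWER, UPPER)}
    by_position = {}
    for roi in rois:
        tac = rp.extract_tac(small_session, roi, LAM)
        other = UPPER if roi.position == LOWER else LOWER
        fc = rp.fraction_curve(tac, totals[roi.position], totals[other])
        assert np.all(fc.fraction <= 1.0)
        by_position.setdefault(roi.position, []).append(fc.fraction)
    for fracs in by_position.values():
        assert np.all(np.sum(fracs, axis=0) <= 1.0)


def test_parameter_recovery_within_5pct_with_default_noise():
    # full-size phantom, default noise: each nodule's windowed mean
    # fraction lands within 5% relative of its allocation share
    ph = rp.build_phantom(seed=1)
    model = rp.build_kinetics(ph, seed=1)
    cfg = dataclasses.replace(rp.AcquisitionConfig(), seed=1)
    frames = acquisition.simulate_session(ph, model, 1, cfg)
    rois = quantify.nodule_rois_from_truth(ph, frames, cfg)
    assert len(rois) == 6
    totals_rois = quantify.whole_root_rois(ph, cfg)
    totals = {p: rp.extract_tac(frames, totals_rois[p], LAM) for p in (LOWER, UPPER)}
    truth = {f"nodule_{s.id}": s.allocation_weight for s in ph.nodules}
    for roi in rois:
        tac = rp.extract_tac(frames, roi, LAM)
        other = UPPER if roi.position == LOWER else LOWER
        fc = rp.fraction_curve(tac, totals[roi.position], totals[other])
        mean, _sd = rp.mean_fraction(fc, quantify.run_window(fc, 7, 4))
        assert abs(mean / truth[roi.id] - 1.0) < 0.05


# ---------------------------------------------------------------------------
# windows


def test_mean_fraction_constant_curve():
    t = np.arange(0.0, 110.0, 10.0)
    fc = quantify.FractionCurve("nodule_1", LOWER, t, t + 2.5, np.full_like(t, 0.05))
    mean, sd = rp.mean_fraction(fc, (70.0, 100.0))
    assert (mean, sd) == (pytest.approx(0.05), 0.0)


def test_mean_fraction_hand_computation():
    t = np.array([70.0, 80.0, 90.0, 100.0])
    fc = quantify.FractionCurve("nodule_1", LOWER, t, t + 2.5, np.array([0.08, 0.09, 0.07, 0.08]))
    mean, sd = rp.mean_fraction(fc, (70.0, 100.0))
    assert mean == pytest.approx(0.080)
    assert sd == pytest.approx(np.sqrt(2e-4 / 3))  # sample sd, hand formula


def test_default_window_holds_exactly_four_points_per_position():
    for start in (0.0, 5.0):  # lower / upper frame starts
        t = np.arange(start, 110.0, 10.0)
        fc = quantify.FractionCurve("x", LOWER, t, t + 2.5, np.linspace(0.01, 0.02, len(t)))
        idx = quantify.default_window_index(len(fc), 4)
        lo, hi = quantify.run_window(fc, idx, 4)
        assert np.sum((t >= lo) & (t <= hi)) == 4
    assert (lo, hi) == (75.0, 105.0)  # upper position: the 75-105 min window


def test_mean_fraction_empty_window_raises():
    t = np.arange(0.0, 50.0, 10.0)
    fc = quantify.FractionCurve("x", LOWER, t, t + 2.5, np.full_like(t, 0.1))
    with pytest.raises(QuantifyError):
        rp.mean_fraction(fc, (200.0, 300.0))


def select_window_oracle(curves, width):
    """Exhaustive search over all runs; ties to the latest."""
    n = min(len(c) for c in curves)
    best, best_score = None, None
    for i in range(n - width + 1):
        score = sum(
            np.std(c.fraction[i:i + width], ddof=1) / np.mean(c.fraction[i:i + width])
            for c in curves
        )
        if best_score is None or score <= best_score:
            best, best_score = i, score
    return best


def test_select_window_prefers_quiet_late_run():
    t = np.arange(0.0, 110.0, 10.0)
    vals = np.full_like(t, 0.08)
    vals[:3] = [0.2, 0.02, 0.15]  # noisy early segment
    fc = quantify.FractionCurve("x", LOWER, t, t + 2.5, vals)
    assert rp.select_window([fc], 4) >= 3


def test_select_window_all_constant_ties_to_latest():
    t = np.arange(0.0, 110.0, 10.0)
    fc = quantify.FractionCurve("x", LOWER, t, t + 2.5, np.full_like(t, 0.08))
    assert rp.select_window([fc], 4) == len(t) - 4


def test_select_window_matches_exhaustive_oracle():
    rng = np.random.default_rng(99)
    t = np.arange(0.0, 110.0, 10.0)
    curves = [
        quantify.FractionCurve(f"c{i}", LOWER, t, t + 2.5, 0.05 + 0.02 * rng.random(len(t)))
        for i in range(3)
    ]
    assert rp.select_window(curves, 4) == select_window_oracle(curves, 4)
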