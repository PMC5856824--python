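"""Nesting statistic, surrogates, group comparison, and comodulogram."""

import numpy as np
import pytest
from scipy import stats

from tcd.cfc import (
    CouplingResult,
    comodulogram,
    first_pc,
    group_compare_cfc,
    pac_nesting,
    surrogate_threshold,
)
from tcd.rois import ROI_BY_NAME
from tcd.synth import GeneratorParams, RoiTimeSeries, generate_subject

FS = 128.0


def _roi(comps):
    return RoiTimeSeries(ROI_BY_NAME["AUD_L"], np.asarray(comps), FS)


def test_first_pc_single_active_component():
    rng = np.random.default_rng(0)
    s = rng.standard_normal(1000)
    out = first_pc(np.vstack([s, np.zeros(1000), np.zeros(1000)]))
    np.testing.assert_allclose(out, s - s.mean(), atol=1e-10)


def test_first_pc_rank_one_recovery():
    rng = np.random.default_rng(1)
    s = rng.standard_normal(2000)
    comps = np.outer([0.5, -1.2, 0.3], s) + 1e-4 * rng.standard_normal((3, 2000))
    out = first_pc(comps)
    assert abs(np.corrcoef(out, s)[0, 1]) > 0.999


def test_first_pc_rotation_invariance():
    rng = np.random.default_rng(2)
    comps = np.outer([1.0, 0.4, -0.2], rng.standard_normal(2000))
    comps += 0.01 * rng.standard_normal(comps.shape)
    base = first_pc(comps)
    rot = np.linalg.qr(np.random.default_rng(3).standard_normal((3, 3)))[0]
    rotated = first_pc(rot @ comps)
    r = np.corrcoef(base, rotated)[0, 1]
    assert abs(abs(r) - 1) < 1e-3


def test_first_pc_zero_variance_errors():
    with pytest.raises(ValueError):
        first_pc(np.zeros((3, 100)))


def test_pac_on_coupled_synthetic_roi(params_60s):
    rec = generate_subject("tinnitus", params_60s, 21)
    res = pac_nesting(rec.roi_series["AUD_L"])
    assert res.r_theta_gamma > 0.5
    assert res.r_theta_beta > 0.5


def test_pac_sign_flip_of_all_components(params_60s):
    rec = generate_subject("tinnitus", params_60s, 22)
    ts = rec.roi_series["AUD_L"]
    flipped = RoiTimeSeries(ts.roi, -ts.components, ts.fs)
    a, b = pac_nesting(ts), pac_nesting(flipped)
    assert abs(a.r_theta_gamma) == pytest.approx(abs(b.r_theta_gamma), abs=1e-9)
    assert abs(a.r_theta_beta) == pytest.approx(abs(b.r_theta_beta), abs=1e-9)


def test_uncoupled_roi_within_surrogate_band():
    p = GeneratorParams(duration_s=60.0, modulation_depth=0.0)
    rec = generate_subject("tinnitus", p, 23)
    ts = rec.roi_series["AUD_L"]
    res = pac_nesting(ts)
    q = surrogate_threshold(ts, n_surr=200, seed=0)
    assert abs(res.r_theta_gamma) < q["q95_gamma"] * 1.5 + 0.05
    assert abs(res.r_theta_gamma) < 0.1


def test_surrogate_threshold_deterministic_and_small_on_noise():
    rng = np.random.default_rng(5)
    ts = _roi(rng.standard_normal((3, int(60 * FS))))
    q1 = surrogate_threshold(ts, n_surr=100, seed=7)
    q2 = surrogate_threshold(ts, n_surr=100, seed=7)
    assert q1 == q2
    assert q1["q95_beta"] < 0.1 and q1["q95_gamma"] < 0.1


def test_coupled_exceeds_surrogate(params_60s):
    rec = generate_subject("tinnitus", params_60s, 24)
    ts = rec.roi_series["AUD_L"]
    q = surrogate_threshold(ts, n_surr=100, seed=1)
    assert pac_nesting(ts).r_theta_gamma > q["q95_gamma"]


def test_pac_monotone_in_modulation_depth():
    depths = [0.0, 0.2, 0.4, 0.6, 0.8]
    means = []
    for m in depths:
        p = GeneratorParams(duration_s=60.0, modulation_depth=m)
        rs = [
            pac_nesting(generate_subject("tinnitus", p, 500 + i).roi_series["AUD_L"]).r_theta_gamma
            for i in range(8)
        ]
        means.append(np.mean(rs))
    assert all(b > a for a, b in zip(means, means[1:]))


def test_group_compare_identities():
    rng = np.random.default_rng(6)
    results, groups = [], {}
    for g, shift in [("healthy", 0.0), ("tinnitus", 0.5), ("pain", 0.0)]:
        for i in range(10):
            sid = f"{g}_{i}"
            groups[sid] = g
            r = np.clip(shift + 0.05 * rng.standard_normal(), -1, 1)
            results.append(CouplingResult(sid, "AUD_L", r, r))
    out = group_compare_cfc(results, groups, "AUD_L", "theta_gamma")
    assert out["p"] < 0.001
    assert out["pairwise"]["healthy vs tinnitus"] < 0.05
    assert out["pairwise"]["healthy vs pain"] > 0.05  # no true difference
    # two-group case: F == t^2
    two = [r for r in results if groups[r.subject_id] != "pain"]
    out2 = group_compare_cfc(two, groups, "AUD_L", "theta_gamma")
    a = [r.r_theta_gamma for r in two if groups[r.subject_id] == "healthy"]
    b = [r.r_theta_gamma for r in two if groups[r.subject_id] == "tinnitus"]
    t = stats.ttest_ind(a, b).statistic
    assert out2["F"] == pytest.approx(t**2, rel=1e-8)


def test_group_compare_identical_values_zero_F():
    results, groups = [], {}
    for g in ("healthy", "tinnitus"):
        for i in range(3):
            sid = f"{g}_{i}"
            groups[sid] = g
            results.append(CouplingResult(sid, "dACC", 0.3, 0.3))
    out = group_compare_cfc(results, groups, "dACC")
    assert out["F"] == 0.0 and out["p"] == 1.0


def test_comodulogram_symmetric_unit_diagonal():
    rng = np.random.default_rng(8)
    ts = _roi(rng.standard_normal((3, int(60 * FS))))
    com = comodulogram(ts)
    np.testing.assert_allclose(com.matrix, com.matrix.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(com.matrix), 1.0, atol=1e-12)
    assert np.all(np.abs(com.matrix) <= 1 + 1e-12)


def test_comodulogram_shared_slow_envelope():
    rng = np.random.default_rng(9)
    n = int(120 * FS)
    t = np.arange(n) / FS
    slow = 1 + 0.8 * np.convolve(rng.standard_normal(n), np.ones(256) / 256, mode="same")
    sig = slow * (np.sin(2 * np.pi * 6 * t) + np.sin(2 * np.pi * 40 * t))
    comps = np.outer([0.8, 0.5, 0.3], sig) + 0.05 * rng.standard_normal((3, n))
    com = comodulogram(_roi(comps))
    i6 = int(np.where(com.freqs == 6)[0][0])
    i40 = int(np.where(com.freqs == 40)[0][0])
    assert com.matrix[i6, i40] > 0.6


def test_comodulogram_white_noise_off_diagonal_small():
    # frequencies separated by more than the multitaper bandwidth (+-1 Hz at
    # NW=2, 2 s windows): estimator leakage correlates immediate neighbors
    rng = np.random.default_rng(10)
    com = comodulogram(_roi(rng.standard_normal((3, int(60 * FS)))))
    df = np.abs(com.freqs[:, None] - com.freqs[None, :])
    off = com.matrix[df > 2]
    assert np.quantile(np.abs(off), 0.95) < 0.3


def test_comodulogram_time_reversal_invariant(params_60s):
    rec = generate_subject("tinnitus", params_60s, 30)
    ts = rec.roi_series["AUD_L"]
    rev = RoiTimeSeries(ts.roi, ts.components[:, ::-1], ts.fs)
    a = comodulogram(ts).matrix
    b = comodulogram(rev).matrix
    # amplitude statistics are reversal-invariant up to window placement
    assert np.corrcoef(a.ravel(), b.ravel())[0, 1] > 0.98
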