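"""Cardiac phase sorting, vessel ROI, perfusion amplitude and QQ."""

import numpy as np
import pytest

from preful.card_perf import (CardPhases, PerfCycle, compute_qq,
                              fit_monoexponential, fit_piecewise_sinusoid,
                              perf_cycle, perfusion_amplitude,
                              perfusion_weighted_map, select_vessel_roi)
from preful.io import FrameSeries
from preful.resp_vent import ParamMap


def _series(data, dt=0.288):
    return FrameSeries(data=np.asarray(data, dtype=float), dt=dt)


# ---------------------------------------------------------------------------
# perfusion-weighted map
# ---------------------------------------------------------------------------

def test_std_map_constant_and_sinusoid():
    n, dt = 300, 0.05
    t = np.arange(n) * dt
    data = np.zeros((n, 1, 2))
    data[:, 0, 1] = 2.0 * np.sin(2 * np.pi * 1.2 * t)
    m = perfusion_weighted_map(_series(data, dt))
    assert m[0, 0] == 0.0
    assert abs(m[0, 1] - 2.0 / np.sqrt(2)) / (2.0 / np.sqrt(2)) < 0.05
    with pytest.raises(ValueError):
        perfusion_weighted_map(_series(np.zeros((2, 2, 2))))


def test_std_map_vessels_dominate(phantom64):
    _, series, truth = phantom64
    from preful import preprocess
    from preful.registration import apply_fields
    reg = apply_fields(series, truth.fields_true)
    br = preprocess.split_frequencies(reg)
    perf = preprocess.drop_steady_state(br.perf_series)
    m = perfusion_weighted_map(perf)
    assert np.median(m[truth.vessel_mask]) > 3 * np.median(m[truth.parenchyma_mask])


# ---------------------------------------------------------------------------
# vessel ROI selection
# ---------------------------------------------------------------------------

def test_vessel_roi_overlaps_truth(phantom128):
    _, series, truth = phantom128
    from preful import preprocess
    from preful.registration import apply_fields
    reg = apply_fields(series, truth.fields_true)
    br = preprocess.split_frequencies(reg)
    perf = preprocess.drop_steady_state(br.perf_series)
    m = perfusion_weighted_map(perf)
    roi = select_vessel_roi(m, perf, search_mask=truth.lung_mask)
    overlap = (roi & truth.vessel_mask).sum() / roi.sum()
    assert overlap >= 0.8


def test_vessel_roi_pure_noise_errors():
    rng = np.random.default_rng(0)
    data = rng.normal(0, 1e-3, size=(120, 24, 24))
    series = _series(data)
    m = perfusion_weighted_map(series)
    with pytest.raises(ValueError, match="no cardiac signal"):
        select_vessel_roi(m, series)


def test_vessel_roi_prefers_clean_sinusoid():
    n, dt = 150, 0.288
    t = np.arange(n) * dt
    rng = np.random.default_rng(1)
    data = rng.normal(0, 0.01, size=(n, 20, 40))
    clean = np.sin(2 * np.pi * 1.1 * t)
    burst = np.exp(-t / 3.0) * rng.normal(0, 1.2, n)
    for dy in range(3):
        for dx in range(3):
            data[:, 5 + dy, 5 + dx] += clean
            data[:, 5 + dy, 30 + dx] += burst
    series = _series(data, dt)
    roi = select_vessel_roi(perfusion_weighted_map(series), series, size_cap=20)
    ys, xs = np.where(roi)
    assert xs.mean() < 20          # the clean-sinusoid side wins


def test_vessel_roi_deterministic(phantom64):
    _, series, truth = phantom64
    from preful import preprocess
    br = preprocess.split_frequencies(series)
    perf = preprocess.drop_steady_state(br.perf_series)
    m = perfusion_weighted_map(perf)
    r1 = select_vessel_roi(m, perf, size_cap=40, search_mask=truth.lung_mask)
    r2 = select_vessel_roi(m, perf, size_cap=40, search_mask=truth.lung_mask)
    np.testing.assert_array_equal(r1, r2)


# ---------------------------------------------------------------------------
# piecewise sinusoidal regression
# ---------------------------------------------------------------------------

def test_piecewise_fit_recovers_period_and_phase():
    dt, P = 0.05, 0.9
    t = np.arange(int(5 * P / dt)) * dt
    sig = np.cos(2 * np.pi * t / P)
    cp = fit_piecewise_sinusoid(sig, dt)
    assert np.all(np.abs(cp.period_per_beat - P) / P < 0.05)
    assert cp.fit_quality > 0.99
    peak_idx = int(round(P / dt))              # a later signal peak
    assert min(cp.phase[peak_idx], 1 - cp.phase[peak_idx]) < 0.05
    assert abs(cp.heart_rate_bpm - 60 / P) < 2.0


def test_piecewise_fit_tracks_period_drift():
    dt = 0.03
    t = np.arange(0, 12, dt)
    inst_p = 0.8 + 0.2 * t / t[-1]             # 0.8 s -> 1.0 s
    phase = np.cumsum(dt / inst_p)
    sig = np.cos(2 * np.pi * phase)
    cp = fit_piecewise_sinusoid(sig, dt)
    periods = cp.period_per_beat
    assert np.all(np.diff(periods) > -0.02)    # monotone up to sampling jitter


def test_piecewise_fit_too_few_peaks_errors():
    with pytest.raises(ValueError, match="peaks"):
        fit_piecewise_sinusoid(np.linspace(0, 1, 50), 0.1)


# ---------------------------------------------------------------------------
# perfusion cycle and amplitude
# ---------------------------------------------------------------------------

def _fake_card(n, dt, P):
    t = np.arange(n) * dt
    phase = np.mod(t / P, 1.0)
    return CardPhases(phase=phase, beat_index=(t / P).astype(int),
                      fit_quality=1.0, period_per_beat=np.array([P]))


def test_perf_cycle_amplitude_recovery():
    n, dt, P = 200, 0.288, 0.9
    cp = _fake_card(n, dt, P)
    sig = 1.5 * np.cos(2 * np.pi * cp.phase)
    series = _series(np.tile(sig[:, None, None], (1, 2, 2)), dt)
    cyc = perf_cycle(series, cp, n_phases=15, bandwidth=0.5 / 15)
    amp = 0.5 * (cyc.signal[:, 0, 0].max() - cyc.signal[:, 0, 0].min())
    assert abs(amp - 1.5) / 1.5 < 0.05


def test_perf_cycle_permutation_invariance():
    n, dt, P = 120, 0.288, 0.9
    cp = _fake_card(n, dt, P)
    rng = np.random.default_rng(2)
    data = rng.normal(size=(n, 2, 2))
    series = _series(data, dt)
    c1 = perf_cycle(series, cp, n_phases=15)
    perm = rng.permutation(n)
    cp2 = CardPhases(phase=cp.phase[perm], beat_index=cp.beat_index[perm],
                     fit_quality=1.0, period_per_beat=cp.period_per_beat)
    c2 = perf_cycle(_series(data[perm], dt), cp2, n_phases=15)
    np.testing.assert_allclose(c1.signal, c2.signal, atol=1e-12)


def test_perfusion_amplitude_shared_cycle():
    ph = np.arange(15) / 15
    cyc_sig = np.tile(np.cos(2 * np.pi * ph)[:, None, None], (1, 4, 4))
    cyc = PerfCycle(signal=cyc_sig, phase_axis=ph)
    qamp = perfusion_amplitude(cyc, np.ones((4, 4), bool))
    assert cyc.parenchymal_phase == 0          # cosine peak at phase 0
    np.testing.assert_allclose(qamp.values, 1.0 - cyc_sig.min(axis=0), atol=1e-9)


def test_perfusion_amplitude_zero_perfusion():
    cyc = PerfCycle(signal=np.zeros((15, 3, 3)), phase_axis=np.arange(15) / 15)
    with pytest.warns(UserWarning, match="degenerate"):
        qamp = perfusion_amplitude(cyc, np.ones((3, 3), bool))
    np.testing.assert_allclose(qamp.values, 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# QQ
# ---------------------------------------------------------------------------

def test_monoexponential_recovery():
    dt, tau, s_ss, s0 = 0.288, 1.5, 100.0, 300.0
    t = np.arange(100) * dt
    sig = s_ss + (s0 - s_ss) * np.exp(-t / tau)
    f_ss, f0, f_tau = fit_monoexponential(sig, dt)
    assert abs(f_ss - s_ss) / s_ss < 0.01
    assert abs(f0 - s0) / s0 < 0.01
    assert abs(f_tau - tau) / tau < 0.01


def test_qq_formula_arithmetic():
    n, dt = 60, 0.288
    transient = _series(np.full((n, 4, 4), 5.0), dt)
    qamp = ParamMap(values=np.full((4, 4), 0.05), kind="Qamp",
                    mask=np.ones((4, 4), bool))
    card = CardPhases(phase=np.zeros(n), beat_index=np.zeros(n, int),
                      fit_quality=1.0, period_per_beat=np.array([1.0]))
    roi = np.zeros((4, 4), bool)
    roi[0, 0] = True
    qq = compute_qq(transient, qamp, card, roi)
    # Qamp/S_blood = 0.01, f = 60 bpm -> QQ = 60
    np.testing.assert_allclose(qq.values, 60.0, atol=1e-6)
    assert qq.meta["units"] == "mL/min/100mL"


def test_qq_zero_amplitude_and_bad_roi():
    n = 60
    transient = _series(np.full((n, 2, 2), 5.0))
    card = CardPhases(phase=np.zeros(n), beat_index=np.zeros(n, int),
                      fit_quality=1.0, period_per_beat=np.array([0.9]))
    qamp = ParamMap(values=np.zeros((2, 2)), kind="Qamp", mask=np.ones((2, 2), bool))
    roi = np.ones((2, 2), bool)
    qq = compute_qq(transient, qamp, card, roi)
    np.testing.assert_allclose(qq.values, 0.0, atol=1e-12)
    with pytest.raises(ValueError, match="ROI"):
        compute_qq(transient, qamp, card, np.zeros((2, 2), bool))


def test_qq_scales_linearly_with_heart_rate():
    n = 60
    transient = _series(np.full((n, 2, 2), 5.0))
    qamp = ParamMap(values=np.full((2, 2), 0.05), kind="Qamp",
                    mask=np.ones((2, 2), bool))
    roi = np.ones((2, 2), bool)
    mk = lambda P: CardPhases(phase=np.zeros(n), beat_index=np.zeros(n, int),
                              fit_quality=1.0, period_per_beat=np.array([P]))
    q1 = compute_qq(transient, qamp, mk(0.9), roi)
    q2 = compute_qq(transient, qamp, mk(0.45), roi)
    np.testing.assert_allclose(q2.values, 2.0 * q1.values, rtol=1e-9)
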