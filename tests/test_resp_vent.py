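"""Respiratory phases, ventilation cycle, RVent and FVL-CM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from preful.io import FrameSeries
from preful.resp_vent import (VentCycle, compute_fvlcm, compute_rvent,
                              cosine_phase_map, diaphragm_signal,
                              exclude_outliers, kernel_cycle,
                              respiratory_grouping, rvent_from_anchors)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def _area_series(areas):
    """Series whose threshold-fallback lung area tracks ``areas``."""
    n = len(areas)
    data = np.ones((n, 20, 20))
    for t, a in enumerate(areas):
        data[t, :2, :int(a)] = 0.0   # dark 'lung' pixels
    return FrameSeries(data=data, dt=0.288)


def test_grouping_monotone_ramp_gives_equal_deciles():
    masks = np.zeros((100, 10, 10), dtype=bool)
    for t in range(100):
        masks[t].flat[: t + 1] = True
    series = FrameSeries(data=np.zeros((100, 10, 10)), dt=0.288)
    resp = respiratory_grouping(series, lung_masks=masks, n_groups=10)
    counts = np.bincount(resp.group)[1:]
    assert np.all(counts == 10)


def test_grouping_orders_by_amplitude(phantom64):
    _, series, truth = phantom64
    resp = respiratory_grouping(series)
    v = 0.5 * (1 - np.cos(2 * np.pi * truth.resp_phase_true))
    assert v[resp.group == 1].mean() < v[resp.group == 10].mean()


def test_grouping_time_reversal_same_multiset(phantom64):
    _, series, _ = phantom64
    g1 = respiratory_grouping(series).group
    rev = FrameSeries(data=series.data[::-1].copy(), dt=series.dt)
    g2 = respiratory_grouping(rev).group
    assert sorted(g1) == sorted(g2)


def test_grouping_constant_area_single_group():
    series = FrameSeries(data=np.ones((30, 8, 8)), dt=0.288)
    with pytest.warns(UserWarning, match="constant"):
        resp = respiratory_grouping(series)
    assert len(set(resp.group)) == 1


# ---------------------------------------------------------------------------
# diaphragm signal
# ---------------------------------------------------------------------------

def test_diaphragm_tracks_truth(phantom64):
    _, series, truth = phantom64
    band = np.arange(18, 24)
    pos = diaphragm_signal(series, band, row_range=(28, 62))
    v = 0.5 * (1 - np.cos(2 * np.pi * truth.resp_phase_true))
    assert np.corrcoef(pos, v)[0, 1] > 0.99
    amp = pos.max() - pos.min()
    assert abs(amp - 4.0) / 4.0 < 0.2        # configured amplitude 4 px


def test_diaphragm_motionless_constant():
    data = np.zeros((30, 40, 40))
    data[:, 25:, :] = 1.0                    # static edge
    series = FrameSeries(data=data, dt=0.288)
    pos = diaphragm_signal(series, np.arange(10, 20), row_range=(10, 38))
    assert pos.std() < 0.1


def test_diaphragm_no_edge_errors():
    series = FrameSeries(data=np.zeros((10, 20, 20)), dt=0.288)
    with pytest.raises(ValueError, match="edge"):
        diaphragm_signal(series, np.arange(5, 10))


# ---------------------------------------------------------------------------
# outliers and cosine phase model
# ---------------------------------------------------------------------------

def test_exclude_outliers_percentile_arithmetic():
    sig = np.arange(1.0, 101.0)
    inc = exclude_outliers(sig, 5, 97)
    # linear-interpolation percentiles: P5 = 5.95, P97 = 97.03
    assert inc.sum() == 92
    assert not inc[:5].any() and inc[5] and inc[96] and not inc[97:].any()


def test_exclude_outliers_edge_cases():
    assert exclude_outliers(np.full(25, 3.0)).all()
    sig = np.zeros(99)
    sig[40] = 100.0
    assert not exclude_outliers(sig)[40]
    with pytest.raises(ValueError):
        exclude_outliers(np.arange(10.0))


def test_cosine_phase_inverts_a_cosine_signal():
    t = np.arange(150) * 0.288
    T = 4.0
    sig = np.cos(2 * np.pi * t / T)
    phase = cosine_phase_map(sig)
    true = np.mod(t / T, 1.0)
    err = np.abs(phase - true)
    err = np.minimum(err, 1 - err)
    interior = (t > T / 2) & (t < t[-1] - T / 2)
    assert err[interior].max() < 0.02


def test_cosine_phase_extreme_conventions():
    t = np.arange(120) * 0.1
    sig = np.cos(2 * np.pi * t / 3.0)
    phase = cosine_phase_map(sig)
    at_max = np.argmin(np.abs(t[5:-5] - 3.0)) + 5     # a signal maximum
    at_min = np.argmin(np.abs(t[5:-5] - 4.5)) + 5     # a signal minimum
    assert min(phase[at_max], 1 - phase[at_max]) < 0.03
    assert abs(phase[at_min] - 0.5) < 0.03


def test_cosine_phase_excluded_get_nan():
    t = np.arange(100) * 0.2
    sig = np.cos(2 * np.pi * t / 3.0)
    inc = np.ones(100, bool)
    inc[10] = False
    phase = cosine_phase_map(sig, inc)
    assert np.isnan(phase[10]) and np.isfinite(phase[11])


# ---------------------------------------------------------------------------
# kernel regression
# ---------------------------------------------------------------------------

def test_kernel_cycle_constant_voxel():
    data = np.full((80, 2, 2), 3.3)
    phases = np.random.default_rng(0).uniform(0, 1, 80)
    cyc = kernel_cycle(data, phases, n_phases=60)
    np.testing.assert_allclose(cyc.signal, 3.3, atol=1e-9)
    assert cyc.phase_axis.size == 60 and np.all(np.diff(cyc.phase_axis) > 0)


def test_kernel_cycle_reconstructs_cosine():
    rng = np.random.default_rng(1)
    phases = rng.uniform(0, 1, 150)
    vals = np.cos(2 * np.pi * phases)
    data = np.tile(vals[:, None, None], (1, 1, 1))
    cyc = kernel_cycle(data, phases, n_phases=60, bandwidth=1.0 / 60)
    truth = np.cos(2 * np.pi * cyc.phase_axis)
    rmse = np.sqrt(np.mean((cyc.signal[:, 0, 0] - truth) ** 2))
    assert rmse < 0.02


def test_kernel_cycle_small_bandwidth_returns_exact_sample():
    phases = np.array([0.0, 0.25, 0.5, 0.75])
    data = np.array([1.0, 2.0, 3.0, 4.0])[:, None, None]
    cyc = kernel_cycle(data, phases, n_phases=4, bandwidth=1e-4)
    np.testing.assert_allclose(cyc.signal[:, 0, 0], [1, 2, 3, 4], atol=1e-9)


def test_kernel_cycle_order_invariance():
    rng = np.random.default_rng(2)
    phases = rng.uniform(0, 1, 60)
    vals = np.sin(2 * np.pi * phases) + 0.1 * rng.normal(size=60)
    data = vals[:, None, None]
    perm = rng.permutation(60)
    c1 = kernel_cycle(data, phases, n_phases=30)
    c2 = kernel_cycle(data[perm], phases[perm], n_phases=30)
    np.testing.assert_allclose(c1.signal, c2.signal, atol=1e-12)


def test_kernel_cycle_warns_on_phase_gaps():
    phases = np.concatenate([np.linspace(0, 0.4, 30), [0.99]])
    data = np.ones((31, 1, 1))
    with pytest.warns(UserWarning, match="bandwidth"):
        kernel_cycle(data, phases, n_phases=60, bandwidth=0.01)


# ---------------------------------------------------------------------------
# RVent
# ---------------------------------------------------------------------------

def _cycle_from_profile(profile):
    sig = np.tile(np.asarray(profile, float)[:, None, None], (1, 1, 1))
    return VentCycle(signal=sig, phase_axis=np.arange(len(profile)) / len(profile))


def test_rvent_formula_arithmetic():
    prof = 1.1 + 0.1 * np.cos(2 * np.pi * np.arange(60) / 60)  # EE 1.2, EI 1.0
    cyc = _cycle_from_profile(prof)
    rv = compute_rvent(cyc, np.ones((1, 1), bool))
    np.testing.assert_allclose(rv.values[0, 0], 20.0, atol=1e-9)


def test_rvent_constant_cycle_is_zero_and_nonpositive_is_nan():
    rv = compute_rvent(_cycle_from_profile(np.full(60, 2.0)), np.ones((1, 1), bool))
    assert rv.values[0, 0] == 0.0
    rv2 = compute_rvent(_cycle_from_profile(np.linspace(1, -1, 60)),
                        np.ones((1, 1), bool))
    assert np.isnan(rv2.values[0, 0])


def test_rvent_anchor_variants():
    assert np.isclose(rvent_from_anchors(np.array(1.2), np.array(1.1),
                                         np.array(1.0)), 0.2)
    half = rvent_from_anchors(np.array(1.2), np.array(1.1), np.array(1.0),
                              method="half_cycle_sum")
    assert np.isclose(half, 0.1 / 1.1 + 0.1 / 1.0)
    with pytest.raises(ValueError):
        rvent_from_anchors(np.array(1.0), np.array(1.0), np.array(1.0),
                           method="nope")


@given(scale=st.floats(0.1, 10.0))
@settings(max_examples=20, deadline=None)
def test_rvent_invariant_to_intensity_scaling(scale):
    prof = 1.5 + 0.2 * np.cos(2 * np.pi * np.arange(60) / 60)
    rv1 = compute_rvent(_cycle_from_profile(prof), np.ones((1, 1), bool))
    rv2 = compute_rvent(_cycle_from_profile(scale * prof), np.ones((1, 1), bool))
    np.testing.assert_allclose(rv1.values, rv2.values, rtol=1e-9)


# ---------------------------------------------------------------------------
# FVL-CM
# ---------------------------------------------------------------------------

def _synthetic_cycle_map(n_phase=60, H=12, W=12, shift_col=None, delta=0):
    """All voxels share a cosine cycle; one column optionally phase-shifted."""
    ph = np.arange(n_phase) / n_phase
    base = np.cos(2 * np.pi * ph)
    sig = np.tile(base[:, None, None], (1, H, W))
    rng = np.random.default_rng(0)
    amp = 1.0 + 0.2 * rng.random((H, W))
    sig = sig * amp[None]
    if shift_col is not None:
        sig[:, :, shift_col] = np.cos(2 * np.pi * (ph + delta / n_phase))[:, None] \
            * amp[:, shift_col][None]
    cyc = VentCycle(signal=2.0 + 0.2 * sig, phase_axis=ph)
    mask = np.ones((H, W), bool)
    rv = compute_rvent(cyc, mask)
    return cyc, rv, mask


def test_fvlcm_identical_and_inverted_loops():
    cyc, rv, mask = _synthetic_cycle_map()
    fvl, ref = compute_fvlcm(cyc, rv, mask)
    assert ref.any()
    np.testing.assert_allclose(fvl.values[mask], 1.0, atol=1e-9)
    inv = VentCycle(signal=2.0 - (cyc.signal - 2.0), phase_axis=cyc.phase_axis)
    fvl_inv, _ = compute_fvlcm(inv, rv, mask)
    # loops inverted relative to the (also inverted) reference stay at +1;
    # correlate one voxel against the original reference instead
    flow = 0.5 * (np.roll(cyc.signal, -1, 0) - np.roll(cyc.signal, 1, 0))
    flow_inv = -flow
    r = np.corrcoef(flow[:, 0, 0], flow_inv[:, 0, 0])[0, 1]
    assert np.isclose(r, -1.0)


def test_fvlcm_phase_shift_gives_cosine_correlation():
    delta = 10
    cyc, rv, mask = _synthetic_cycle_map(shift_col=5, delta=delta)
    fvl, _ = compute_fvlcm(cyc, rv, mask)
    expected = np.cos(2 * np.pi * delta / 60)
    got = fvl.values[:, 5]
    np.testing.assert_allclose(got, expected, atol=0.02)


def test_fvlcm_reference_voxels_not_below_median():
    cyc, rv, mask = _synthetic_cycle_map()
    fvl, ref = compute_fvlcm(cyc, rv, mask)
    med = np.nanmedian(fvl.values[mask])
    assert np.all(fvl.values[ref] >= med - 1e-9)
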