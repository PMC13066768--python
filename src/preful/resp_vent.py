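"""Respiratory phase estimation and ventilation parameter maps.

Two respiratory signals are used at different pipeline stages: before
registration, the low-pass filtered lung-area signal sorts frames into
equal-count respiratory groups; after registration, the cranio-caudal
diaphragm position (tracked on the unregistered frames) is mapped to a
continuous respiratory phase with a cosine model, the phase-resolved
ventilation cycle is reconstructed at 60 evenly spaced phases by
Nadaraya-Watson kernel regression, and regional ventilation (RVent) and
the flow-volume-loop correlation metric (FVL-CM) are computed per voxel.

Phase convention: phase 0 at end-expiration (signal maximum of the
oriented respiratory signal), phase 0.5 at end-inspiration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import signal as sps
from skimage import measure

from .io import FrameSeries

logger = logging.getLogger("preful")


@dataclass
class RespPhases:
    group: np.ndarray                    # per-frame id 1..n_groups
    phase: np.ndarray | None = None      # per-frame phase in [0,1), NaN if excluded
    included: np.ndarray | None = None
    area_signal: np.ndarray | None = None
    diaphragm_signal: np.ndarray | None = None


@dataclass
class VentCycle:
    signal: np.ndarray                   # (n_phases, H, W)
    phase_axis: np.ndarray               # evenly spaced in [0, 1)
    covered: np.ndarray | None = None    # per-phase flag: samples within 3 bandwidths


@dataclass
class ParamMap:
    values: np.ndarray                   # H x W, NaN outside mask
    kind: str                            # "RVent" | "FVL-CM" | "Qamp" | "QQ"
    mask: np.ndarray
    meta: dict = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# respiratory grouping (pre-registration)
# ---------------------------------------------------------------------------


def lung_area_signal(series: FrameSeries, lung_masks: np.ndarray | None = None
                     ) -> np.ndarray:
    """Per-frame lung area, from per-frame masks or a threshold fallback.

    The fallback counts dark pixels (below half the median body intensity)
    inside the body outline of the temporal mean image; on proton lung MRI
    the low-signal parenchyma grows with inspiration, so this tracks lung
    area without segmentation.
    """
    if lung_masks is not None:
        masks = np.asarray(lung_masks, dtype=bool)
        if masks.shape != series.data.shape:
            raise ValueError("lung_masks must be (T, H, W)")
        return masks.sum(axis=(1, 2)).astype(np.float64)
    mean_img = series.data.mean(axis=0)
    body = mean_img > 0.1 * mean_img.max()
    thresh = 0.5 * np.median(mean_img[body])
    dark = (series.data < thresh) & body[None]
    return dark.sum(axis=(1, 2)).astype(np.float64)


def lowpass_signal(x: np.ndarray, dt: float, cutoff_hz: float = 0.7,
                   order: int = 4) -> np.ndarray:
    nyq = 0.5 / dt
    if cutoff_hz >= nyq:
        raise ValueError("cutoff must lie below Nyquist")
    sos = sps.butter(order, cutoff_hz / nyq, btype="low", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), padtype="even")


def respiratory_grouping(series: FrameSeries, lung_masks: np.ndarray | None = None,
                         n_groups: int = 10, cutoff_hz: float = 0.7) -> RespPhases:
    """Sort frames into equal-count amplitude bins of the lung-area signal.

    Group 1 holds the smallest areas (deepest expiration) and the top group
    the largest, so the two middle groups straddle mid-amplitude.
    """
    area = lung_area_signal(series, lung_masks)
    smooth = lowpass_signal(area, series.dt, cutoff_hz)
    groups = np.empty(series.n_frames, dtype=int)
    if np.ptp(smooth) == 0:
        warnings.warn("lung-area signal is constant; assigning all frames to one group")
        groups[:] = (n_groups + 1) // 2
    else:
        order = np.argsort(smooth, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(series.n_frames)
        groups = ranks * n_groups // series.n_frames + 1
    return RespPhases(group=groups, area_signal=smooth)


# ---------------------------------------------------------------------------
# diaphragm tracking
# ---------------------------------------------------------------------------


def diaphragm_signal(series: FrameSeries, column_band: np.ndarray,
                     row_range: tuple[int, int] | None = None) -> np.ndarray:
    """Sub-pixel cranio-caudal diaphragm position per frame.

    The intensity profile averaged over a band of columns crossing the
    diaphragm shows a dark-to-bright edge at the lung/abdomen interface;
    the row of maximal positive vertical gradient, refined by parabolic
    interpolation, is returned for each frame.
    """
    cols = np.asarray(column_band, dtype=int)
    if cols.size == 0:
        raise ValueError("column band is empty")
    H = series.data.shape[1]
    lo, hi = row_range if row_range is not None else (H // 4, H - 2)
    profiles = series.data[:, :, cols].mean(axis=2)          # (T, H)
    grad = np.gradient(profiles, axis=1)[:, lo:hi]
    if grad.size == 0 or np.nanmax(grad) <= 1e-9:
        raise ValueError("no diaphragm edge found in the column band")
    idx = np.argmax(grad, axis=1)
    pos = idx.astype(np.float64)
    # parabolic sub-pixel refinement where the peak is interior
    interior = (idx > 0) & (idx < grad.shape[1] - 1)
    t_int = np.where(interior)[0]
    if t_int.size:
        g0 = grad[t_int, idx[t_int] - 1]
        g1 = grad[t_int, idx[t_int]]
        g2 = grad[t_int, idx[t_int] + 1]
        denom = g0 - 2 * g1 + g2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (g0 - g2) / denom, 0.0)
        pos[t_int] += np.clip(shift, -0.5, 0.5)
    return pos + lo


# ---------------------------------------------------------------------------
# outlier exclusion and cosine phase model
# ---------------------------------------------------------------------------


def exclude_outliers(sig: np.ndarray, lo_pct: float = 5.0,
                     hi_pct: float = 97.0) -> np.ndarray:
    """Flag samples inside the [lo_pct, hi_pct] percentile band (kept samples).

    Percentiles use linear interpolation; samples are flagged, never
    deleted, so frame indexing stays intact downstream.
    """
    sig = np.asarray(sig, dtype=np.float64)
    if sig.size < 20:
        raise ValueError("need at least 20 samples for stable percentiles")
    lo = np.percentile(sig, lo_pct)
    hi = np.percentile(sig, hi_pct)
    return (sig >= lo) & (sig <= hi)


def _refined_extrema(sig: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alternating extrema of a quasi-periodic signal with parabolic refinement.

    Returns ``(times, values, is_max)`` sorted by time.
    """
    span = np.ptp(sig)
    prom = 0.25 * span if span > 0 else None
    pk, _ = sps.find_peaks(sig, prominence=prom, distance=2)
    tr, _ = sps.find_peaks(-sig, prominence=prom, distance=2)
    idx = np.concatenate([pk, tr])
    kinds = np.concatenate([np.ones(len(pk), bool), np.zeros(len(tr), bool)])
    order = np.argsort(idx, kind="stable")
    idx, kinds = idx[order], kinds[order]
    # enforce alternation: of two consecutive same-kind extrema keep the stronger
    keep = []
    for i, (j, mx) in enumerate(zip(idx, kinds)):
        if keep and kinds[keep[-1]] == mx:
            prev = idx[keep[-1]]
            better = sig[j] > sig[prev] if mx else sig[j] < sig[prev]
            if better:
                keep[-1] = i
        else:
            keep.append(i)
    idx, kinds = idx[keep], kinds[keep]
    times = idx.astype(np.float64)
    values = sig[idx].astype(np.float64)
    interior = (idx > 0) & (idx < len(sig) - 1)
    g0, g1, g2 = sig[idx[interior] - 1], sig[idx[interior]], sig[idx[interior] + 1]
    denom = g0 - 2 * g1 + g2
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (g0 - g2) / denom, 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    times[interior] += shift
    values[interior] = g1 - 0.25 * (g0 - g2) * shift
    return times, values, kinds


def cosine_phase_map(sig: np.ndarray, included: np.ndarray | None = None
                     ) -> np.ndarray:
    """Map a respiratory signal to phase in [0, 1) with a cosine model.

    The signal must be oriented so that end-expiration is its maximum.
    Within each breath the signal is normalized to [-1, 1] using the
    bracketing (parabolically refined) extrema; on the falling branch
    (expiratory extreme toward inspiration) ``phase = acos(s)/2pi`` and on
    the rising branch ``1 - acos(s)/2pi``, placing phase 0 at
    end-expiration and 0.5 at end-inspiration.  Excluded samples get NaN.
    """
    sig = np.asarray(sig, dtype=np.float64)
    if np.ptp(sig) == 0:
        raise ValueError("signal has zero span; cannot assign phases")
    included = np.ones(sig.size, bool) if included is None else np.asarray(included, bool)
    times, values, kinds = _refined_extrema(sig)
    if times.size < 2:
        raise ValueError("fewer than two respiratory extrema detected")

    t = np.arange(sig.size, dtype=np.float64)
    seg = np.clip(np.searchsorted(times, t) - 1, 0, times.size - 2)
    lo_v = np.minimum(values[seg], values[seg + 1])
    hi_v = np.maximum(values[seg], values[seg + 1])
    amp = np.where(hi_v > lo_v, hi_v - lo_v, 1.0)
    s_norm = np.clip(2.0 * (sig - lo_v) / amp - 1.0, -1.0, 1.0)
    falling = kinds[seg]                     # segment starts at a maximum
    base = np.arccos(s_norm) / (2.0 * np.pi)
    phase = np.where(falling, base, 1.0 - base)
    # outside the first/last extremum the segment direction comes from the
    # local slope (nearest-neighbor branch assignment at the boundaries)
    out_lo, out_hi = t < times[0], t > times[-1]
    if np.any(out_lo):
        # heading toward a maximum means the signal is rising there
        phase[out_lo] = np.where(kinds[0], 1.0 - base[out_lo], base[out_lo])
    if np.any(out_hi):
        falling_end = kinds[-1]              # last extremum a maximum -> now falling
        phase[out_hi] = np.where(falling_end, base[out_hi], 1.0 - base[out_hi])
    phase = np.mod(phase, 1.0)
    phase[~included] = np.nan
    return phase


# ---------------------------------------------------------------------------
# Nadaraya-Watson phase-resolved reconstruction
# ---------------------------------------------------------------------------


def kernel_cycle(data: np.ndarray, phases: np.ndarray,
                 included: np.ndarray | None = None, n_phases: int = 60,
                 bandwidth: float | None = None) -> VentCycle:
    """Nadaraya-Watson reconstruction of the mean cycle at even phases.

    ``data`` is ``(T, H, W)`` (or ``(T, ...)``); ``phases`` per-frame in
    [0, 1).  A circular Gaussian kernel on wrapped phase distance weights
    the included frames; the default bandwidth is 1.5 phase spacings, so
    roughly the +-3 nearest phase neighbours contribute.
    """
    data = np.asarray(data, dtype=np.float64)
    phases = np.asarray(phases, dtype=np.float64)
    if bandwidth is None:
        bandwidth = 1.5 / n_phases
    ok = np.isfinite(phases)
    if included is not None:
        ok &= np.asarray(included, bool)
    if ok.sum() < 3:
        raise ValueError("too few included frames for phase reconstruction")
    ph = phases[ok]
    X = data[ok].reshape(ok.sum(), -1)
    axis = np.arange(n_phases) / n_phases
    d = axis[:, None] - ph[None, :]
    d = np.abs(d - np.round(d))                       # circular distance
    covered = (d.min(axis=1) <= 3.0 * bandwidth)
    if not covered.all():
        warnings.warn(f"{(~covered).sum()} of {n_phases} query phases lie more "
                      f"than 3 bandwidths from any sample")
    w = np.exp(-0.5 * (d / bandwidth) ** 2)
    w_sum = w.sum(axis=1, keepdims=True)
    w_sum = np.where(w_sum > 0, w_sum, 1.0)
    cyc = (w @ X) / w_sum
    return VentCycle(signal=cyc.reshape((n_phases,) + data.shape[1:]),
                     phase_axis=axis, covered=covered)


def _cycle_at_phase(cycle: VentCycle, phase: float) -> np.ndarray:
    """Circular linear interpolation of the cycle at an arbitrary phase."""
    n = cycle.phase_axis.size
    pos = np.mod(phase, 1.0) * n
    i0 = int(np.floor(pos)) % n
    i1 = (i0 + 1) % n
    f = pos - np.floor(pos)
    return (1 - f) * cycle.signal[i0] + f * cycle.signal[i1]


# ---------------------------------------------------------------------------
# parameter maps
# ---------------------------------------------------------------------------


def rvent_from_anchors(s_ee: np.ndarray, s_mid: np.ndarray, s_ei: np.ndarray,
                       method: str = "full_cycle") -> np.ndarray:
    """Fractional ventilation from the end-expiration / mid / end-inspiration
    anchors of the phase-resolved cycle.

    ``full_cycle`` is the primary definition, the full-cycle fractional
    signal change ``(S_EE - S_EI) / S_EI``.  ``half_cycle_sum`` accumulates
    the two half-cycle fractional changes through mid-respiration; it is
    isolated here so the anchor construction can be swapped wholesale.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "full_cycle":
            rv = (s_ee - s_ei) / s_ei
        elif method == "half_cycle_sum":
            rv = (s_ee - s_mid) / s_mid + (s_mid - s_ei) / s_ei
        else:
            raise ValueError(f"unknown RVent method {method!r}")
    rv = np.where(s_ei > 0, rv, np.nan)
    return rv


def compute_rvent(cycle: VentCycle, mask: np.ndarray,
                  method: str = "full_cycle") -> ParamMap:
    """Regional ventilation (percent) from the phase-resolved cycle.

    Anchors are read from the reconstructed cycle (end-expiration at phase
    0, end-inspiration at phase 0.5, mid-respiration as the mean of phases
    0.25 and 0.75) rather than from raw extreme frames, which keeps the
    estimate stable under series truncation.
    """
    mask = np.asarray(mask, bool)
    s_ee = _cycle_at_phase(cycle, 0.0)
    s_ei = _cycle_at_phase(cycle, 0.5)
    s_mid = 0.5 * (_cycle_at_phase(cycle, 0.25) + _cycle_at_phase(cycle, 0.75))
    rv = 100.0 * rvent_from_anchors(s_ee, s_mid, s_ei, method=method)
    rv = np.where(mask, rv, np.nan)
    return ParamMap(values=rv, kind="RVent", mask=mask, meta={"units": "%"})


def _reference_region(rvent: ParamMap, parenchyma_mask: np.ndarray,
                      band: tuple[float, float] = (80.0, 90.0)) -> np.ndarray:
    """Largest 8-connected component of voxels with RVent in the percentile band."""
    mask = np.asarray(parenchyma_mask, bool) & np.isfinite(rvent.values)
    if not mask.any():
        raise ValueError("parenchyma mask is empty")
    vals = rvent.values[mask]
    lo, hi = np.percentile(vals, band)
    in_band = mask & (rvent.values >= lo) & (rvent.values <= hi)
    if not in_band.any():
        warnings.warn("empty RVent percentile band; using whole parenchyma")
        return mask
    labels = measure.label(in_band, connectivity=2)
    best_lab, best_key = 0, (-1, -np.inf)
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        key = (comp.sum(), float(np.nanmean(rvent.values[comp])))
        if key > best_key:
            best_key, best_lab = key, lab
    return labels == best_lab


def compute_fvlcm(cycle: VentCycle, rvent: ParamMap, parenchyma_mask: np.ndarray,
                  band: tuple[float, float] = (80.0, 90.0)
                  ) -> tuple[ParamMap, np.ndarray]:
    """Flow-volume-loop correlation metric per voxel, plus the reference mask.

    The per-voxel "flow" loop is the circular central phase-derivative of
    the ventilation cycle; the reference loop averages the flow loops over
    the largest connected parenchymal region with RVent in the 80th-90th
    percentile band; FVL-CM is the zero-lag Pearson correlation between
    each voxel loop and the reference loop.
    """
    mask = np.asarray(parenchyma_mask, bool)
    flow = 0.5 * (np.roll(cycle.signal, -1, axis=0) - np.roll(cycle.signal, 1, axis=0))
    ref_mask = _reference_region(rvent, mask, band)
    ref_loop = flow[:, ref_mask].mean(axis=1)
    ref_c = ref_loop - ref_loop.mean()
    ref_n = np.sqrt((ref_c ** 2).sum())
    flat = flow.reshape(flow.shape[0], -1)
    flat_c = flat - flat.mean(axis=0, keepdims=True)
    norms = np.sqrt((flat_c ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (ref_c @ flat_c) / (ref_n * norms)
    corr = np.clip(corr.reshape(cycle.signal.shape[1:]), -1.0, 1.0)
    corr = np.where(mask & (norms.reshape(corr.shape) > 0) & (ref_n > 0), corr, np.nan)
    return (ParamMap(values=corr, kind="FVL-CM", mask=mask, meta={"units": "1"}),
            ref_mask)
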