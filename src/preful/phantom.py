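"""Synthetic free-breathing lung MRI phantom with known ground truth.

The phantom emulates a coronal spoiled-gradient-echo time series acquired
during free breathing:

* two half-ellipse lungs inside a bright body, closed caudally by a flat
  diaphragm edge above a bright abdomen;
* diaphragm-dominated cranio-caudal motion: the diaphragm displaces with
  the respiratory waveform and the deformation decays linearly from the
  diaphragm (maximum) to the lung apex (zero), so the generating
  displacement is exactly invertible;
* a slow (< 0.7 Hz) respiratory density modulation of the parenchyma
  (signal maximal at end-expiration) and a fast (> 0.7 Hz) cardiac signal
  concentrated in a small vessel tree with a scaled parenchymal component;
* a monoexponential approach of the global signal to magnetization steady
  state over the first frames;
* circular ventilation/perfusion defect lesions with a multiplicative
  reduction of the local truth value;
* additive Gaussian noise.

Every map and per-frame field used to render the series is returned as
ground truth, so downstream parameter recovery can be checked voxel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np

from .io import FrameSeries, write_map, write_series, write_provenance
from .registration import DispField, warp

# steady-state envelope starts at this multiple of the equilibrium signal
ENV_START_RATIO = 3.0
# default multiplicative reduction of truth values inside defect lesions
DEFECT_FACTOR = 0.2
# asymmetry of the respiratory phase warp (0 = symmetric; larger = shorter
# inspiration, longer expiration); smooth so harmonics stay below the cutoff
RESP_ASYMMETRY = 0.9
# vessel cardiac amplitude, as multiple of the parenchymal fractional amplitude
VESSEL_AMP_RATIO = 6.0

BASE_BODY = 0.80
BASE_ABDOMEN = 0.90
BASE_PARENCHYMA = 0.35
BASE_VESSEL = 0.70


@dataclass
class PhantomConfig:
    """Generation parameters; defaults follow the 2D PREFUL protocol.

    ``resp_period`` and ``card_period`` must keep the respiratory rate
    below and the cardiac rate above the 0.7 Hz separation cutoff.
    """

    grid_size: tuple[int, int] = (128, 128)
    n_frames: int = 200
    dt: float = 0.288                 # s
    resp_period: float = 4.0          # s  (0.25 Hz)
    card_period: float = 0.9          # s  (~1.11 Hz)
    resp_amplitude: float = 8.0       # px, max diaphragm displacement
    rvent_base: float = 0.15          # fractional ventilation
    perf_base: float = 0.012          # fractional parenchymal cardiac amplitude
    steady_state_tau: float = 1.5     # s
    n_defects: int = 2
    defect_kind: str = "both"         # ventilation | perfusion | both
    defect_factor: float = DEFECT_FACTOR
    card_lag_s: float = 0.09          # s, parenchymal pulse-arrival delay
    noise_sigma: float = 0.01         # intensity units
    seed: int = 0
    noise_seed: int | None = None     # defaults to `seed` (anatomy vs noise split)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 52:
            raise ValueError("n_frames must be >= 52 (shortest analyzable series)")
        if 1.0 / self.resp_period >= 0.7:
            raise ValueError("respiratory frequency must stay below the 0.7 Hz cutoff")
        if 1.0 / self.card_period <= 0.7:
            raise ValueError("cardiac frequency must stay above the 0.7 Hz cutoff")
        if self.defect_kind not in ("ventilation", "perfusion", "both"):
            raise ValueError(f"unknown defect_kind {self.defect_kind!r}")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated series."""

    rvent_true: np.ndarray            # per-voxel fractional ventilation
    q_true: np.ndarray                # per-voxel perfusion amplitude (intensity units)
    defect_labels: np.ndarray         # 0 none, 1 vent, 2 perf, 3 both
    fields_true: list[DispField]      # per-frame frame->reference registration fields
    lung_mask: np.ndarray
    vessel_mask: np.ndarray
    parenchyma_mask: np.ndarray
    resp_phase_true: np.ndarray       # per-frame signal phase in [0, 1)
    card_phase_true: np.ndarray
    diaphragm_row: float = 0.0        # reference (end-expiration) diaphragm row
    apex_row: float = 0.0
    geometry: dict = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------


def resp_waveform(t: np.ndarray, period: float) -> tuple[np.ndarray, np.ndarray]:
    """Asymmetric raised-cosine respiratory waveform.

    Returns ``(v, p)`` with ``v`` in [0, 1] (0 at end-expiration, 1 at
    end-inspiration) and the signal phase ``p`` in [0, 1) satisfying
    ``v = (1 - cos(2 pi p)) / 2``.  The phase warp
    ``p = phi + a sin(2 pi phi) / 2 pi`` shortens inspiration and lengthens
    expiration, as in quiet breathing; being smooth, it keeps the
    waveform's harmonic energy essentially below the 0.7 Hz cutoff.
    """
    phi = np.mod(np.asarray(t, dtype=np.float64) / period, 1.0)
    p = phi + RESP_ASYMMETRY * np.sin(2.0 * np.pi * phi) / (2.0 * np.pi)
    v = 0.5 * (1.0 - np.cos(2.0 * np.pi * p))
    return v, np.mod(p, 1.0)


def card_waveform(t: np.ndarray, period: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit sinusoid cardiac waveform and its phase (0 at the signal peak)."""
    tt = np.asarray(t, dtype=np.float64)
    c = np.sin(2.0 * np.pi * tt / period)
    p = np.mod(tt / period - 0.25, 1.0)
    return c, p


# ---------------------------------------------------------------------------
# analytic scene
# ---------------------------------------------------------------------------
#
# Frames are rendered by evaluating a continuous scene (soft-edged ellipses)
# at analytically deformed coordinates, so the series carries no rendering
# interpolation error and the only resampling happens where the real
# pipeline resamples too (registration warps).

_EDGE_W = 1.5  # px, soft edge width of all structures


def _sstep(x: np.ndarray) -> np.ndarray:
    """Smootherstep ramp of width ``_EDGE_W`` centred on the boundary."""
    t = np.clip(x / _EDGE_W + 0.5, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _soft_ellipse(yy, xx, cy, cx, ry, rx):
    q = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    r_eff = np.sqrt(ry * rx)
    return _sstep((1.0 - q) * r_eff)


class _Scene:
    """Continuous reference-space scene of one phantom subject."""

    def __init__(self, cfg: PhantomConfig, rng: np.random.Generator):
        H, W = cfg.grid_size
        self.shape = (H, W)
        self.cfg = cfg
        self.body = (0.52 * H, 0.50 * W, 0.46 * H, 0.42 * W)
        self.apex = 0.46 * H - 0.34 * H          # top of the lung ellipses
        self.dia = 0.70 * H                      # reference diaphragm row
        self.lungs = [(0.46 * H, 0.32 * W, 0.34 * H, 0.145 * W),
                      (0.46 * H, 0.68 * W, 0.34 * H, 0.145 * W)]
        self.vessels = []
        for cy, cx, ry, rx in self.lungs:
            side = 1.0 if cx < 0.5 * W else -1.0
            for k, r in enumerate((0.024, 0.017, 0.014)):
                self.vessels.append(((0.48 + 0.05 * k) * H,
                                     cx + side * (0.035 + 0.028 * k) * W,
                                     r * H + 1.0, r * W + 1.0))
        # defect lesions: circles centred on parenchymal voxels
        self.defects = []
        yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
        par = self._lung_m(yy, xx) > 0.5
        for v in self.vessels:
            par &= _soft_ellipse(yy, xx, *v) < 0.5
        pc = np.argwhere(par)
        radius = 0.085 * min(H, W)
        for _ in range(cfg.n_defects):
            cy, cx = pc[rng.integers(len(pc))]
            self.defects.append((float(cy), float(cx), radius))

    # memberships -----------------------------------------------------------
    def _lung_m(self, yy, xx):
        m = np.zeros_like(yy)
        for e in self.lungs:
            m = np.maximum(m, _soft_ellipse(yy, xx, *e))
        return m * _sstep(self.dia - yy)

    def _vessel_m(self, yy, xx):
        m = np.zeros_like(yy)
        for e in self.vessels:
            m = np.maximum(m, _soft_ellipse(yy, xx, *e))
        return m

    def _defect_m(self, yy, xx, kinds):
        m = np.zeros_like(yy)
        cfg = self.cfg
        if cfg.defect_kind in kinds:
            for cy, cx, r in self.defects:
                m = np.maximum(m, _sstep(r - np.hypot(yy - cy, xx - cx)))
        return m

    def _grad(self, yy):
        return 0.85 + 0.30 * np.clip((yy - self.apex) / (self.dia - self.apex),
                                     0.0, 1.0)

    def rvent_at(self, yy, xx):
        mult = 1.0 - (1.0 - self.cfg.defect_factor) * self._defect_m(
            yy, xx, ("ventilation", "both"))
        return self.cfg.rvent_base * self._grad(yy) * mult

    def q_par_at(self, yy, xx):
        mult = 1.0 - (1.0 - self.cfg.defect_factor) * self._defect_m(
            yy, xx, ("perfusion", "both"))
        return self.cfg.perf_base * BASE_PARENCHYMA * self._grad(yy) * mult

    # rendering -------------------------------------------------------------
    def render(self, yy, xx, v: float, c_ves: float, c_par: float) -> np.ndarray:
        """Scene intensity at (deformed) coordinates.

        ``c_ves`` and ``c_par`` are the cardiac waveform values in the
        vessels and (pulse-delayed) parenchyma for this frame.
        """
        img = BASE_BODY * _soft_ellipse(yy, xx, *self.body)
        m_abd = _soft_ellipse(yy, xx, *self.body) * _sstep(yy - self.dia)
        img = img * (1 - m_abd) + BASE_ABDOMEN * m_abd
        m_lung = self._lung_m(yy, xx)
        lung_val = (BASE_PARENCHYMA * (1.0 - self.rvent_at(yy, xx) * v)
                    + self.q_par_at(yy, xx) * c_par)
        img = img * (1 - m_lung) + lung_val * m_lung
        m_ves = self._vessel_m(yy, xx) * m_lung
        ves_val = BASE_VESSEL + VESSEL_AMP_RATIO * self.cfg.perf_base * BASE_VESSEL * c_ves
        return img * (1 - m_ves) + ves_val * m_ves

    # ground truth ----------------------------------------------------------
    def truth_masks(self):
        H, W = self.shape
        yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
        m_lung = self._lung_m(yy, xx)
        m_ves = self._vessel_m(yy, xx)
        lung = m_lung > 0.5
        ves = (m_ves > 0.5) & lung
        # quantification ROI: pure parenchyma only — partial-volume voxels on
        # the pleural/vessel interface carry mixed signal and are excluded,
        # as a real parenchymal ROI excludes pleura and central vessels
        par = (m_lung >= 0.999) & (m_ves <= 0.001)
        rvent = np.where(par, self.rvent_at(yy, xx), 0.0)
        q = np.where(par, self.q_par_at(yy, xx), 0.0)
        q = np.where(ves, VESSEL_AMP_RATIO * self.cfg.perf_base * BASE_VESSEL, q)
        labels = np.zeros((H, W), dtype=np.uint8)
        if self.cfg.defect_kind in ("ventilation", "both"):
            labels[(self._defect_m(yy, xx, ("ventilation", "both")) > 0.5) & lung] |= 1
        if self.cfg.defect_kind in ("perfusion", "both"):
            labels[(self._defect_m(yy, xx, ("perfusion", "both")) > 0.5) & lung] |= 2
        return lung, ves, par, rvent, q, labels


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------


def _source_rows(y: np.ndarray, apex: float, dia: float, a: float) -> np.ndarray:
    """Reference-space row sampled by frame row ``y`` (diaphragm down by ``a``)."""
    if a == 0:
        return y
    k = a / (dia - apex)
    lin = (y + k * apex) / (1.0 + k)
    return np.where(y <= apex, y, np.where(y <= dia + a, lin, y - a))


def _registration_field(shape, apex, dia, a: float) -> DispField:
    """Exact frame -> reference backward field for diaphragm displacement ``a``."""
    H, W = shape
    y = np.arange(H, dtype=np.float64)
    k = a / (dia - apex)
    u_col = np.where(y <= apex, 0.0,
                     np.where(y <= dia, k * (y - apex), a))
    u = np.repeat(u_col[:, None], W, axis=1)
    return DispField(u, np.zeros(shape))


def warp_forward(frame: np.ndarray, fld: DispField, order: int = 3) -> np.ndarray:
    """Apply a backward-mapping displacement field to a single frame."""
    return warp(frame, fld, order=order)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_phantom(config: PhantomConfig) -> tuple[FrameSeries, PhantomTruth]:
    """Render the phantom series and its ground truth.

    Frame model: each frame evaluates the continuous scene at analytically
    deformed coordinates, ``I_t(p) = env(t) * scene(psi_t(p); v(t), c(t))
    + noise``, where ``v`` is the respiratory and ``c`` the cardiac unit
    waveform, ``psi_t`` the diaphragm-driven deformation and ``env`` the
    monoexponential steady-state envelope.  Rendering involves no image
    interpolation, so the ground-truth registration fields invert the
    motion exactly.  Identical configs (and seeds) produce
    bitwise-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    scene = _Scene(cfg, rng)
    noise_rng = np.random.default_rng(
        cfg.seed if cfg.noise_seed is None else cfg.noise_seed)

    t = np.arange(cfg.n_frames) * cfg.dt
    v, resp_phase = resp_waveform(t, cfg.resp_period)
    c, card_phase = card_waveform(t, cfg.card_period)
    # parenchymal perfusion lags the vessel pulse by the transit delay
    c_par, _ = card_waveform(t - cfg.card_lag_s, cfg.card_period)
    if cfg.steady_state_tau > 0:
        env = 1.0 + (ENV_START_RATIO - 1.0) * np.exp(-t / cfg.steady_state_tau)
    else:
        env = np.ones_like(t)

    H, W = cfg.grid_size
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    apex, dia = scene.apex, scene.dia
    frames = np.empty((cfg.n_frames, H, W))
    fields_true: list[DispField] = []
    for i in range(cfg.n_frames):
        a = cfg.resp_amplitude * v[i]
        ys = _source_rows(yy, apex, dia, a)
        frames[i] = env[i] * scene.render(ys, xx, v[i], c[i], c_par[i])
        fields_true.append(_registration_field(cfg.grid_size, apex, dia, a))
    if cfg.noise_sigma > 0:
        frames = frames + noise_rng.normal(0.0, cfg.noise_sigma, frames.shape)

    lung, ves, par, rvent, q, labels = scene.truth_masks()
    series = FrameSeries(data=frames, dt=cfg.dt,
                         meta={"phantom_seed": cfg.seed, "kind": "phantom"})
    truth = PhantomTruth(
        rvent_true=rvent, q_true=q, defect_labels=labels,
        fields_true=fields_true,
        lung_mask=lung, vessel_mask=ves, parenchyma_mask=par,
        resp_phase_true=resp_phase, card_phase_true=card_phase,
        diaphragm_row=dia, apex_row=apex,
        geometry={"scene": scene},
    )
    return series, truth


def scan_pair_configs(subject_seed: int, base: PhantomConfig | None = None
                      ) -> tuple[PhantomConfig, PhantomConfig]:
    """Configs for two scans of one subject: same anatomy, new physiology/noise.

    The second scan keeps the anatomy seed (identical lungs, vessels and
    defects) but jitters the breathing period/depth and heart rate slightly
    and uses an independent noise stream, emulating a scan-rescan visit.
    """
    base = base or PhantomConfig()
    srng = np.random.default_rng(subject_seed)
    common = dict(
        resp_period=float(srng.uniform(3.2, 4.8)),
        card_period=float(srng.uniform(0.78, 1.05)),
        resp_amplitude=float(srng.uniform(0.75, 1.15)) * base.resp_amplitude,
        rvent_base=float(srng.uniform(0.8, 1.2)) * base.rvent_base,
        perf_base=float(srng.uniform(0.8, 1.2)) * base.perf_base,
    )
    scan1 = replace(base, seed=subject_seed, noise_seed=subject_seed * 2 + 1, **common)
    jit = np.random.default_rng(subject_seed + 10_000)
    scan2 = replace(
        scan1,
        noise_seed=subject_seed * 2 + 2,
        resp_period=min(max(common["resp_period"] * float(jit.uniform(0.95, 1.05)), 1.5), 10.0),
        card_period=min(max(common["card_period"] * float(jit.uniform(0.96, 1.04)), 0.72), 1.40),
        resp_amplitude=common["resp_amplitude"] * float(jit.uniform(0.9, 1.1)),
    )
    return scan1, scan2


def write_phantom(series: FrameSeries, truth: PhantomTruth,
                  config: PhantomConfig, out_dir) -> None:
    """Write the series, truth maps and a JSON config sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_series(series, out / "series.nii.gz")
    write_map(truth.rvent_true, out / "rvent_true.nii.gz", "fractional ventilation")
    write_map(truth.q_true, out / "q_true.nii.gz", "perfusion amplitude (a.u.)")
    write_map(truth.defect_labels, out / "defect_labels.nii.gz", "0 none 1 vent 2 perf 3 both")
    write_map(truth.lung_mask, out / "lung_mask.nii.gz")
    write_map(truth.vessel_mask, out / "vessel_mask.nii.gz")
    write_map(truth.parenchyma_mask, out / "parenchyma_mask.nii.gz")
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(config).items()}
    write_provenance(cfg, out / "phantom_config.json")
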