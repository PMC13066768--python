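"""Series/config containers and NIfTI / TSV / TOML / JSON input-output.

Conventions used everywhere in this package:

* arrays are time-major ``(T, H, W)``, 0-based, row-major, pixel-centered;
* the time step ``dt`` is in seconds and is read from ``pixdim[4]`` of a
  4D NIfTI file, falling back to the configured default when the header
  carries no usable value.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("preful")

# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FrameSeries:
    """A 2D+t image stack with temporal metadata.

    Parameters
    ----------
    data:
        ``(T, H, W)`` float array of image intensities (arbitrary units).
    dt:
        Temporal resolution in seconds.
    frame_valid:
        Per-frame boolean; frames flagged ``False`` are excluded from
        phase-resolved reconstruction but kept in the stack.
    meta:
        Free-form provenance dictionary.
    """

    data: np.ndarray
    dt: float
    frame_valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"FrameSeries data must be (T, H, W), got {self.data.shape}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.frame_valid is None:
            self.frame_valid = np.ones(self.data.shape[0], dtype=bool)
        self.frame_valid = np.asarray(self.frame_valid, dtype=bool)
        if self.frame_valid.shape != (self.data.shape[0],):
            raise ValueError("frame_valid length must equal number of frames")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.dt

    def copy_with(self, data: np.ndarray, **meta) -> "FrameSeries":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return FrameSeries(data=data, dt=self.dt,
                           frame_valid=self.frame_valid[: data.shape[0]].copy(),
                           meta=new_meta)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    The defaults encode the standard 2D PREFUL protocol: a 0.7 Hz
    ventilation/perfusion cutoff, 10 respiratory groups for registration,
    60 respiratory / 15 cardiac reconstruction phases, exclusion of the
    first 20 frames to reach magnetization steady state, and defect
    thresholds of 0.4 x P90 (RVent), 0.15 x P90 (QQ) and 0.90 (FVL-CM).
    """

    dt_default: float = 0.288          # s, fallback temporal resolution
    cutoff_hz: float = 0.7             # ventilation/perfusion split
    filter_order: int = 4              # Butterworth order (zero-phase)
    n_resp_groups: int = 10
    n_resp_phases: int = 60
    n_card_phases: int = 15
    steady_state_skip: int = 20        # frames
    # defect thresholds
    rvent_factor: float = 0.4          # x P90(RVent)
    qq_factor: float = 0.15            # x P90(QQ)
    fvlcm_min: float = 0.90
    # diaphragm-signal outlier percentiles
    outlier_lo_pct: float = 5.0
    outlier_hi_pct: float = 97.0
    # FVL-CM reference band (percentiles of RVent)
    reference_band_lo: float = 80.0
    reference_band_hi: float = 90.0
    # registration
    reg_mode: str = "direct"           # direct | goreg
    reference_group: int = 5
    start_scale: int = 3
    iters_per_scale: int = 6
    fluid_sigma: float = 3.0
    elastic_sigma: float = 3.0
    window_sigma: float = 2.0
    # guided filter
    guided_radius: int = 2
    guided_eps_frac: float = 0.01      # eps = (frac * dynamic range)^2
    denoise_before_split: bool = True
    # cardiac analysis
    vessel_seed_count: int = 5
    vessel_seed_top_frac: float = 0.01
    vessel_roi_cap: int = 200
    vessel_r2_patience: int = 3
    qq_scale: float = 1.0              # blood/exchange-fraction correction hook
    parenchymal_phase_method: str = "histogram"  # histogram | mean
    histogram_bins: int = 32
    # kernel regression bandwidth, in phase units, as multiple of phase spacing
    kernel_bandwidth_factor: float = 1.5

    def __post_init__(self) -> None:
        for name in ("n_resp_groups", "n_resp_phases", "n_card_phases", "filter_order"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        nyquist = 0.5 / self.dt_default
        if not 0 < self.cutoff_hz < nyquist:
            raise ValueError(f"cutoff_hz must lie in (0, {nyquist:.3f}) Hz")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_toml(self, path: str | Path) -> None:
        """Write the fully resolved configuration (flat TOML)."""
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            else:
                lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def read_series(path: str | Path, dt_fallback: float = 0.288) -> FrameSeries:
    """Read a 4D NIfTI time series as a time-major :class:`FrameSeries`.

    ``dt`` is taken from ``pixdim[4]``; a missing or non-positive header
    value falls back to ``dt_fallback`` with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 3:
        raise ValueError("fewer than 2 frames: series must be 4D (X, Y, 1, T) or (X, Y, T)")
    if arr.ndim != 4:
        raise ValueError(f"expected a 4D NIfTI series, got {arr.ndim} dims")
    # on disk: (X, Y, Z=1, T); internal: (T, H, W) with H=Y rows, W=X cols
    if arr.shape[2] != 1:
        raise ValueError("expected a single-slice (X, Y, 1, T) series")
    data = np.transpose(arr[:, :, 0, :], (2, 1, 0)).astype(np.float64)
    if data.shape[0] < 2:
        raise ValueError("fewer than 2 frames")
    dt = float(img.header["pixdim"][4])
    if not np.isfinite(dt) or dt <= 0:
        logger.warning("pixdim[4] missing or non-positive; falling back to dt=%g s", dt_fallback)
        dt = dt_fallback
    if dt <= 0:
        raise ValueError("non-positive dt")
    return FrameSeries(data=data, dt=dt, meta={"source": str(path)})


def write_series(series: FrameSeries, path: str | Path) -> None:
    """Write a series as 4D NIfTI with ``pixdim[4] = dt``."""
    arr = np.transpose(series.data, (2, 1, 0))[:, :, None, :]
    img = nib.Nifti1Image(np.asarray(arr), affine=np.eye(4))
    img.header["pixdim"][4] = series.dt
    nib.save(img, str(path))


def write_map(values: np.ndarray, path: str | Path, description: str = "") -> None:
    """Write a 2D map (or boolean mask) as a single-slice NIfTI."""
    arr = np.asarray(values)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr.T[:, :, None], affine=np.eye(4))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def read_map(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    return np.asarray(arr[:, :, 0]).T


# ---------------------------------------------------------------------------
# tables & provenance
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ["subject", "scan", "duration_s", "registration", "parameter", "value"]


def write_tables(results: pd.DataFrame | list[dict], path: str | Path) -> Path:
    """Write per-(subject, duration, registration, parameter) values as TSV.

    Column order and row order are fixed so that re-running on the same
    results produces a byte-identical file.
    """
    df = pd.DataFrame(results, columns=TABLE_COLUMNS) if not isinstance(results, pd.DataFrame) \
        else results.reindex(columns=TABLE_COLUMNS)
    df = df.sort_values(TABLE_COLUMNS[:-1], kind="stable").reset_index(drop=True)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
    return path


def write_provenance(info: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(info, indent=2, sort_keys=True, default=str) + "\n")
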