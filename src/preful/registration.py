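"""Nonrigid registration by local polynomial expansion.

The engine follows the displacement-estimation scheme built on quadratic
polynomial expansion: each image is approximated locally, under a Gaussian
applicability window, by

    f(x) ~ x^T A x + b^T x + c

and the displacement between two images follows pointwise from the change
of the linear coefficient, ``A d = -(b_moving - b_fixed) / 2``.  The solve
is embedded in a coarse-to-fine pyramid with fluid (certainty-weighted
smoothing of each incremental update) and elastic (smoothing of the
accumulated field) regularization, and optional composition of updates.

Displacement fields use the backward-mapping convention throughout:
``warp(im, field)[p] = im[p + (u, v)(p)]`` with ``u`` along rows (axis 0)
and ``v`` along columns (axis 1), so a field maps each output pixel to the
location it samples in the input image.

The engine is fully deterministic: repeated runs on identical inputs are
bitwise identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .io import FrameSeries

logger = logging.getLogger("preful")

_COND_LIMIT = 1e6  # pixels with worse-conditioned A get zero certainty
_MAX_STEP = 2.0    # px, per-iteration displacement increment bound
_ELASTIC_BASE_WEIGHT = 0.05  # floor weight of uncertain pixels in elastic smoothing


@dataclass
class DispField:
    """Per-pixel backward-mapping displacement, in pixels."""

    u: np.ndarray                      # displacement along rows (axis 0)
    v: np.ndarray                      # displacement along columns (axis 1)
    certainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share a grid")
        if self.certainty is None:
            self.certainty = np.ones_like(self.u)
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("displacement field must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "DispField":
        return cls(np.zeros(shape), np.zeros(shape))


@dataclass
class RegSchedule:
    """Registration settings: scheduling mode plus engine parameters."""

    mode: str = "direct"               # direct | goreg
    reference_group: int = 5
    start_scale: int = 3               # pyramid starts at downsampling 2**start_scale
    iters_per_scale: int = 6
    fluid_sigma: float = 3.0
    elastic_sigma: float = 3.0
    window_sigma: float = 2.0          # applicability sigma of the expansion
    symmetric: bool = False            # one-directional only (the only mode)
    composite_accumulation: bool = True

    def __post_init__(self) -> None:
        if self.start_scale < 0:
            raise ValueError("start_scale must be >= 0")
        if self.iters_per_scale < 1:
            raise ValueError("iters_per_scale must be >= 1")
        if self.mode not in ("direct", "goreg"):
            raise ValueError(f"unknown registration mode {self.mode!r}")


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------


def warp(image: np.ndarray, field: DispField, order: int = 3) -> np.ndarray:
    """Backward warp with reflected boundary handling.

    Cubic B-spline interpolation by default: the lower-order bilinear
    kernel blurs the warped image relative to the fixed one, which on
    anatomy with asymmetric intensity structure turns into a systematic
    sub-pixel displacement bias along the asymmetry.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != field.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs field {field.shape}")
    rows, cols = np.meshgrid(np.arange(image.shape[0], dtype=np.float64),
                             np.arange(image.shape[1], dtype=np.float64), indexing="ij")
    coords = np.stack([rows + field.u, cols + field.v])
    return ndimage.map_coordinates(image, coords, order=order, mode="reflect")


def compose(inner: DispField, outer: DispField) -> DispField:
    """Compose two backward fields applied in sequence (``inner`` first).

    ``warp(warp(im, inner), outer) == warp(im, compose(inner, outer))``.
    """
    rows, cols = np.meshgrid(np.arange(inner.shape[0], dtype=np.float64),
                             np.arange(inner.shape[1], dtype=np.float64), indexing="ij")
    coords = np.stack([rows + outer.u, cols + outer.v])
    u = outer.u + ndimage.map_coordinates(inner.u, coords, order=1, mode="nearest")
    v = outer.v + ndimage.map_coordinates(inner.v, coords, order=1, mode="nearest")
    cert = np.minimum(inner.certainty, outer.certainty)
    return DispField(u, v, cert)


# ---------------------------------------------------------------------------
# polynomial expansion
# ---------------------------------------------------------------------------


def _window(sigma: float) -> tuple[np.ndarray, np.ndarray]:
    radius = int(np.ceil(3.0 * sigma))
    t = np.arange(-radius, radius + 1, dtype=np.float64)
    w = np.exp(-0.5 * (t / sigma) ** 2)
    return t, w


def polynomial_expansion(image: np.ndarray, window_sigma: float = 2.0) -> dict[str, np.ndarray]:
    """Per-pixel quadratic expansion under a Gaussian applicability window.

    Returns per-pixel coefficient grids ``{"A": (H,W,2,2), "b": (H,W,2),
    "c": (H,W)}`` of the weighted least-squares fit
    ``f(x) ~ x^T A x + b^T x + c`` in local coordinates (rows first).

    The fit is evaluated with separable correlations: six weighted moment
    images are combined through the inverse of the (constant) Gram matrix
    of the basis ``[1, y, x, y^2, x^2, xy]``.
    """
    if window_sigma <= 0:
        raise ValueError("window_sigma must be positive")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single 2D frame")
    t, w = _window(window_sigma)
    k0, k1, k2 = w, w * t, w * t * t

    def corr(img2d, ky, kx):
        tmp = ndimage.correlate1d(img2d, ky, axis=0, mode="reflect")
        return ndimage.correlate1d(tmp, kx, axis=1, mode="reflect")

    m00 = corr(img, k0, k0)
    m10 = corr(img, k1, k0)   # weighted y moment
    m01 = corr(img, k0, k1)   # weighted x moment
    m20 = corr(img, k2, k0)
    m02 = corr(img, k0, k2)
    m11 = corr(img, k1, k1)

    s0, s2, s4 = w.sum(), (w * t * t).sum(), (w * t ** 4).sum()
    # Gram matrix of [1, y, x, y^2, x^2, xy] under the separable window
    G = np.zeros((6, 6))
    G[0, 0] = s0 * s0
    G[0, 3] = G[3, 0] = s2 * s0
    G[0, 4] = G[4, 0] = s0 * s2
    G[1, 1] = s2 * s0
    G[2, 2] = s0 * s2
    G[3, 3] = s4 * s0
    G[4, 4] = s0 * s4
    G[3, 4] = G[4, 3] = s2 * s2
    G[5, 5] = s2 * s2
    Ginv = np.linalg.inv(G)

    m = np.stack([m00, m10, m01, m20, m02, m11], axis=-1)
    r = m @ Ginv.T  # (H, W, 6): [c, b_y, b_x, a_yy, a_xx, a_xy]

    A = np.empty(img.shape + (2, 2))
    A[..., 0, 0] = r[..., 3]
    A[..., 1, 1] = r[..., 4]
    A[..., 0, 1] = A[..., 1, 0] = 0.5 * r[..., 5]
    b = np.stack([r[..., 1], r[..., 2]], axis=-1)
    return {"A": A, "b": b, "c": r[..., 0], "radius": len(t) // 2}


def _solve_increment(fixed_coeffs: dict, moving_coeffs: dict
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise solve of ``A d = -(b_m - b_f)/2`` with conditioning certainty."""
    A = 0.5 * (fixed_coeffs["A"] + moving_coeffs["A"])
    rhs = -0.5 * (moving_coeffs["b"] - fixed_coeffs["b"])
    a, bb, c = A[..., 0, 0], A[..., 0, 1], A[..., 1, 1]
    det = a * c - bb * bb
    # eigenvalue magnitudes of the symmetric 2x2 for conditioning
    tr_half = 0.5 * (a + c)
    disc = np.sqrt(np.maximum((0.5 * (a - c)) ** 2 + bb * bb, 0.0))
    lam_max = np.abs(tr_half) + disc
    lam_min = np.abs(np.abs(tr_half) - disc)
    ok = (lam_min * _COND_LIMIT > lam_max) & (np.abs(det) > 1e-300)
    safe_det = np.where(ok, det, 1.0)
    du = (c * rhs[..., 0] - bb * rhs[..., 1]) / safe_det
    dv = (-bb * rhs[..., 0] + a * rhs[..., 1]) / safe_det
    du = np.where(ok, du, 0.0)
    dv = np.where(ok, dv, 0.0)
    cert = ok.astype(np.float64)
    r = fixed_coeffs["radius"]
    if cert.shape[0] > 2 * r and cert.shape[1] > 2 * r:
        border = np.zeros_like(cert, dtype=bool)
        border[:r], border[-r:], border[:, :r], border[:, -r:] = True, True, True, True
        cert[border] = 0.0
    return du, dv, cert


def _solve_increment_averaged(fixed_coeffs: dict, moving_coeffs: dict,
                              sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Increment from certainty-weighted averaging of the normal equations.

    The pointwise system ``A d = -(b_m - b_f)/2`` is ill-posed where the
    local structure is weak, so the engine averages ``A^T A`` and
    ``A^T rhs`` over a Gaussian neighbourhood (the fluid term), weighted by
    per-pixel certainty, before solving.  This is the certainty-weighted
    formulation of polynomial-expansion displacement estimation.
    """
    A = 0.5 * (fixed_coeffs["A"] + moving_coeffs["A"])
    rhs = -0.5 * (moving_coeffs["b"] - fixed_coeffs["b"])
    a, bb, c = A[..., 0, 0], A[..., 0, 1], A[..., 1, 1]
    # A symmetric: A^T A = A^2
    g11 = a * a + bb * bb
    g12 = bb * (a + c)
    g22 = c * c + bb * bb
    h1 = a * rhs[..., 0] + bb * rhs[..., 1]
    h2 = bb * rhs[..., 0] + c * rhs[..., 1]
    cert = np.ones_like(a)
    r = fixed_coeffs["radius"]
    if cert.shape[0] > 2 * r and cert.shape[1] > 2 * r:
        cert[:r], cert[-r:], cert[:, :r], cert[:, -r:] = 0, 0, 0, 0
    if sigma > 0:
        sm = lambda x: ndimage.gaussian_filter(x * cert, sigma, mode="nearest")
    else:
        sm = lambda x: x * cert
    g11, g12, g22, h1, h2 = map(sm, (g11, g12, g22, h1, h2))
    det = g11 * g22 - g12 * g12
    lam_max = 0.5 * (g11 + g22) + np.sqrt(np.maximum(
        (0.5 * (g11 - g22)) ** 2 + g12 ** 2, 0.0))
    # conditioning gate plus an absolute structure gate: textureless regions
    # carry no displacement information and must not emit spurious solves
    ok = (det > lam_max ** 2 / _COND_LIMIT) & (lam_max > 1e-6 * lam_max.max())
    safe_det = np.where(ok, det, 1.0)
    du = np.where(ok, (g22 * h1 - g12 * h2) / safe_det, 0.0)
    dv = np.where(ok, (-g12 * h1 + g11 * h2) / safe_det, 0.0)
    return du, dv, ok.astype(np.float64)


def estimate_update(fixed_coeffs: dict, moving_coeffs: dict,
                    prior: DispField | None = None) -> DispField:
    """One displacement update from two coefficient grids.

    ``moving_coeffs`` is expected to come from the moving image already
    warped with ``prior`` (the update is estimated around the prior field);
    the returned field is ``prior`` plus the pointwise update.  Singular
    pixels receive zero update and zero certainty.
    """
    du, dv, cert = _solve_increment(fixed_coeffs, moving_coeffs)
    if prior is None:
        return DispField(du, dv, cert)
    return DispField(prior.u + du, prior.v + dv, cert)


# ---------------------------------------------------------------------------
# regularization
# ---------------------------------------------------------------------------


def _weighted_gauss(arr: np.ndarray, cert: np.ndarray, sigma: float) -> np.ndarray:
    """Normalized (certainty-weighted) Gaussian smoothing."""
    num = ndimage.gaussian_filter(arr * cert, sigma, mode="nearest")
    den = ndimage.gaussian_filter(cert, sigma, mode="nearest")
    return np.where(den > 1e-12, num / np.where(den > 1e-12, den, 1.0), 0.0)


def regularize_field(field: DispField, fluid_sigma: float = 0.0,
                     elastic_sigma: float = 0.0) -> DispField:
    """Fluid and/or elastic smoothing of a displacement field.

    Fluid smoothing is certainty-weighted (meant for incremental updates),
    elastic smoothing is a plain Gaussian on the accumulated field.  A sigma
    of zero is the identity for that term.
    """
    if fluid_sigma < 0 or elastic_sigma < 0:
        raise ValueError("regularization sigma must be non-negative")
    u, v = field.u, field.v
    if fluid_sigma > 0:
        u = _weighted_gauss(u, field.certainty, fluid_sigma)
        v = _weighted_gauss(v, field.certainty, fluid_sigma)
    if elastic_sigma > 0:
        u = ndimage.gaussian_filter(u, elastic_sigma, mode="nearest")
        v = ndimage.gaussian_filter(v, elastic_sigma, mode="nearest")
    return DispField(u, v, field.certainty)


# ---------------------------------------------------------------------------
# multiscale estimation
# ---------------------------------------------------------------------------


def _pyramid_shapes(shape: tuple[int, int], start_scale: int) -> list[tuple[int, int]]:
    shapes = []
    for s in range(start_scale, -1, -1):
        f = 2 ** s
        shapes.append((max(4, int(round(shape[0] / f))), max(4, int(round(shape[1] / f)))))
    return shapes


def _resize_img(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if img.shape == shape:
        return img
    return resize(img, shape, order=1, mode="reflect", anti_aliasing=True,
                  preserve_range=True)


def _effective_start_scale(shape: tuple[int, int], start_scale: int) -> int:
    s = start_scale
    while s > 0 and min(shape) // 2 ** s < 8:
        s -= 1
    if s != start_scale:
        warnings.warn(f"images too small for start scale {start_scale}; reduced to {s}")
    return s


def multiscale_register(fixed: np.ndarray, moving: np.ndarray,
                        schedule: RegSchedule | None = None,
                        _fixed_cache: dict | None = None) -> DispField:
    """Estimate the backward field registering ``moving`` onto ``fixed``.

    A coarse-to-fine pyramid from downsampling factor ``2**start_scale`` to
    full resolution, with ``iters_per_scale`` update/regularize iterations
    per level.  With composite accumulation enabled, each incremental update
    is composed with (rather than added to) the accumulated field.

    ``_fixed_cache`` allows reusing the fixed-image pyramid and expansions
    across calls that share the same fixed image.
    """
    schedule = schedule or RegSchedule()
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must have the same shape")
    start = _effective_start_scale(fixed.shape, schedule.start_scale)
    shapes = _pyramid_shapes(fixed.shape, start)

    if _fixed_cache is None:
        _fixed_cache = {}
    if "levels" not in _fixed_cache:
        _fixed_cache["levels"] = [
            polynomial_expansion(_resize_img(fixed, shp), schedule.window_sigma)
            for shp in shapes
        ]
    fixed_levels = _fixed_cache["levels"]

    fld: DispField | None = None
    for level, shp in enumerate(shapes):
        mv = _resize_img(moving, shp)
        if fld is None:
            fld = DispField.zero(shp)
        elif fld.shape != shp:
            ry = shp[0] / fld.shape[0]
            rx = shp[1] / fld.shape[1]
            u = resize(fld.u, shp, order=1, mode="edge", preserve_range=True) * ry
            v = resize(fld.v, shp, order=1, mode="edge", preserve_range=True) * rx
            fld = DispField(u, v)
        fcoef = fixed_levels[level]
        for _ in range(schedule.iters_per_scale):
            warped = warp(mv, fld)
            mcoef = polynomial_expansion(warped, schedule.window_sigma)
            du, dv, cert = _solve_increment_averaged(fcoef, mcoef,
                                                     schedule.fluid_sigma)
            # bound each incremental step: expansions are local models and
            # large jumps belong to coarser pyramid levels
            np.clip(du, -_MAX_STEP, _MAX_STEP, out=du)
            np.clip(dv, -_MAX_STEP, _MAX_STEP, out=dv)
            if schedule.composite_accumulation:
                fld = compose(fld, DispField(du, dv))
            else:
                fld = DispField(fld.u + du, fld.v + dv)
            # certainty-weighted elastic smoothing: structured regions anchor
            # the field and textureless interiors adopt the consensus of
            # their surroundings over the iterations
            w = cert + _ELASTIC_BASE_WEIGHT
            fld = DispField(_weighted_gauss(fld.u, w, schedule.elastic_sigma),
                            _weighted_gauss(fld.v, w, schedule.elastic_sigma),
                            cert)
    assert fld is not None
    return fld


# ---------------------------------------------------------------------------
# series-level scheduling
# ---------------------------------------------------------------------------


def register_series(series: FrameSeries, groups: np.ndarray,
                    schedule: RegSchedule | None = None
                    ) -> tuple[FrameSeries, list[DispField]]:
    """Register every frame of a series to a uniform respiratory state.

    ``direct`` mode registers each frame to the mean image of the reference
    respiratory group.  ``goreg`` mode first intra-registers the frames of
    each group to that group's mean image, then registers each group mean
    toward the reference group mean, and composes the two fields per frame.
    """
    schedule = schedule or RegSchedule()
    groups = np.asarray(groups)
    if groups.shape != (series.n_frames,):
        raise ValueError("groups must give one group id per frame")
    ref = schedule.reference_group
    ref_sel = groups == ref
    if not np.any(ref_sel):
        raise ValueError(f"reference group {ref} is empty")
    ref_img = series.data[ref_sel].mean(axis=0)

    fields: list[DispField] = []
    if schedule.mode == "direct":
        cache: dict = {}
        for t in range(series.n_frames):
            fields.append(multiscale_register(ref_img, series.data[t], schedule,
                                              _fixed_cache=cache))
    else:  # goreg
        group_ids = np.unique(groups)
        intra: dict[int, list] = {}
        inter: dict[int, DispField] = {}
        ref_cache: dict = {}
        for g in group_ids:
            sel = np.where(groups == g)[0]
            gmean = series.data[sel].mean(axis=0)
            gcache: dict = {}
            intra[g] = [multiscale_register(gmean, series.data[t], schedule,
                                            _fixed_cache=gcache) for t in sel]
            if g == ref:
                inter[g] = DispField.zero(series.shape)
            else:
                inter[g] = multiscale_register(ref_img, gmean, schedule,
                                               _fixed_cache=ref_cache)
        per_frame: list[DispField | None] = [None] * series.n_frames
        for g in group_ids:
            sel = np.where(groups == g)[0]
            for i, t in enumerate(sel):
                per_frame[t] = compose(intra[g][i], inter[g])
        fields = [f for f in per_frame if f is not None]

    registered = np.stack([warp(series.data[t], fields[t])
                           for t in range(series.n_frames)])
    out = series.copy_with(registered, registration=schedule.mode,
                           reference_group=ref)
    return out, fields


def apply_fields(series: FrameSeries, fields: list[DispField]) -> FrameSeries:
    """Warp every frame with a precomputed field (external-engine adapter path)."""
    if len(fields) != series.n_frames:
        raise ValueError("need one field per frame")
    registered = np.stack([warp(series.data[t], fields[t])
                           for t in range(series.n_frames)])
    return series.copy_with(registered, registration="precomputed")


class ExternalEngine:
    """Adapter contract for an external registration tool.

    Implementations take ``(fixed, moving)`` 2D arrays and return a
    :class:`DispField` in this package's backward-mapping convention; the
    series scheduling above can then be reused unchanged.
    """

    def register(self, fixed: np.ndarray, moving: np.ndarray) -> DispField:  # pragma: no cover
        raise NotImplementedError


def export_field(fld: DispField, path) -> None:
    """Write a field as a 2-component NIfTI (u, v stacked on the last axis)."""
    import nibabel as nib
    arr = np.stack([fld.u.T, fld.v.T], axis=-1)[:, :, None, :]
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))


def import_field(path) -> DispField:
    import nibabel as nib
    arr = np.asanyarray(nib.load(str(path)).dataobj)
    return DispField(arr[:, :, 0, 0].T, arr[:, :, 0, 1].T)
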