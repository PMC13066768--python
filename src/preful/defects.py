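"""Defect classification, defect percentages, and regional overlap.

Voxels are defective when RVent falls below 0.4 x its 90th percentile,
QQ below 0.15 x its 90th percentile, or FVL-CM below 0.90; percentiles are
taken within the parenchymal ROI (vessels excluded).  From the three
boolean maps the ventilation/perfusion defect percentages (VDP, QDP) and
the ventilation-perfusion match of nondefect regions (VQM) follow by voxel
counting, so VQM plus the any-defect percentage is exactly 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .resp_vent import ParamMap


@dataclass
class DefectSet:
    vd_rvent: np.ndarray
    vd_fvl: np.ndarray
    qd: np.ndarray
    roi: np.ndarray
    vdp_rvent: float = 0.0
    vdp_fvl: float = 0.0
    qdp: float = 0.0
    vqm: float = 0.0
    thresholds: dict = dc_field(default_factory=dict)

    def scalars(self) -> dict:
        return {"VDP_RVent": self.vdp_rvent, "VDP_FVL": self.vdp_fvl,
                "QDP": self.qdp, "VQM": self.vqm}


def classify_defects(rvent: ParamMap, fvlcm: ParamMap, qq: ParamMap,
                     roi: np.ndarray, rvent_factor: float = 0.4,
                     qq_factor: float = 0.15, fvlcm_min: float = 0.90
                     ) -> DefectSet:
    """Threshold the three parameter maps into defect maps and percentages."""
    roi = np.asarray(roi, bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    for m in (rvent, fvlcm, qq):
        if m.values.shape != roi.shape:
            raise ValueError("parameter maps and ROI must share a grid")

    p90_rv = np.nanpercentile(rvent.values[roi], 90)
    p90_qq = np.nanpercentile(qq.values[roi], 90)
    with np.errstate(invalid="ignore"):
        vd_rvent = roi & (rvent.values < rvent_factor * p90_rv)
        qd = roi & (qq.values < qq_factor * p90_qq)
        vd_fvl = roi & (fvlcm.values < fvlcm_min)

    pct = lambda m: 100.0 * int(m.sum()) / n_roi
    any_defect = vd_rvent | vd_fvl | qd
    return DefectSet(
        vd_rvent=vd_rvent, vd_fvl=vd_fvl, qd=qd, roi=roi,
        vdp_rvent=pct(vd_rvent), vdp_fvl=pct(vd_fvl), qdp=pct(qd),
        vqm=100.0 * int((roi & ~any_defect).sum()) / n_roi,
        thresholds={"rvent": rvent_factor * p90_rv, "qq": qq_factor * p90_qq,
                    "fvlcm": fvlcm_min},
    )


# ---------------------------------------------------------------------------
# regional overlap after affine alignment
# ---------------------------------------------------------------------------


def _mask_moments(mask: np.ndarray):
    pts = np.argwhere(mask).astype(np.float64)
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T) if len(pts) > 1 else np.eye(2)
    return c, np.atleast_2d(cov)


def _moment_transform(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Affine map (matrix, offset) sending mask A coordinates to mask B.

    Closed-form moment matching: centroids align the translation, the
    principal axes and their standard deviations fix rotation and
    anisotropic scale.  Eigenvector signs are fixed deterministically
    (largest component positive) so identical masks give the identity.
    """
    ca, cov_a = _mask_moments(mask_a)
    cb, cov_b = _mask_moments(mask_b)

    def decomp(cov):
        w, U = np.linalg.eigh(cov)
        w = np.maximum(w, 1e-6)
        for j in range(2):
            k = np.argmax(np.abs(U[:, j]))
            if U[k, j] < 0:
                U[:, j] = -U[:, j]
        return U, np.sqrt(w)

    Ua, sa = decomp(cov_a)
    Ub, sb = decomp(cov_b)
    M = Ub @ np.diag(sb) @ np.diag(1.0 / sa) @ Ua.T
    return M, cb - M @ ca


def regional_overlap(map_a: np.ndarray, map_b: np.ndarray,
                     mask_a: np.ndarray, mask_b: np.ndarray,
                     return_dice: bool = False):
    """Percent label agreement between two classifications after alignment.

    Map A is resampled (nearest neighbour) onto B's grid through the
    moment-matching affine transform of the masks; agreement counts voxels
    with identical defect labels over the intersection of the aligned
    masks.  With ``return_dice`` the Dice coefficient of the defect voxels
    is reported alongside.
    """
    map_a = np.asarray(map_a, bool)
    map_b = np.asarray(map_b, bool)
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)
    if not (mask_a.any() and mask_b.any()):
        raise ValueError("empty mask")
    if np.array_equal(mask_a, mask_b):
        inter = mask_b
        a_on_b, valid = map_a, mask_b
    else:
        M, off = _moment_transform(mask_a, mask_b)
        Minv = np.linalg.inv(M)
        yy, xx = np.mgrid[0: mask_b.shape[0], 0: mask_b.shape[1]]
        pts_b = np.stack([yy.ravel(), xx.ravel()]).astype(np.float64)
        pts_a = Minv @ (pts_b - off[:, None])
        coords = pts_a.reshape(2, *mask_b.shape)
        a_on_b = ndimage.map_coordinates(map_a.astype(np.uint8), coords,
                                         order=0, mode="constant") > 0
        valid = ndimage.map_coordinates(mask_a.astype(np.uint8), coords,
                                        order=0, mode="constant") > 0
        inter = valid & mask_b
    if not inter.any():
        raise ValueError("empty mask intersection after alignment")
    agree = 100.0 * int((a_on_b[inter] == map_b[inter]).sum()) / int(inter.sum())
    if not return_dice:
        return agree
    denom = int(a_on_b[inter].sum()) + int(map_b[inter].sum())
    dice = 2.0 * int((a_on_b & map_b & inter).sum()) / denom if denom else np.nan
    return agree, dice


def run_twice_consistency(run1: dict, run2: dict) -> dict:
    """Per-parameter correlation and overlap between two pipeline runs.

    ``run1``/``run2`` map parameter names to :class:`ParamMap` or
    :class:`DefectSet`-style boolean maps from two analyses of the same
    input.  With the deterministic engine both correlation and overlap are
    exactly 100 for every parameter.
    """
    report: dict[str, dict] = {}
    for name in run1:
        a, b = run1[name], run2[name]
        if isinstance(a, ParamMap):
            va = a.values[a.mask & np.isfinite(a.values) & np.isfinite(b.values)]
            vb = b.values[a.mask & np.isfinite(a.values) & np.isfinite(b.values)]
            if va.size < 3 or va.std() == 0 or vb.std() == 0:
                corr = 100.0 if np.array_equal(va, vb) else np.nan
            else:
                corr = 100.0 * float(np.corrcoef(va, vb)[0, 1])
            report[name] = {"correlation_pct": corr,
                            "identical": bool(np.array_equal(a.values[a.mask],
                                                             b.values[b.mask],
                                                             equal_nan=True))}
        else:
            a_arr, b_arr = np.asarray(a, bool), np.asarray(b, bool)
            overlap = 100.0 * int((a_arr == b_arr).sum()) / a_arr.size
            report[name] = {"overlap_pct": overlap,
                            "identical": bool(np.array_equal(a_arr, b_arr))}
    return report
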