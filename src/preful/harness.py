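"""End-to-end pipeline and the acquisition-time truncation study.

``run_pipeline`` chains the full analysis: respiratory grouping ->
registration to a uniform respiratory state -> guided denoising ->
ventilation/perfusion frequency split -> steady-state frame exclusion ->
diaphragm-based respiratory phases -> 60-phase ventilation cycle with
RVent and FVL-CM -> vessel-ROI cardiac phases -> 15-phase perfusion cycle
with amplitude and QQ -> defect classification.  Everything is
deterministic: identical inputs give bitwise-identical outputs.

``truncation_study`` reproduces the acquisition-time experiment: each
scan is truncated to a set of durations (55/45/30/15 s by default), the
reference duration is analyzed twice with the first analysis as ground
truth (GT), every truncation is compared against the GT with Wilcoxon,
Pearson and regional-overlap statistics, and scan-rescan repeatability is
summarized with ICC(A,1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import card_perf, defects as defects_mod, preprocess, resp_vent
from .io import FrameSeries, RunConfig
from .phantom import PhantomConfig, generate_phantom, scan_pair_configs
from .registration import DispField, RegSchedule, apply_fields, register_series
from .resp_vent import ParamMap
from .stats import ICCResult, PairedSample, icc_a1, pearson, wilcoxon_signed_rank

logger = logging.getLogger("preful")

PARAMETERS = ["RVent", "FVL-CM", "QQ", "VDP_RVent", "VDP_FVL", "QDP", "VQM"]
DEFECT_MAPS = ["VD_RVent", "VD_FVL", "QD"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    rvent: ParamMap
    fvlcm: ParamMap
    qamp: ParamMap
    qq: ParamMap
    defect_set: defects_mod.DefectSet
    scalars: dict
    meta: dict = dc_field(default_factory=dict)

    def defect_maps(self) -> dict[str, np.ndarray]:
        return {"VD_RVent": self.defect_set.vd_rvent,
                "VD_FVL": self.defect_set.vd_fvl,
                "QD": self.defect_set.qd}


@dataclass
class StudyDesign:
    durations: tuple = (55.0, 45.0, 30.0, 15.0)   # seconds, descending; [0] = reference
    double_run_reference: bool = True
    registrations: tuple = ("direct", "goreg")
    scans_per_subject: int = 2

    def __post_init__(self) -> None:
        if list(self.durations) != sorted(self.durations, reverse=True):
            raise ValueError("durations must be sorted descending (reference first)")

    @property
    def analyses_per_subject(self) -> int:
        per_reg = len(self.durations) + (1 if self.double_run_reference else 0)
        return per_reg * len(self.registrations)


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------


def truncate_series(series: FrameSeries, duration_s: float) -> FrameSeries:
    """Keep the first ``round(duration / dt)`` frames; ``dt`` unchanged."""
    n = int(round(duration_s / series.dt))
    if n > series.n_frames:
        raise ValueError(f"requested {duration_s} s ({n} frames) but series has "
                         f"only {series.n_frames} frames")
    out = series.copy_with(series.data[:n], truncated_to_s=duration_s)
    out.frame_valid = series.frame_valid[:n].copy()
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _diaphragm_band(lung_mask: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Column band through the thickest part of one lung, plus a row search range."""
    H, W = lung_mask.shape
    depth = lung_mask.sum(axis=0)
    left = depth[: W // 2]
    col = int(np.argmax(left)) if left.max() > 0 else int(np.argmax(depth))
    band = np.arange(max(0, col - 2), min(W, col + 3))
    rows = np.where(lung_mask.any(axis=1))[0]
    lo = int(0.5 * (rows[0] + rows[-1]))
    return band, (lo, H - 2)


def run_pipeline(series: FrameSeries, masks: dict, config: RunConfig | None = None,
                 truth_fields: list[DispField] | None = None) -> PipelineResult:
    """Run the full analysis on one 2D+t series.

    ``masks`` must provide boolean ``lung``, ``vessel`` and ``parenchyma``
    maps in the registered (reference respiratory state) geometry.  With
    ``truth_fields`` the registration stage warps with the supplied
    per-frame fields instead of estimating them (phantom ground-truth
    path, or an external engine's output through the adapter).
    """
    cfg = config or RunConfig()
    parenchyma = np.asarray(masks["parenchyma"], bool)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage '{name}': {exc}") from exc
                return False
        return _Ctx()

    with stage("respiratory_grouping"):
        resp = resp_vent.respiratory_grouping(series, n_groups=cfg.n_resp_groups,
                                              cutoff_hz=cfg.cutoff_hz)
    with stage("registration"):
        if truth_fields is not None:
            registered = apply_fields(series, truth_fields[: series.n_frames])
        else:
            sched = RegSchedule(mode=cfg.reg_mode, reference_group=cfg.reference_group,
                                start_scale=cfg.start_scale,
                                iters_per_scale=cfg.iters_per_scale,
                                fluid_sigma=cfg.fluid_sigma,
                                elastic_sigma=cfg.elastic_sigma,
                                window_sigma=cfg.window_sigma)
            registered, _ = register_series(series, resp.group, sched)
    with stage("guided_denoise"):
        denoised = preprocess.guided_denoise(registered, radius=cfg.guided_radius)
    with stage("split_frequencies"):
        branches = preprocess.split_frequencies(denoised, cutoff_hz=cfg.cutoff_hz,
                                                order=cfg.filter_order)
    with stage("drop_steady_state"):
        vent = preprocess.drop_steady_state(branches.vent_series, cfg.steady_state_skip)
        perf = preprocess.drop_steady_state(branches.perf_series, cfg.steady_state_skip)
    with stage("diaphragm_phase"):
        band, row_range = _diaphragm_band(masks["lung"])
        dia = resp_vent.diaphragm_signal(series, band, row_range)
        sig = -dia[cfg.steady_state_skip:]          # end-expiration = maximum
        included = resp_vent.exclude_outliers(sig, cfg.outlier_lo_pct,
                                              cfg.outlier_hi_pct)
        phases = resp_vent.cosine_phase_map(sig, included)
    with stage("ventilation_cycle"):
        cycle = resp_vent.kernel_cycle(
            vent.data, phases, n_phases=cfg.n_resp_phases,
            bandwidth=cfg.kernel_bandwidth_factor / cfg.n_resp_phases)
        rvent = resp_vent.compute_rvent(cycle, parenchyma)
        fvlcm, ref_mask = resp_vent.compute_fvlcm(
            cycle, rvent, parenchyma,
            band=(cfg.reference_band_lo, cfg.reference_band_hi))
    with stage("vessel_roi"):
        std_map = card_perf.perfusion_weighted_map(perf)
        vessel_roi = card_perf.select_vessel_roi(
            std_map, perf, n_seeds=cfg.vessel_seed_count,
            top_frac=cfg.vessel_seed_top_frac, size_cap=cfg.vessel_roi_cap,
            r2_patience=cfg.vessel_r2_patience, search_mask=masks["lung"])
    with stage("cardiac_phase"):
        roi_sig = perf.data[:, vessel_roi].mean(axis=1)
        card = card_perf.fit_piecewise_sinusoid(roi_sig, perf.dt)
    with stage("perfusion_cycle"):
        pcycle = card_perf.perf_cycle(
            perf, card, n_phases=cfg.n_card_phases,
            bandwidth=cfg.kernel_bandwidth_factor / cfg.n_card_phases)
        qamp = card_perf.perfusion_amplitude(
            pcycle, parenchyma, method=cfg.parenchymal_phase_method,
            bins=cfg.histogram_bins)
    with stage("quantified_perfusion"):
        qq = card_perf.compute_qq(branches.transient_series, qamp, card,
                                  blood_roi=masks["vessel"], scale=cfg.qq_scale)
    with stage("defect_classification"):
        dset = defects_mod.classify_defects(
            rvent, fvlcm, qq, parenchyma, rvent_factor=cfg.rvent_factor,
            qq_factor=cfg.qq_factor, fvlcm_min=cfg.fvlcm_min)

    scalars = {
        "RVent": float(np.nanmedian(rvent.values[parenchyma])),
        "FVL-CM": 100.0 * float(np.nanmedian(fvlcm.values[parenchyma])),
        "QQ": float(np.nanmedian(qq.values[parenchyma])),
        **dset.scalars(),
    }
    meta = {"n_frames": series.n_frames, "dt": series.dt,
            "heart_rate_bpm": card.heart_rate_bpm,
            "vessel_roi_size": int(vessel_roi.sum()),
            "reference_region_size": int(ref_mask.sum()),
            "registration": "truth" if truth_fields is not None else cfg.reg_mode}
    return PipelineResult(rvent=rvent, fvlcm=fvlcm, qamp=qamp, qq=qq,
                          defect_set=dset, scalars=scalars, meta=meta)


# ---------------------------------------------------------------------------
# synthetic cohort
# ---------------------------------------------------------------------------


def make_cohort(n_subjects: int, seed: int = 1,
                base_config: PhantomConfig | None = None,
                scans_per_subject: int = 2) -> list[dict]:
    """Generate a phantom cohort: per subject, 1-2 scans with shared anatomy.

    Returns a list of ``{"subject": id, "scans": [(series, truth), ...]}``.
    Subject seeds derive from one seed sequence, so the cohort is fully
    reproducible and adding subjects never changes existing ones.
    """
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    cohort = []
    for i, child in enumerate(children):
        subject_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg1, cfg2 = scan_pair_configs(subject_seed, base_config)
        scans = [generate_phantom(cfg1)]
        if scans_per_subject > 1:
            scans.append(generate_phantom(cfg2))
        cohort.append({"subject": f"S{i + 1:02d}", "scans": scans})
    return cohort


def masks_from_truth(truth) -> dict:
    return {"lung": truth.lung_mask, "vessel": truth.vessel_mask,
            "parenchyma": truth.parenchyma_mask}


# ---------------------------------------------------------------------------
# truncation study
# ---------------------------------------------------------------------------


@dataclass
class StudyResult:
    values: pd.DataFrame        # subject, scan, duration, registration, parameter, value
    comparisons: pd.DataFrame   # vs GT: wilcoxon_p, pearson_r_pct per duration/reg/param
    overlaps: pd.DataFrame      # per-subject regional overlap vs GT per defect map
    icc: pd.DataFrame           # scan-rescan ICC per duration/reg/param


def _analysis_labels(design: StudyDesign) -> list[tuple[str, float]]:
    labels = [("GT", design.durations[0])]
    if design.double_run_reference:
        labels.append((f"{design.durations[0]:g}", design.durations[0]))
    labels += [(f"{d:g}", d) for d in design.durations[1:]]
    return labels


def truncation_study(cohort: list[dict], design: StudyDesign | None = None,
                     config: RunConfig | None = None) -> StudyResult:
    """Run the full truncation experiment on a cohort and tabulate statistics."""
    design = design or StudyDesign()
    cfg = config or RunConfig()
    labels = _analysis_labels(design)

    rows, overlap_rows = [], []
    results: dict[tuple, PipelineResult] = {}
    for subj in cohort:
        for scan_no, (series, truth) in enumerate(subj["scans"], start=1):
            masks = masks_from_truth(truth)
            for reg in design.registrations:
                run_cfg = RunConfig(**{**cfg.to_dict(), "reg_mode": reg})
                for label, dur in labels:
                    trunc = truncate_series(series, dur)
                    res = run_pipeline(trunc, masks, run_cfg)
                    key = (subj["subject"], scan_no, reg, label)
                    results[key] = res
                    for p in PARAMETERS:
                        rows.append({"subject": subj["subject"], "scan": scan_no,
                                     "duration_s": label, "registration": reg,
                                     "parameter": p, "value": res.scalars[p]})
                gt = results[(subj["subject"], scan_no, reg, "GT")]
                for label, _ in labels[1:]:
                    res = results[(subj["subject"], scan_no, reg, label)]
                    for map_name in DEFECT_MAPS:
                        ov = defects_mod.regional_overlap(
                            res.defect_maps()[map_name], gt.defect_maps()[map_name],
                            res.defect_set.roi, gt.defect_set.roi)
                        overlap_rows.append({"subject": subj["subject"],
                                             "scan": scan_no,
                                             "duration_s": label,
                                             "registration": reg,
                                             "map": map_name, "overlap_pct": ov})

    values = pd.DataFrame(rows)
    overlaps = pd.DataFrame(overlap_rows)

    comp_rows = []
    for reg in design.registrations:
        for label, _ in labels[1:]:
            for p in PARAMETERS:
                gt_vals, vals = [], []
                for subj in cohort:
                    gt_vals.append(results[(subj["subject"], 1, reg, "GT")].scalars[p])
                    vals.append(results[(subj["subject"], 1, reg, label)].scalars[p])
                gt_vals, vals = np.array(gt_vals), np.array(vals)
                row = {"duration_s": label, "registration": reg, "parameter": p,
                       "median": float(np.median(vals))}
                if len(vals) >= 5:
                    sample = PairedSample(vals, gt_vals, label=p)
                    row["wilcoxon_p"] = wilcoxon_signed_rank(sample)
                    if np.array_equal(vals, gt_vals):
                        row["pearson_r_pct"] = 100.0
                    elif vals.std() > 0 and gt_vals.std() > 0:
                        row["pearson_r_pct"] = 100.0 * pearson(sample)[0]
                    else:
                        row["pearson_r_pct"] = np.nan
                comp_rows.append(row)
    comparisons = pd.DataFrame(comp_rows)

    icc_rows = []
    if design.scans_per_subject >= 2 and all(len(s["scans"]) >= 2 for s in cohort):
        for reg in design.registrations:
            for label, _ in labels:
                for p in PARAMETERS:
                    mat = np.array([
                        [results[(s["subject"], 1, reg, label)].scalars[p],
                         results[(s["subject"], 2, reg, label)].scalars[p]]
                        for s in cohort])
                    if len(mat) < 5 or np.allclose(mat, mat.mean()):
                        continue
                    r: ICCResult = icc_a1(mat)
                    icc_rows.append({"duration_s": label, "registration": reg,
                                     "parameter": p, "icc_pct": 100.0 * r.icc,
                                     "ci_lo_pct": 100.0 * r.ci_lo,
                                     "ci_hi_pct": 100.0 * r.ci_hi})
    else:
        if design.scans_per_subject >= 2:
            warnings.warn("missing second scans; ICC rows skipped")
    icc = pd.DataFrame(icc_rows)
    return StudyResult(values=values, comparisons=comparisons,
                       overlaps=overlaps, icc=icc)
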