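"""End-to-end orchestration: sessions in, hypothesis report out.

Thin glue over the analysis modules; every step here is individually
exposed and tested in its own module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from alertfmri.bold_synth import BoldSession, SubjectRecord
from alertfmri.glm import ActivationMap, GroupMap, beta_to_psc, fit_glm, group_map, smooth_volume
from alertfmri.roigrid import (
    NetworkSignal,
    RoiGrid,
    assign_networks,
    network_mean,
    roi_mean_psc,
    select_rois,
)
from alertfmri.stats_report import HypothesisReport, run_main_hypotheses
from alertfmri.taskdesign import DesignMatrix, TaskDesign, build_design_matrix

__all__ = ["CohortResult", "fit_first_level", "analyze_cohort"]


@dataclass
class CohortResult:
    group_cue: GroupMap
    selected: list[int]
    network_of: dict[int, str]
    signals: list[NetworkSignal]
    report: HypothesisReport | None


def fit_first_level(
    session: BoldSession,
    design: TaskDesign,
    dm: DesignMatrix | None = None,
    smoothing_fwhm_mm: float = 0.0,
) -> ActivationMap:
    """Optionally smooth, fit the GLM, and attach PSC maps."""
    if dm is None:
        dm = build_design_matrix(design, tr_s=session.tr_s, n_timepoints=session.n_timepoints)
    if smoothing_fwhm_mm > 0:
        session = BoldSession(
            data=smooth_volume(session.data, smoothing_fwhm_mm, session.voxel_size_mm),
            tr_s=session.tr_s,
            voxel_size_mm=session.voxel_size_mm,
            affine=session.affine,
            brain_mask=session.brain_mask,
        )
    amap = fit_glm(session, dm)
    return beta_to_psc(amap, session)


def analyze_cohort(
    subjects: list[tuple[BoldSession, SubjectRecord]],
    design: TaskDesign,
    grid: RoiGrid,
    t_threshold: float = 4.0,
    alpha: float = 0.05,
    smoothing_fwhm_mm: float = 0.0,
    selection_regressor: str = "CUE",
    run_report: bool = True,
    network_of: dict[int, str] | None = None,
) -> CohortResult:
    """Full second-level flow on an already-generated cohort.

    Fits every subject, builds the group map on the selection regressor,
    selects hotspot ROIs (threshold + mirror rule), allocates networks by
    group PSC sign, computes per-subject network means, and runs the
    conditional-Bonferroni hypothesis battery.
    """
    dm = build_design_matrix(
        design, tr_s=subjects[0][0].tr_s, n_timepoints=subjects[0][0].n_timepoints
    )
    amaps = [
        fit_first_level(sess, design, dm=dm, smoothing_fwhm_mm=smoothing_fwhm_mm)
        for sess, _ in subjects
    ]
    group = group_map(amaps, selection_regressor)
    if network_of is None:
        selected = select_rois(group, grid, t_threshold=t_threshold)
        if not selected:
            return CohortResult(group, [], {}, [], None)
        network_of = assign_networks(selected, group, grid)
    else:
        selected = sorted(network_of)

    signals = []
    for amap, (_, record) in zip(amaps, subjects):
        per_roi = roi_mean_psc(amap, grid, selection_regressor)
        sig = network_mean(
            {rid: per_roi[rid] for rid in network_of},
            network_of,
            subject_id=record.subject_id,
        )
        record.network_signal = sig
        signals.append(sig)

    report = None
    if run_report:
        scores = [rec.scores for _, rec in subjects]
        groups = {rec.subject_id: rec.group for _, rec in subjects}
        report = run_main_hypotheses(
            signals, scores, alpha=alpha, groups=groups, network_of=network_of
        )
    return CohortResult(group, selected, network_of, signals, report)
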