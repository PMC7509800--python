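"""Rank-correlation inference with the two-main-test correction scheme.

Two main hypotheses — fatigue total vs CEN signal and fatigue total vs DMN
signal — are each judged at a Bonferroni-corrected alpha/2.  Follow-ups
(per fatigue domain, per patient subgroup, per member ROI) of a significant
main test are read as elaborations and stay uncorrected; follow-ups of a
non-significant main test are post-hoc and Bonferroni-corrected within
their family (all follow-ups of one main test form one family).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from alertfmri.errors import (
    AlignmentError,
    ConfigurationError,
    MissingDataError,
    ValidationError,
)
from alertfmri.mfi import DOMAINS, MfiScores
from alertfmri.roigrid import NetworkSignal, RoiGrid

__all__ = [
    "CorrelationResult",
    "HypothesisReport",
    "spearman",
    "run_main_hypotheses",
    "per_roi_correlations",
    "build_report",
]


@dataclass(frozen=True)
class CorrelationResult:
    """One Spearman test, reported in the ``r(df)`` convention (df = n − 2)."""

    rho: float
    n: int
    p: float
    role: str  # main | followup | posthoc
    alpha_effective: float
    label: str = ""

    @property
    def df(self) -> int:
        return self.n - 2

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_effective

    def __str__(self) -> str:  # e.g. "r(61) = 0.47, p < 0.001"
        ptxt = "p < 0.001" if self.p < 0.001 else f"p = {self.p:.3f}"
        return f"r({self.df}) = {self.rho:.3g}, {ptxt}"


@dataclass
class HypothesisReport:
    main_results: dict[str, CorrelationResult]  # "CEN", "DMN"
    followups: dict[str, list[CorrelationResult]]  # keyed by main test
    alpha: float
    correction_note: str = ""

    def any_significant_main(self) -> bool:
        return any(r.significant for r in self.main_results.values())


def spearman(
    x,
    y,
    role: str = "main",
    alpha_effective: float = 0.05,
    label: str = "",
    method: str = "t",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman rank correlation with average-rank tie handling.

    rho is the Pearson correlation of the rank vectors; the two-sided p
    comes from the t approximation at df = n − 2 (``method="t"``) or from a
    seeded permutation null (``method="permutation"``, for small n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValidationError(f"need n >= 3 observations, got {n}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise MissingDataError("missing values are not allowed in correlation inputs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("rank correlation undefined for a constant input vector")

    rx = _st.rankdata(x)
    ry = _st.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * _st.t.sf(abs(t), df=n - 2))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            null[i] = np.corrcoef(rx, rng.permutation(ry))[0, 1]
        p = float((np.sum(np.abs(null) >= abs(rho) - 1e-12) + 1) / (n_permutations + 1))
    else:
        raise ConfigurationError(f"unknown p-value method {method!r}")

    return CorrelationResult(
        rho=rho, n=n, p=p, role=role, alpha_effective=alpha_effective, label=label
    )


def _spearman_or_flag(x, y, role, alpha_effective, label) -> CorrelationResult:
    """Degenerate (constant) inputs yield a flagged NaN result, not a crash."""
    try:
        return spearman(x, y, role=role, alpha_effective=alpha_effective, label=label)
    except ValidationError:
        return CorrelationResult(
            rho=float("nan"),
            n=len(x),
            p=float("nan"),
            role=role,
            alpha_effective=alpha_effective,
            label=label + " [flagged: constant input]",
        )


def _align(
    signals: list[NetworkSignal], scores: list[MfiScores]
) -> tuple[list[NetworkSignal], list[MfiScores]]:
    sig_ids = {s.subject_id for s in signals}
    score_ids = {s.subject_id for s in scores}
    if sig_ids != score_ids:
        raise AlignmentError(sig_ids ^ score_ids)
    order = sorted(sig_ids)
    sig_by = {s.subject_id: s for s in signals}
    score_by = {s.subject_id: s for s in scores}
    return [sig_by[i] for i in order], [score_by[i] for i in order]


def run_main_hypotheses(
    signals: list[NetworkSignal],
    scores: list[MfiScores],
    alpha: float = 0.05,
    groups: dict[str, str] | None = None,
    network_of: dict[int, str] | None = None,
) -> HypothesisReport:
    """Run both main tests and their conditionally corrected follow-ups.

    ``groups`` (subject_id → subgroup label) enables subgroup follow-ups;
    ``network_of`` (roi_id → network) enables per-ROI follow-ups.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    signals, scores = _align(signals, scores)
    total = np.array([s.mfi_total for s in scores], dtype=float)
    net_values = {
        "CEN": np.array([s.cen_psc for s in signals]),
        "DMN": np.array([s.dmn_psc for s in signals]),
    }

    n_mains = 2
    mains = {
        nw: spearman(
            net_values[nw],
            total,
            role="main",
            alpha_effective=alpha / n_mains,
            label=f"MFI-total vs {nw}",
        )
        for nw in ("CEN", "DMN")
    }

    followups: dict[str, list[CorrelationResult]] = {}
    notes = [f"main tests at alpha/{n_mains} = {alpha / n_mains:g}"]
    for nw, main in mains.items():
        family: list[tuple[str, np.ndarray, np.ndarray]] = []
        for domain in DOMAINS:
            dom = np.array([s.domain(domain) for s in scores], dtype=float)
            family.append((f"{domain} vs {nw}", net_values[nw], dom))
        if groups is not None:
            labels = sorted({groups[s.subject_id] for s in signals})
            for g in labels:
                idx = [i for i, s in enumerate(signals) if groups[s.subject_id] == g]
                if len(idx) >= 3:
                    family.append(
                        (
                            f"MFI-total vs {nw} [{g}]",
                            net_values[nw][idx],
                            total[idx],
                        )
                    )
        if network_of is not None:
            for rid in sorted(r for r, n in network_of.items() if n == nw):
                roi_vals = np.array([s.per_roi_psc[rid] for s in signals])
                family.append((f"MFI-total vs ROI {rid} [{nw}]", roi_vals, total))

        if main.significant:
            role, alpha_eff = "followup", alpha
            notes.append(f"{nw} main significant: follow-ups uncorrected at {alpha:g}")
        else:
            role = "posthoc"
            alpha_eff = alpha / max(len(family), 1)
            notes.append(
                f"{nw} main not significant: {len(family)} follow-ups "
                f"Bonferroni-corrected to {alpha_eff:g}"
            )
        followups[nw] = [
            _spearman_or_flag(xv, yv, role, alpha_eff, lab) for lab, xv, yv in family
        ]

    return HypothesisReport(
        main_results=mains,
        followups=followups,
        alpha=alpha,
        correction_note="; ".join(notes),
    )


def per_roi_correlations(
    per_roi_tables: dict[int, np.ndarray],
    mfi_totals: np.ndarray,
    network_of: dict[int, str],
    alpha_effective: float = 0.05,
    role: str = "followup",
) -> list[CorrelationResult]:
    """MFI-total vs ROI PSC for each selected ROI, strongest |rho| first."""
    results = []
    for rid in sorted(per_roi_tables):
        res = spearman(
            per_roi_tables[rid],
            mfi_totals,
            role=role,
            alpha_effective=alpha_effective,
            label=f"ROI {rid} [{network_of.get(rid, 'none')}]",
        )
        results.append(res)
    return sorted(results, key=lambda r: -abs(r.rho))


def _result_row(r: CorrelationResult) -> dict:
    return {
        "label": r.label,
        "rho": r.rho,
        "n": r.n,
        "df": r.df,
        "p": r.p,
        "role": r.role,
        "alpha_effective": r.alpha_effective,
        "significant": r.significant,
    }


def build_report(
    report: HypothesisReport,
    group,
    grid: RoiGrid,
    out_dir: str | Path,
    signals: list[NetworkSignal] | None = None,
    scores: list[MfiScores] | None = None,
    groups: dict[str, str] | None = None,
    overlap_per_roi: dict[int, float] | None = None,
    manifest: dict | None = None,
) -> Path:
    """Write the report bundle (CSV tables + JSON manifest) to ``out_dir``.

    Raises ConfigurationError after writing an explicit stanza when no ROIs
    were selected, so callers can exit nonzero.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if not grid.network_of:
        (out / "NO_ROIS_SELECTED.txt").write_text(
            "no ROIs crossed the selection threshold; no report generated\n"
        )
        raise ConfigurationError("no ROIs selected")

    # per-ROI table (mean, SEM, T, p, overlap) over selected ROIs
    rows = []
    from alertfmri.roigrid import _roi_mean  # reuse the averaging kernel

    for rid in sorted(grid.network_of):
        roi = grid.roi(rid)
        rows.append(
            {
                "roi_id": rid,
                "network": grid.network_of[rid],
                "center_x_mm": roi.center_mm[0],
                "center_y_mm": roi.center_mm[1],
                "center_z_mm": roi.center_mm[2],
                "n_voxels": roi.n_voxels,
                "mean_psc": _roi_mean(group.mean_psc, roi),
                "sem": _roi_mean(group.sem, roi),
                "t": _roi_mean(group.t, roi),
                "p": _roi_mean(group.p, roi),
                "tumor_overlap_pct": (overlap_per_roi or {}).get(rid, np.nan),
            }
        )
    pd.DataFrame(rows).to_csv(out / "roi_table.csv", index=False)

    # network-level correlation table: mains + follow-ups
    corr_rows = [_result_row(r) for r in report.main_results.values()]
    for fam in report.followups.values():
        corr_rows.extend(_result_row(r) for r in fam)
    pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)

    if signals is not None and scores is not None:
        score_by = {s.subject_id: s for s in scores}
        scatter = pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "group": (groups or {}).get(s.subject_id, ""),
                    "cen_psc": s.cen_psc,
                    "dmn_psc": s.dmn_psc,
                    "mfi_total": score_by[s.subject_id].mfi_total,
                }
                for s in sorted(signals, key=lambda s: s.subject_id)
            ]
        )
        scatter.to_csv(out / "network_scatter.csv", index=False)

    payload = {
        "alpha": report.alpha,
        "correction_note": report.correction_note,
        "n_subjects": group.n_subjects,
        "n_selected_rois": len(grid.network_of),
    }
    if manifest:
        payload.update(manifest)
    (out / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return out
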