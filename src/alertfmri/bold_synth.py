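"""Synthetic BOLD cohorts with planted network effects and fatigue coupling.

The forward model mirrors the GLM's assumptions: each in-mask voxel carries
a constant baseline modulated multiplicatively by (i) planted task
responses — positive in "CEN" seed ROIs, negative in "DMN" seed ROIs, on
the same unit-peak regressors the GLM fits — (ii) a slow cosine drift, and
(iii) AR(1) temporal noise.  Cohorts plant a target rank correlation
between the per-subject DMN amplitude and the MFI total via a Gaussian
copula, while CEN amplitudes stay independent of fatigue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy import stats as _st

from alertfmri.errors import ConfigurationError, GeometryError
from alertfmri.mfi import (
    DOMAINS,
    MfiKey,
    MfiResponse,
    MfiScores,
    default_key,
    score_mfi,
)
from alertfmri.roigrid import RoiGrid, build_roi_grid, voxel_centers_mm
from alertfmri.taskdesign import DesignMatrix, TaskDesign, build_design_matrix

__all__ = [
    "BASELINE_SIGNAL",
    "BoldSession",
    "CohortSpec",
    "TumorMask",
    "SubjectRecord",
    "make_brain_geometry",
    "default_grid",
    "plant_networks",
    "synthesize_session",
    "synthesize_cohort",
    "simulate_tumor_mask",
    "synthesize_behavior",
    "decompose_mfi_total",
]

#: Baseline signal level in arbitrary units; makes PSC arithmetic legible.
BASELINE_SIGNAL = 1000.0

GROUP_LABELS = ("MG", "LGG", "HGG")


@dataclass
class BoldSession:
    """One subject's 4D acquisition on an axis-aligned grid."""

    data: np.ndarray  # (x, y, z, t), signal units
    tr_s: float
    voxel_size_mm: float
    affine: np.ndarray
    brain_mask: np.ndarray

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth parameters of a synthetic cohort."""

    n_subjects: int = 63
    planted_rho: float = 0.47
    cen_amplitude_pct: float = 0.10
    dmn_amplitude_pct: float = -0.20
    cen_amplitude_spread_pct: float = 0.10
    dmn_amplitude_spread_pct: float = 0.15
    noise_sd_pct: float = 1.0
    ar1_coef: float = 0.3
    drift_amplitude_pct: float = 0.5
    drift_period_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.planted_rho <= 1.0:
            raise ConfigurationError("planted_rho must lie in [-1, 1]")
        if self.noise_sd_pct < 0:
            raise ConfigurationError("noise_sd_pct must be >= 0")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ConfigurationError("ar1_coef must lie in [0, 1)")


@dataclass(frozen=True)
class TumorMask:
    mask: np.ndarray  # 3D boolean, session-aligned
    voxel_size_mm: float

    @property
    def volume_cm3(self) -> float:
        return int(np.count_nonzero(self.mask)) * self.voxel_size_mm**3 / 1000.0


@dataclass
class SubjectRecord:
    """Per-subject ground truth and derived measurements."""

    subject_id: str
    group: str  # MG | LGG | HGG
    response: MfiResponse
    scores: MfiScores
    true_cen_amplitude_pct: float
    true_dmn_amplitude_pct: float
    behavior: pd.DataFrame | None = None
    tumor: TumorMask | None = None
    network_signal: object | None = None  # filled by the analysis pipeline


def make_brain_geometry(
    shape: tuple[int, int, int] = (20, 20, 20), voxel_size_mm: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """A reduced-extent box brain centered on the origin.

    The affine places voxel centers symmetrically about 0 on every axis so
    that x = 0 is a 15-mm grid plane and cubes fill the box exactly when
    each dimension spans a whole number of cubes.
    """
    mask = np.ones(shape, dtype=bool)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size_mm
    for ax in range(3):
        affine[ax, 3] = -(shape[ax] * voxel_size_mm) / 2.0 + voxel_size_mm / 2.0
    return mask, affine


def default_grid(
    shape: tuple[int, int, int] = (20, 20, 20),
    voxel_size_mm: float = 3.0,
    edge_mm: float = 15.0,
) -> RoiGrid:
    mask, affine = make_brain_geometry(shape, voxel_size_mm)
    return build_roi_grid(mask, affine, edge_mm=edge_mm, origin_mm=(0.0, 0.0, 0.0))


def plant_networks(grid: RoiGrid, n_pairs_per_network: int = 1) -> RoiGrid:
    """Deterministically seed CEN and DMN onto mirror ROI pairs.

    CEN pairs are taken from the most anterior (largest y) lateralized
    mirror pairs, DMN pairs from the most posterior, echoing the
    front-executive / posterior-deactivation layout.
    """
    by_center = {r.center_mm: r.roi_id for r in grid.rois}
    pairs = []
    for r in grid.rois:
        cx, cy, cz = r.center_mm
        if cx >= 0:
            continue
        mirror = by_center.get((-cx, cy, cz))
        if mirror is not None:
            pairs.append(((cy, cz, cx), r.roi_id, mirror))
    pairs.sort(reverse=True)
    if len(pairs) < 2 * n_pairs_per_network:
        raise GeometryError(
            f"grid has only {len(pairs)} mirror pairs; need "
            f"{2 * n_pairs_per_network} to seed both networks"
        )
    network_of: dict[int, str] = {}
    for _, a, b in pairs[:n_pairs_per_network]:
        network_of[a] = network_of[b] = "CEN"
    for _, a, b in pairs[-n_pairs_per_network:]:
        network_of[a] = network_of[b] = "DMN"
    grid.network_of = network_of
    return grid


def _ar1_noise(
    rng: np.random.Generator, n_series: int, n_t: int, sd: float, ar1: float
) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd``, shape (n_series, n_t)."""
    if sd == 0:
        return np.zeros((n_series, n_t))
    innov = rng.standard_normal((n_series, n_t)) * sd * np.sqrt(1.0 - ar1**2)
    x0 = rng.standard_normal(n_series) * sd
    if ar1 == 0:
        noise = innov
        noise[:, 0] = x0
        return noise
    # lfilter with initial condition x[-1] = x0 keeps the series stationary
    zi = (ar1 * x0)[:, None]
    noise, _ = _sig.lfilter([1.0], [1.0, -ar1], innov, axis=-1, zi=zi)
    noise[:, 0] = ar1 * x0 + innov[:, 0]
    return noise


def synthesize_session(
    design: TaskDesign,
    spec: CohortSpec,
    subject_effects: dict[str, dict[str, float]],
    grid: RoiGrid,
    seed: int,
    tr_s: float = 2.0,
    n_timepoints: int | None = None,
    dm: DesignMatrix | None = None,
) -> BoldSession:
    """Generate one subject's 4D session on the grid's geometry.

    ``subject_effects`` maps network label → {regressor name → amplitude in
    % of baseline}; voxels outside seeded ROIs carry no task effect.
    """
    if dm is None:
        dm = build_design_matrix(design, tr_s=tr_s, n_timepoints=n_timepoints)
    n_t = dm.n_timepoints
    shape = grid.shape
    mask = np.zeros(shape, dtype=bool)
    for roi in grid.rois:
        ijk = roi.voxel_indices
        mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True

    for network in subject_effects:
        if network not in set(grid.network_of.values()):
            raise GeometryError(
                f"network {network!r} has no seeded ROIs in the grid"
            )

    rng = np.random.default_rng(seed)
    n_vox = int(mask.sum())
    rel = np.zeros((n_vox, n_t))  # relative modulation around baseline

    # planted task responses on the same unit-peak regressors the GLM fits
    flat_network = np.full(n_vox, "", dtype=object)
    lin = np.zeros(shape, dtype=int)
    lin[mask] = np.arange(n_vox)
    for rid, network in grid.network_of.items():
        ijk = grid.roi(rid).voxel_indices
        flat_network[lin[ijk[:, 0], ijk[:, 1], ijk[:, 2]]] = network
    # Planted components are temporally mean-centered so the voxel temporal
    # mean stays at baseline and the PSC convention (beta / temporal mean)
    # inverts the forward model exactly in the noiseless case.
    for network, amps in subject_effects.items():
        rows = flat_network == network
        if not rows.any():
            continue
        for regressor, amp_pct in amps.items():
            col = dm.column(regressor)
            rel[rows] += (amp_pct / 100.0) * (col - col.mean())[None, :]

    if spec.drift_amplitude_pct > 0:
        t = np.arange(n_t) * tr_s
        phase = rng.uniform(0, 2 * np.pi, size=n_vox)
        drift = (spec.drift_amplitude_pct / 100.0) * np.cos(
            2 * np.pi * t[None, :] / spec.drift_period_s + phase[:, None]
        )
        rel += drift - drift.mean(axis=-1, keepdims=True)
    if spec.noise_sd_pct > 0:
        rel += _ar1_noise(rng, n_vox, n_t, spec.noise_sd_pct / 100.0, spec.ar1_coef)

    data = np.zeros(shape + (n_t,))
    data[mask] = BASELINE_SIGNAL * (1.0 + rel)
    return BoldSession(
        data=data,
        tr_s=tr_s,
        voxel_size_mm=grid.voxel_size_mm,
        affine=grid.affine,
        brain_mask=mask,
    )


def draw_cohort_parameters(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (dmn_amplitude_pct, cen_amplitude_pct, mfi_total) per subject.

    A Gaussian copula links the DMN amplitude to the MFI total: the latent
    Pearson correlation is ``2 sin(pi * rho / 6)`` so that the rank
    correlation of the (continuous) marginals equals ``planted_rho``; the
    integer MFI support then bounds the achievable value slightly below
    |rho| = 1 through ties.
    """
    if abs(spec.planted_rho) == 1.0:
        warnings.warn(
            "planted_rho = ±1 cannot be reached exactly on the discrete "
            "MFI support; ties bound the achievable rank correlation"
        )
    r_latent = 2.0 * np.sin(np.pi * spec.planted_rho / 6.0)
    z1 = rng.standard_normal(spec.n_subjects)
    z2 = r_latent * z1 + np.sqrt(1.0 - r_latent**2) * rng.standard_normal(
        spec.n_subjects
    )
    dmn = spec.dmn_amplitude_pct + spec.dmn_amplitude_spread_pct * z1
    cen = spec.cen_amplitude_pct + spec.cen_amplitude_spread_pct * rng.standard_normal(
        spec.n_subjects
    )
    mfi_total = np.clip(np.rint(20 + 80 * _st.norm.cdf(z2)), 20, 100).astype(int)
    return dmn, cen, mfi_total


def decompose_mfi_total(
    total: int, key: MfiKey, rng: np.random.Generator, subject_id: str = "s"
) -> MfiResponse:
    """Draw 20 raw item responses whose scored sum equals ``total`` exactly.

    Scored values start at 1 and the ``total − 20`` surplus points are
    spread uniformly at random over items with remaining headroom (cap 5
    each); reverse-scored items are then encoded back to raw responses.
    """
    if not 20 <= total <= 100:
        raise ConfigurationError(f"MFI total must lie in 20..100, got {total}")
    scored = np.ones(20, dtype=int)
    surplus = total - 20
    while surplus > 0:
        open_items = np.where(scored < 5)[0]
        take = min(surplus, len(open_items))
        picks = rng.choice(open_items, size=take, replace=False)
        scored[picks] += 1
        surplus -= take
    raw = [
        6 - s if (i + 1) in key.reversed_items else int(s)
        for i, s in enumerate(scored)
    ]
    return MfiResponse(subject_id=subject_id, items=tuple(int(v) for v in raw))


def synthesize_cohort(
    spec: CohortSpec,
    design: TaskDesign,
    grid: RoiGrid,
    tr_s: float = 2.0,
    key: MfiKey | None = None,
    with_sessions: bool = True,
    accuracy_target: float = 0.969,
    rt_mean_ms: float = 900.0,
    rt_sd_ms: float = 190.0,
) -> list[tuple[BoldSession | None, SubjectRecord]]:
    """Generate a full cohort of sessions plus subject records.

    With ``with_sessions=False`` only the parameter draws, questionnaires,
    and behavior logs are produced (fast path for statistical Monte-Carlo).
    """
    if spec.n_subjects < 3:
        raise ConfigurationError("a cohort needs at least 3 subjects")
    if not grid.network_of:
        raise GeometryError("grid has no seeded networks; call plant_networks first")
    if key is None:
        key = default_key()
    rng = np.random.default_rng(spec.seed)
    dmn_amp, cen_amp, mfi_total = draw_cohort_parameters(spec, rng)
    dm = build_design_matrix(design, tr_s=tr_s) if with_sessions else None

    out: list[tuple[BoldSession | None, SubjectRecord]] = []
    for i in range(spec.n_subjects):
        sid = f"sub-{i + 1:03d}"
        group = GROUP_LABELS[i % len(GROUP_LABELS)]
        response = decompose_mfi_total(int(mfi_total[i]), key, rng, subject_id=sid)
        scores = score_mfi(response, key)
        assert scores.mfi_total == mfi_total[i]
        behavior = synthesize_behavior(
            design,
            accuracy_target=accuracy_target,
            rt_mean_ms=rt_mean_ms,
            rt_sd_ms=rt_sd_ms,
            seed=int(rng.integers(0, 2**31)),
        )
        record = SubjectRecord(
            subject_id=sid,
            group=group,
            response=response,
            scores=scores,
            true_cen_amplitude_pct=float(cen_amp[i]),
            true_dmn_amplitude_pct=float(dmn_amp[i]),
            behavior=behavior,
        )
        session = None
        if with_sessions:
            effects = {
                "CEN": {"CUE": float(cen_amp[i]), "CUE_STIM": float(cen_amp[i])},
                "DMN": {"CUE": float(dmn_amp[i]), "CUE_STIM": float(dmn_amp[i])},
            }
            session = synthesize_session(
                design,
                spec,
                effects,
                grid,
                seed=int(rng.integers(0, 2**31)),
                tr_s=tr_s,
                dm=dm,
            )
        out.append((session, record))
    return out


def simulate_tumor_mask(
    center_mm: tuple[float, float, float],
    radii_mm: tuple[float, float, float],
    session: BoldSession,
    seed: int = 0,
) -> TumorMask:
    """Rasterize an ellipsoidal tumor on the session grid.

    A voxel is inside when its center satisfies the ellipsoid inequality.
    Deterministic for fixed inputs (the seed is accepted for interface
    symmetry with the other generators).
    """
    radii = np.asarray(radii_mm, dtype=float)
    if np.any(radii <= 0):
        raise ConfigurationError(f"radii must be positive, got {radii_mm}")
    centers = voxel_centers_mm(session.shape, session.affine)
    center = np.asarray(center_mm, dtype=float)
    lo = centers.reshape(-1, 3).min(axis=0) - session.voxel_size_mm / 2
    hi = centers.reshape(-1, 3).max(axis=0) + session.voxel_size_mm / 2
    if np.any(center < lo) or np.any(center > hi):
        raise ConfigurationError(f"tumor center {center_mm} is outside the volume")
    d = (centers - center) / radii
    mask = (d**2).sum(axis=-1) <= 1.0
    return TumorMask(mask=mask, voxel_size_mm=session.voxel_size_mm)


def synthesize_behavior(
    design: TaskDesign,
    accuracy_target: float,
    rt_mean_ms: float = 900.0,
    rt_sd_ms: float = 190.0,
    seed: int = 0,
    response_window_ms: float = 2000.0,
) -> pd.DataFrame:
    """One response per cue+stimulus trial.

    Correctness is Bernoulli(``accuracy_target``); reaction times are
    Gaussian truncated to (0, ``response_window_ms``].
    """
    if not 0.0 <= accuracy_target <= 1.0:
        raise ConfigurationError("accuracy_target must lie in [0, 1]")
    from alertfmri.taskdesign import TrialKind

    trials = design.trials(TrialKind.CUE_STIM)
    rng = np.random.default_rng(seed)
    rows = []
    if trials:
        a = (0.0 - rt_mean_ms) / rt_sd_ms
        b = (response_window_ms - rt_mean_ms) / rt_sd_ms
        rts = _st.truncnorm.rvs(
            a, b, loc=rt_mean_ms, scale=rt_sd_ms, size=len(trials), random_state=rng
        )
        correct = rng.random(len(trials)) < accuracy_target
        for trial, rt, ok in zip(trials, rts, correct):
            rows.append(
                {
                    "trial_onset_s": trial.onset,
                    "stim_onset_s": trial.stim_onset,
                    "response_time_s": trial.stim_onset + rt / 1000.0,
                    "correct": bool(ok),
                    "responded": True,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_onset_s",
            "stim_onset_s",
            "response_time_s",
            "correct",
            "responded",
        ],
    )
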