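"""Event-related task schedules and GLM design matrices.

The task alternates two trial types — a warning cue alone (``CUE``) and a
cue followed by an arrow-judgment stimulus (``CUE_STIM``) — packed
back-to-back inside runs that are enveloped by rest blocks.  The design
matrix convolves the cue/stimulus boxcars with the canonical double-gamma
HRF, rescales task columns to unit peak, and appends a discrete-cosine
high-pass basis plus an intercept.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import gamma as _gamma_dist

from alertfmri.errors import ConfigurationError, DimensionError

__all__ = [
    "TrialKind",
    "TrialEvent",
    "TaskDesign",
    "DesignMatrix",
    "HRF_WINDOW_S",
    "CUE_SUBONSET_S",
    "STIM_SUBONSET_S",
    "CUE_DURATION_S",
    "STIM_DURATION_S",
    "DEFAULT_HRF_PARAMS",
    "generate_task_design",
    "canonical_hrf",
    "build_design_matrix",
    "events_to_frame",
    "write_events_tsv",
    "read_events_tsv",
    "design_from_yaml",
]

# Sub-event timing within one trial (fixed by the task, not configurable):
# the cue lights up at t=0 for 1.5 s; in cue+stimulus trials the arrow
# stimulus appears at t=+2.0 s for another 1.5 s.
CUE_SUBONSET_S = 0.0
STIM_SUBONSET_S = 2.0
CUE_DURATION_S = 1.5
STIM_DURATION_S = 1.5

HRF_WINDOW_S = 32.0

#: Canonical double-gamma parameters (response delay/dispersion, undershoot
#: delay/dispersion, response:undershoot amplitude ratio).
DEFAULT_HRF_PARAMS = {
    "response_delay": 6.0,
    "undershoot_delay": 16.0,
    "response_dispersion": 1.0,
    "undershoot_dispersion": 1.0,
    "undershoot_ratio": 6.0,
}


class TrialKind(str, enum.Enum):
    CUE = "CUE"
    CUE_STIM = "CUE_STIM"
    REST = "REST"


@dataclass(frozen=True)
class TrialEvent:
    """One scheduled event: a trial or a rest block.

    ``run_index`` is the 0-based run for trials; rest blocks carry the index
    of the run they precede (the final rest block carries ``n_runs``).
    """

    onset: float
    duration: float
    kind: TrialKind
    run_index: int

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ConfigurationError(f"event onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ConfigurationError(
                f"event duration must be > 0, got {self.duration}"
            )

    @property
    def cue_onset(self) -> float:
        """Absolute onset of the cue sub-event."""
        return self.onset + CUE_SUBONSET_S

    @property
    def stim_onset(self) -> float | None:
        """Absolute onset of the stimulus sub-event (cue+stim trials only)."""
        if self.kind is TrialKind.CUE_STIM:
            return self.onset + STIM_SUBONSET_S
        return None


@dataclass(frozen=True)
class TaskDesign:
    """A full session schedule: runs of randomized trials between rest blocks."""

    events: tuple[TrialEvent, ...]
    n_runs: int
    run_length_s: float
    rest_length_s: float
    n_cue_per_run: int
    n_cuestim_per_run: int
    trial_duration_s: float
    rng_seed: int

    @property
    def session_duration_s(self) -> float:
        nominal = self.n_runs * self.run_length_s + (self.n_runs + 1) * self.rest_length_s
        last = max((e.onset + e.duration for e in self.events), default=0.0)
        return max(nominal, last)  # jitter can stretch runs past nominal

    @property
    def n_rest_blocks(self) -> int:
        return sum(1 for e in self.events if e.kind is TrialKind.REST)

    def trials(self, kind: TrialKind | None = None) -> list[TrialEvent]:
        out = [e for e in self.events if e.kind is not TrialKind.REST]
        if kind is not None:
            out = [e for e in out if e.kind is kind]
        return out


@dataclass(frozen=True)
class DesignMatrix:
    """Regressors sampled at the repetition time.

    Column order: task regressors (unit peak), discrete-cosine high-pass
    basis, intercept.
    """

    values: np.ndarray  # (n_timepoints, n_columns)
    names: tuple[str, ...]
    tr_s: float
    hrf_params: dict
    highpass_cutoff_s: float | None

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def task_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n in ("CUE", "CUE_STIM"))

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))


def generate_task_design(
    n_runs: int = 4,
    n_cue_per_run: int = 20,
    n_cuestim_per_run: int = 20,
    trial_duration_s: float = 4.0,
    rest_length_s: float = 20.0,
    seed: int = 0,
    jitter_s: float = 0.0,
) -> TaskDesign:
    """Generate a seeded session schedule.

    Each run holds exactly ``n_cue_per_run`` cue-only and
    ``n_cuestim_per_run`` cue+stimulus trials in a seeded random order,
    stacked back-to-back (optional uniform jitter up to ``jitter_s`` between
    trials).  Rest blocks envelop the runs: one before each run and one
    after the last, ``n_runs + 1`` in total.
    """
    if n_runs < 1:
        raise ConfigurationError(f"n_runs must be >= 1, got {n_runs}")
    if n_cue_per_run < 0 or n_cuestim_per_run < 0:
        raise ConfigurationError("trial counts must be non-negative")
    if n_cue_per_run + n_cuestim_per_run < 1:
        raise ConfigurationError("at least one trial per run is required")
    if trial_duration_s <= 0 or rest_length_s <= 0:
        raise ConfigurationError("durations must be positive")
    if jitter_s < 0:
        raise ConfigurationError("jitter must be non-negative")

    rng = np.random.default_rng(seed)
    n_per_run = n_cue_per_run + n_cuestim_per_run
    run_length_s = n_per_run * trial_duration_s  # jitter extends beyond this

    events: list[TrialEvent] = []
    t = 0.0
    for run in range(n_runs):
        events.append(TrialEvent(t, rest_length_s, TrialKind.REST, run))
        t += rest_length_s
        pool = [TrialKind.CUE] * n_cue_per_run + [TrialKind.CUE_STIM] * n_cuestim_per_run
        kinds = [pool[i] for i in rng.permutation(n_per_run)]
        for kind in kinds:
            events.append(TrialEvent(t, trial_duration_s, kind, run))
            t += trial_duration_s
            if jitter_s > 0:
                t += rng.uniform(0.0, jitter_s)
    events.append(TrialEvent(t, rest_length_s, TrialKind.REST, n_runs))

    return TaskDesign(
        events=tuple(events),
        n_runs=n_runs,
        run_length_s=run_length_s,
        rest_length_s=rest_length_s,
        n_cue_per_run=n_cue_per_run,
        n_cuestim_per_run=n_cuestim_per_run,
        trial_duration_s=trial_duration_s,
        rng_seed=seed,
    )


def canonical_hrf(
    tr_s: float,
    oversampling: int = 16,
    params: dict | None = None,
    window_s: float = HRF_WINDOW_S,
) -> np.ndarray:
    """Sample the canonical double-gamma HRF, normalized to unit peak.

    The kernel is the difference of two gamma densities — a positive
    response lobe and a scaled-down late undershoot — evaluated on a grid of
    step ``tr_s / oversampling`` over ``[0, window_s]``.
    """
    if tr_s <= 0:
        raise ConfigurationError(f"tr_s must be > 0, got {tr_s}")
    if oversampling < 1:
        raise ConfigurationError("oversampling must be >= 1")
    p = dict(DEFAULT_HRF_PARAMS)
    if params:
        p.update(params)
    dt = tr_s / oversampling
    t = np.arange(0.0, window_s + dt / 2, dt)
    peak = _gamma_dist.pdf(
        t, a=p["response_delay"] / p["response_dispersion"], scale=p["response_dispersion"]
    )
    undershoot = _gamma_dist.pdf(
        t,
        a=p["undershoot_delay"] / p["undershoot_dispersion"],
        scale=p["undershoot_dispersion"],
    )
    hrf = peak - undershoot / p["undershoot_ratio"]
    return hrf / hrf.max()


def dct_highpass_basis(
    n_timepoints: int, tr_s: float, cutoff_s: float
) -> np.ndarray:
    """Discrete-cosine nuisance columns spanning frequencies below 1/cutoff.

    Basis order ``K = floor(2 * N * tr / cutoff)``; columns are the DCT-II
    cosines for k = 1..K, which are mutually orthogonal and orthogonal to
    the constant column.
    """
    if cutoff_s <= 0:
        raise ConfigurationError("high-pass cutoff must be positive")
    n = np.arange(n_timepoints)
    order = int(np.floor(2.0 * n_timepoints * tr_s / cutoff_s))
    cols = [
        np.sqrt(2.0 / n_timepoints) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_timepoints))
        for k in range(1, order + 1)
    ]
    if not cols:
        return np.empty((n_timepoints, 0))
    return np.column_stack(cols)


def _boxcar(intervals: Sequence[tuple[float, float]], n_fine: int, dt: float) -> np.ndarray:
    box = np.zeros(n_fine)
    for onset, duration in intervals:
        i0 = int(np.round(onset / dt))
        i1 = int(np.round((onset + duration) / dt))
        box[i0 : max(i1, i0 + 1)] = 1.0
    return box


def build_design_matrix(
    design: TaskDesign,
    tr_s: float = 2.0,
    n_timepoints: int | None = None,
    highpass_cutoff_s: float | None = 128.0,
    oversampling: int = 16,
    hrf_params: dict | None = None,
    scale_to_unit_peak: bool = True,
) -> DesignMatrix:
    """Build the first-level design matrix for a task schedule.

    The ``CUE`` column convolves the cue boxcars of cue-only trials with the
    HRF; the ``CUE_STIM`` column convolves both the cue and stimulus boxcars
    of cue+stimulus trials.  Task columns are rescaled to unit peak so that
    fitted betas read directly as response amplitude in signal units.
    """
    if n_timepoints is None:
        n_timepoints = int(np.ceil(design.session_duration_s / tr_s))
    if n_timepoints * tr_s < design.session_duration_s:
        raise DimensionError(
            f"scan of {n_timepoints} x {tr_s} s = {n_timepoints * tr_s} s is "
            f"shorter than the {design.session_duration_s} s session"
        )

    dt = tr_s / oversampling
    n_fine = n_timepoints * oversampling
    kernel = canonical_hrf(tr_s, oversampling, params=hrf_params)

    cue_intervals = [
        (e.cue_onset, CUE_DURATION_S) for e in design.trials(TrialKind.CUE)
    ]
    cuestim_intervals: list[tuple[float, float]] = []
    for e in design.trials(TrialKind.CUE_STIM):
        cuestim_intervals.append((e.cue_onset, CUE_DURATION_S))
        cuestim_intervals.append((e.stim_onset, STIM_DURATION_S))

    columns, names = [], []
    for name, intervals in (("CUE", cue_intervals), ("CUE_STIM", cuestim_intervals)):
        fine = np.convolve(_boxcar(intervals, n_fine, dt), kernel)[:n_fine]
        col = fine[::oversampling]
        peak = np.abs(col).max()
        if scale_to_unit_peak and peak > 0:
            col = col / peak
        columns.append(col)
        names.append(name)

    if highpass_cutoff_s is not None:
        hp = dct_highpass_basis(n_timepoints, tr_s, highpass_cutoff_s)
        for k in range(hp.shape[1]):
            columns.append(hp[:, k])
            names.append(f"drift_{k + 1}")
    columns.append(np.ones(n_timepoints))
    names.append("intercept")

    p = dict(DEFAULT_HRF_PARAMS)
    if hrf_params:
        p.update(hrf_params)
    return DesignMatrix(
        values=np.column_stack(columns),
        names=tuple(names),
        tr_s=tr_s,
        hrf_params=p,
        highpass_cutoff_s=highpass_cutoff_s,
    )


# ---------------------------------------------------------------------------
# I/O: BIDS-style events TSV and YAML design configuration


def events_to_frame(design: TaskDesign) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset": [e.onset for e in design.events],
            "duration": [e.duration for e in design.events],
            "trial_type": [e.kind.value for e in design.events],
            "run": [e.run_index for e in design.events],
        }
    )


def write_events_tsv(design: TaskDesign, path: str | Path) -> None:
    events_to_frame(design).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[TrialEvent]:
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"events TSV missing columns: {sorted(missing)}")
    run = df["run"] if "run" in df.columns else pd.Series([0] * len(df))
    return [
        TrialEvent(float(o), float(d), TrialKind(t), int(r))
        for o, d, t, r in zip(df["onset"], df["duration"], df["trial_type"], run)
    ]


def design_from_yaml(path: str | Path, seed: int | None = None) -> TaskDesign:
    """Build a schedule from a YAML config (keys mirror generate_task_design)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if seed is not None:
        cfg["seed"] = seed
    return generate_task_design(**cfg)
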