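"""MFI-20 questionnaire scoring and task-behavior metrics.

The instrument has 20 items on a 1..5 scale, grouped into five 4-item
domains (general fatigue, physical fatigue, reduced activity, reduced
motivation, mental fatigue).  Which items belong to which domain, and which
are reverse-scored, is configuration: the engine accepts any key of the
right shape, and the published assignment ships as a packaged YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from alertfmri.errors import MissingDataError, ValidationError

__all__ = [
    "DOMAINS",
    "MfiKey",
    "MfiResponse",
    "MfiScores",
    "default_key",
    "load_key",
    "score_mfi",
    "compute_accuracy",
    "compute_rt",
    "responses_from_csv",
    "scores_to_frame",
]

DOMAINS = (
    "general_fatigue",
    "physical_fatigue",
    "reduced_activity",
    "reduced_motivation",
    "mental_fatigue",
)

N_ITEMS = 20
ITEM_MIN, ITEM_MAX = 1, 5


@dataclass(frozen=True)
class MfiKey:
    """Item→domain assignment plus the set of reverse-scored items (1-based)."""

    domain_of: dict[int, str]
    reversed_items: frozenset[int]

    def __post_init__(self) -> None:
        items = sorted(self.domain_of)
        if items != list(range(1, N_ITEMS + 1)):
            raise ValidationError("key must cover items 1..20 exactly")
        for d in DOMAINS:
            n = sum(1 for v in self.domain_of.values() if v == d)
            if n != 4:
                raise ValidationError(f"domain {d!r} has {n} items; expected 4")
        if not self.reversed_items <= set(range(1, N_ITEMS + 1)):
            raise ValidationError("reversed items must be in 1..20")

    def items_of(self, domain: str) -> list[int]:
        return sorted(i for i, d in self.domain_of.items() if d == domain)


@dataclass(frozen=True)
class MfiResponse:
    subject_id: str
    items: tuple[int, ...]  # raw item responses, 1..5, item order 1..20

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise MissingDataError(
                f"subject {self.subject_id}: expected {N_ITEMS} items, got {len(self.items)}"
            )
        for idx, v in enumerate(self.items, start=1):
            if not (isinstance(v, (int, np.integer)) and ITEM_MIN <= v <= ITEM_MAX):
                raise ValidationError(
                    f"subject {self.subject_id}: item {idx} response {v!r} "
                    f"outside {ITEM_MIN}..{ITEM_MAX}"
                )


@dataclass(frozen=True)
class MfiScores:
    subject_id: str
    general_fatigue: int
    physical_fatigue: int
    reduced_activity: int
    reduced_motivation: int
    mental_fatigue: int

    @property
    def mfi_total(self) -> int:
        return sum(getattr(self, d) for d in DOMAINS)

    def domain(self, name: str) -> int:
        if name not in DOMAINS:
            raise ValidationError(f"unknown domain {name!r}")
        return getattr(self, name)


def load_key(path: str | Path) -> MfiKey:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    domain_of: dict[int, str] = {}
    for domain, items in raw["domains"].items():
        for i in items:
            domain_of[int(i)] = domain
    return MfiKey(domain_of=domain_of, reversed_items=frozenset(int(i) for i in raw["reversed"]))


def default_key() -> MfiKey:
    """The packaged published scoring key."""
    with resources.as_file(
        resources.files("alertfmri.data").joinpath("mfi20_key.yaml")
    ) as p:
        return load_key(p)


def score_mfi(resp: MfiResponse, key: MfiKey | None = None) -> MfiScores:
    """Score one complete response.

    Reverse-scored items are mapped r → 6 − r; each domain is the sum of
    its four scored items; the total is the sum of the five domains.
    """
    if key is None:
        key = default_key()
    scored = {
        i: (6 - v if i in key.reversed_items else v)
        for i, v in enumerate(resp.items, start=1)
    }
    domain_scores = {
        d: sum(scored[i] for i in key.items_of(d)) for d in DOMAINS
    }
    return MfiScores(subject_id=resp.subject_id, **domain_scores)


# ---------------------------------------------------------------------------
# Behavior: accuracy and reaction time from a response log.
#
# Response-log schema (one row per cue+stimulus trial):
#   trial_onset_s, stim_onset_s, response_time_s, correct (bool),
#   responded (bool)


def compute_accuracy(log: pd.DataFrame) -> float:
    """Percentage of correct responses among recorded responses."""
    if "correct" not in log.columns:
        raise ValidationError("response log lacks a 'correct' column")
    responded = log[log.get("responded", True) == True]  # noqa: E712
    if len(responded) == 0:
        raise MissingDataError("accuracy undefined: no recorded responses")
    return 100.0 * float(responded["correct"].mean())


def compute_rt(log: pd.DataFrame) -> float:
    """Mean reaction time (ms) over correct responses only.

    Reaction time is the response timestamp minus the stimulus onset.
    """
    responded = log[log.get("responded", True) == True]  # noqa: E712
    correct = responded[responded["correct"] == True]  # noqa: E712
    if len(correct) == 0:
        raise MissingDataError("reaction time undefined: no correct responses")
    rt_s = correct["response_time_s"] - correct["stim_onset_s"]
    return 1000.0 * float(rt_s.mean())


def responses_from_csv(path: str | Path) -> list[MfiResponse]:
    """Read responses from CSV with columns subject_id, item_01..item_20."""
    df = pd.read_csv(path)
    cols = [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise MissingDataError(f"response CSV lacks columns: {missing}")
    return [
        MfiResponse(subject_id=str(row["subject_id"]), items=tuple(int(row[c]) for c in cols))
        for _, row in df.iterrows()
    ]


def scores_to_frame(scores: list[MfiScores]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                **{d: s.domain(d) for d in DOMAINS},
                "mfi_total": s.mfi_total,
            }
            for s in scores
        ]
    )
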