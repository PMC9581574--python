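"""Scoring questionnaire data model, per-scorer output files, validation metrics.

Each detected event is answered with three questions: (1) true or false
positive — a true positive may additionally be flagged as the continuation
of a previous event; (2) hemisphere (left / right / both); (3) severity —
``subclinical`` (electrographic seizure with no behavioral correlate) or
Racine stage I-V. Stages III-V count as behavioral seizures.

Annotation files are JSON, one per (scorer, date), named
``<scorer>_<date>_annotations.json`` so several people can score the same
events blindly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError

HEMISPHERES = ("left", "right", "both")
RACINE_LEVELS = ("subclinical", "I", "II", "III", "IV", "V")
BEHAVIORAL_STAGES = frozenset({"III", "IV", "V"})


@dataclass
class Annotation:
    """One scored event."""

    event_id: str
    is_true_positive: bool
    scorer_id: str
    score_date: str  # ISO calendar date
    is_continuation: bool = False
    hemisphere: str | None = None
    racine: str | None = None
    comment: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.is_true_positive:
            if self.hemisphere not in HEMISPHERES:
                raise ValidationError(
                    f"event {self.event_id}: true positive requires hemisphere "
                    f"in {HEMISPHERES}, got {self.hemisphere!r}"
                )
            if self.racine not in RACINE_LEVELS:
                raise ValidationError(
                    f"event {self.event_id}: true positive requires racine "
                    f"in {RACINE_LEVELS}, got {self.racine!r}"
                )
        else:
            if self.is_continuation:
                raise ValidationError(
                    f"event {self.event_id}: only a true positive can be a continuation"
                )
            if self.hemisphere is not None or self.racine is not None:
                raise ValidationError(
                    f"event {self.event_id}: hemisphere/racine only apply to true positives"
                )

    def to_dict(self) -> dict:
        return {
            "event_id": self.event_id,
            "is_true_positive": self.is_true_positive,
            "is_continuation": self.is_continuation,
            "hemisphere": self.hemisphere,
            "racine": self.racine,
            "comment": self.comment,
            "scorer_id": self.scorer_id,
            "score_date": self.score_date,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "Annotation":
        return cls(
            event_id=doc["event_id"],
            is_true_positive=doc["is_true_positive"],
            is_continuation=doc.get("is_continuation", False),
            hemisphere=doc.get("hemisphere"),
            racine=doc.get("racine"),
            comment=doc.get("comment", ""),
            scorer_id=doc["scorer_id"],
            score_date=doc["score_date"],
        )


@dataclass
class ScoringSummary:
    """Counts partitioning the detector hits; rate = FP / hits."""

    n_hits: int
    n_false_positive: int
    n_subclinical: int
    n_behavioral: int
    n_other_true: int  # stages I-II

    @property
    def false_positive_rate(self) -> float:
        return self.n_false_positive / self.n_hits if self.n_hits else 0.0

    def to_dict(self) -> dict:
        return {
            "n_hits": self.n_hits,
            "n_false_positive": self.n_false_positive,
            "n_subclinical": self.n_subclinical,
            "n_behavioral": self.n_behavioral,
            "n_other_true": self.n_other_true,
            "false_positive_rate": self.false_positive_rate,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def annotation_file_name(scorer_id: str, score_date: str) -> str:
    return f"{scorer_id}_{score_date}_annotations.json"


def save_annotations(
    annotations: Sequence[Annotation],
    scorer_id: str,
    out_dir: str | Path,
    score_date: str | None = None,
) -> Path:
    """Write one canonical JSON file per (scorer, date); validates first."""
    for a in annotations:
        a.validate()
        if a.scorer_id != scorer_id:
            raise ValidationError(
                f"annotation {a.event_id} belongs to scorer {a.scorer_id!r}, "
                f"not {scorer_id!r}"
            )
    if score_date is None:
        dates = {a.score_date for a in annotations}
        if len(dates) != 1:
            raise ValidationError(
                "score_date must be given explicitly when annotations span "
                f"{len(dates)} dates"
            )
        score_date = dates.pop()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / annotation_file_name(scorer_id, score_date)
    records = [a.to_dict() for a in annotations]
    path.write_text(
        json.dumps(records, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
    return path


def load_annotations(path: str | Path) -> list[Annotation]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return [Annotation.from_dict(rec) for rec in doc]


def summarize(annotations: Sequence[Annotation]) -> ScoringSummary:
    """Partition hits into FP / subclinical / behavioral / other-true."""
    seen: set[str] = set()
    for a in annotations:
        if a.event_id in seen:
            raise ValidationError(f"duplicate event_id {a.event_id!r}")
        seen.add(a.event_id)
    n_fp = sum(not a.is_true_positive for a in annotations)
    n_sub = sum(
        a.is_true_positive and a.racine == "subclinical" for a in annotations
    )
    n_beh = sum(
        a.is_true_positive and a.racine in BEHAVIORAL_STAGES for a in annotations
    )
    n_other = sum(
        a.is_true_positive and a.racine in ("I", "II") for a in annotations
    )
    return ScoringSummary(
        n_hits=len(annotations),
        n_false_positive=n_fp,
        n_subclinical=n_sub,
        n_behavioral=n_beh,
        n_other_true=n_other,
    )


def inter_scorer_agreement(
    annotation_sets: Sequence[Sequence[Annotation]],
) -> dict[str, float]:
    """Fraction of events on which every scorer gave identical answers.

    Reported per question (``q1_classification`` including the
    continuation flag, ``q2_hemisphere``, ``q3_racine``) and ``overall``.
    """
    if len(annotation_sets) < 2:
        raise ValidationError("agreement needs at least 2 scorers")
    maps = [{a.event_id: a for a in s} for s in annotation_sets]
    universe = set(maps[0])
    for i, m in enumerate(maps[1:], start=2):
        if set(m) != universe:
            diff = sorted(universe.symmetric_difference(set(m)))
            raise ValidationError(
                f"scorer set 1 and scorer set {i} disagree on event ids: {diff}"
            )
    if not universe:
        raise ValidationError("no events to compare")
    n = len(universe)
    q1 = q2 = q3 = overall = 0
    for eid in universe:
        answers = [maps_i[eid] for maps_i in maps]
        same_q1 = len(
            {(a.is_true_positive, a.is_continuation) for a in answers}
        ) == 1
        same_q2 = len({a.hemisphere for a in answers}) == 1
        same_q3 = len({a.racine for a in answers}) == 1
        q1 += same_q1
        q2 += same_q2
        q3 += same_q3
        overall += same_q1 and same_q2 and same_q3
    return {
        "q1_classification": q1 / n,
        "q2_hemisphere": q2 / n,
        "q3_racine": q3 / n,
        "overall": overall / n,
    }


@dataclass
class MatchResult:
    true_pos: list[tuple[int, int]]  # (event index, truth index)
    false_pos: list[int]  # unmatched event indices
    false_neg: list[int]  # unmatched truth indices

    @property
    def n_true_pos(self) -> int:
        return len(self.true_pos)

    @property
    def n_false_pos(self) -> int:
        return len(self.false_pos)

    @property
    def n_false_neg(self) -> int:
        return len(self.false_neg)


def _interval(obj) -> tuple[float, float]:
    if hasattr(obj, "onset_s"):
        return float(obj.onset_s), float(obj.offset_s)
    a, b = obj
    return float(a), float(b)


def match_to_ground_truth(events: Sequence, truth_intervals: Sequence) -> MatchResult:
    """Match detected events to truth intervals, one event per truth.

    An event matches a truth interval when the closed intervals intersect
    (>= 1 shared sample). The matching is a maximum bipartite matching —
    events are offered in onset order, and augmenting paths guarantee a
    greedy pass never costs a feasible match — so each truth interval
    consumes at most one event and as many truths as possible are covered.
    """
    evs = [_interval(e) for e in events]
    truths = [_interval(t) for t in truth_intervals]
    for on, off in evs + truths:
        if off < on:
            raise ValidationError(f"malformed interval ({on}, {off})")
    order = sorted(range(len(evs)), key=lambda i: evs[i])
    adjacency = {
        i: [
            j
            for j, (ton, toff) in enumerate(truths)
            if evs[i][0] <= toff and ton <= evs[i][1]
        ]
        for i in order
    }
    truth_owner: dict[int, int] = {}

    def try_assign(i: int, visited: set[int]) -> bool:
        for j in adjacency[i]:
            if j in visited:
                continue
            visited.add(j)
            if j not in truth_owner or try_assign(truth_owner[j], visited):
                truth_owner[j] = i
                return True
        return False

    for i in order:
        try_assign(i, set())
    pairs = sorted((i, j) for j, i in truth_owner.items())
    matched_events = {i for i, _ in pairs}
    false_pos = [i for i in range(len(evs)) if i not in matched_events]
    false_neg = [j for j in range(len(truths)) if j not in truth_owner]
    return MatchResult(true_pos=pairs, false_pos=false_pos, false_neg=false_neg)
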