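"""Index-event cohort construction with eligibility windows and attrition.

The selection procedure mirrors standard claims-cohort practice for a
surgically defined condition: the index event is each person's first
encounter carrying a qualifying procedure code; candidates are then
filtered, in order, by age at index (completed years, bounds inclusive),
absence of any competing-condition diagnosis on or before the index date,
and continuous plan eligibility over the full look-back/follow-up window
(12 months before through 24 months after the surgery by default, counted
as fixed 365/730-day spans).  Diagnoses occurring strictly after the index
never exclude — post-surgical appearances of these codes may be sequelae of
the surgery itself.  Each filter's removals are tallied in an attrition
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .codebook import CodeSet, builtin_registry, exclusion_union, FAI_INCLUSION_LABEL
from .claims_store import Event, RepositoryBundle, all_timelines, merge_spans


@dataclass
class CohortSpec:
    """Inclusion/exclusion/eligibility triad defining one study cohort."""

    inclusion_set: CodeSet
    exclusion_set: CodeSet
    age_range: Tuple[int, int] = (18, 50)
    pre_days: int = 365
    post_days: int = 730
    gap_tolerance_days: int = 0

    def __post_init__(self):
        if self.pre_days < 0 or self.post_days < 0:
            raise ValueError("pre_days and post_days must be >= 0")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range min must be <= max")

    @classmethod
    def default(cls) -> "CohortSpec":
        reg = builtin_registry()
        return cls(
            inclusion_set=reg[FAI_INCLUSION_LABEL],
            exclusion_set=exclusion_union(reg),
        )


@dataclass(frozen=True)
class CohortMember:
    person_id: str
    index_date: pd.Timestamp
    index_cpt: str
    window_start: pd.Timestamp
    window_end: pd.Timestamp


@dataclass
class AttritionTable:
    """Telescoping per-filter counts: retained[k] = retained[k-1] - removed[k]."""

    stages: List[Tuple[str, int, int]] = field(default_factory=list)  # (stage, retained, removed)

    def add(self, stage: str, retained: int, removed: int) -> None:
        self.stages.append((stage, retained, removed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "retained", "removed"])


def find_index_events(
    bundle: RepositoryBundle,
    inclusion_set: CodeSet,
    timelines: Optional[Dict[str, List[Event]]] = None,
) -> Dict[str, Tuple[pd.Timestamp, str]]:
    """Earliest qualifying procedure per person, scanning direct-care
    procedure codes and purchased claim-line CPT codes.

    Same-day ties are broken by the smallest code string, so the result is
    invariant to input row order.  Persons with no qualifying code are
    absent from the map.
    """
    timelines = timelines if timelines is not None else all_timelines(bundle)
    out: Dict[str, Tuple[pd.Timestamp, str]] = {}
    for pid, events in timelines.items():
        best: Optional[Tuple[pd.Timestamp, str]] = None
        for ev in events:
            if ev.source not in ("inpatient", "outpatient", "purchased_lines"):
                continue
            hits = sorted(c for c in ev.proc_codes if inclusion_set.matches_code(c))
            if not hits:
                continue
            cand = (ev.date, hits[0])
            if best is None or cand < best:
                best = cand
        if best is not None:
            out[pid] = best
    return out


def completed_age(birth_date: pd.Timestamp, at: pd.Timestamp) -> int:
    """Age in completed years at a given date (calendar arithmetic)."""
    birth_date, at = pd.Timestamp(birth_date), pd.Timestamp(at)
    return at.year - birth_date.year - (
        (at.month, at.day) < (birth_date.month, birth_date.day)
    )


def passes_age_filter(
    birth_date: pd.Timestamp, index_date: pd.Timestamp, age_range: Tuple[int, int]
) -> bool:
    age = completed_age(birth_date, index_date)
    return age_range[0] <= age <= age_range[1]


def has_prior_exclusion(
    timeline: List[Event], exclusion_set: CodeSet, index_date: pd.Timestamp
) -> bool:
    """Any excluding diagnosis dated on or before the index date?

    The window is closed at the index date: a same-day competing diagnosis
    indicates the procedure targeted that condition.  Later codes never
    exclude.
    """
    index_date = pd.Timestamp(index_date)
    for ev in timeline:
        if ev.date > index_date:
            break  # timeline is date-ordered
        if ev.dx_codes and exclusion_set.matches_any(ev.dx_codes):
            return True
    return False


def is_continuously_eligible(
    spans: pd.DataFrame,
    index_date: pd.Timestamp,
    pre_days: int = 365,
    post_days: int = 730,
    gap_tolerance_days: int = 0,
) -> bool:
    """Do the (normalized) spans cover the whole surveillance window?

    Uncovered runs of at most ``gap_tolerance_days`` days are tolerated;
    the default of 0 is the strict reading of continuous eligibility.
    """
    index_date = pd.Timestamp(index_date)
    w_start = index_date - pd.Timedelta(days=pre_days)
    w_end = index_date + pd.Timedelta(days=post_days)
    if spans.empty:
        return (w_end - w_start).days + 1 <= gap_tolerance_days

    norm = merge_spans(spans)
    cursor = w_start
    for s, e in zip(norm["start_date"], norm["end_date"]):
        if e < cursor:
            continue
        if s > w_end:
            break
        gap = (min(s, w_end + pd.Timedelta(days=1)) - cursor).days
        if gap > gap_tolerance_days:
            return False
        cursor = max(cursor, e + pd.Timedelta(days=1))
        if cursor > w_end:
            return True
    return (w_end - cursor).days + 1 <= gap_tolerance_days


def build_cohort(
    bundle: RepositoryBundle,
    spec: Optional[CohortSpec] = None,
    timelines: Optional[Dict[str, List[Event]]] = None,
) -> Tuple[List[CohortMember], AttritionTable]:
    """Run the full selection procedure and record per-stage attrition.

    Filters apply in order: index identification, age, prior exclusion,
    continuous eligibility.  Output is sorted by person_id and independent
    of input row order.
    """
    spec = spec if spec is not None else CohortSpec.default()
    timelines = timelines if timelines is not None else all_timelines(bundle)
    attrition = AttritionTable()

    index_events = find_index_events(bundle, spec.inclusion_set, timelines=timelines)
    candidates = sorted(index_events)
    attrition.add("index event identified", len(candidates), 0)

    births = dict(
        zip(bundle.persons["person_id"].astype(str), pd.to_datetime(bundle.persons["birth_date"]))
    )
    age_pass = [
        pid for pid in candidates
        if passes_age_filter(births[pid], index_events[pid][0], spec.age_range)
    ]
    attrition.add("age in range", len(age_pass), len(candidates) - len(age_pass))

    excl_pass = [
        pid for pid in age_pass
        if not has_prior_exclusion(timelines[pid], spec.exclusion_set, index_events[pid][0])
    ]
    attrition.add(
        "no prior exclusion diagnosis", len(excl_pass), len(age_pass) - len(excl_pass)
    )

    elig = bundle.eligibility
    members: List[CohortMember] = []
    for pid in excl_pass:
        spans = elig[elig["person_id"].astype(str) == pid]
        idx_date, idx_cpt = index_events[pid]
        if is_continuously_eligible(
            spans, idx_date, spec.pre_days, spec.post_days, spec.gap_tolerance_days
        ):
            members.append(CohortMember(
                person_id=pid,
                index_date=idx_date,
                index_cpt=idx_cpt,
                window_start=idx_date - pd.Timedelta(days=spec.pre_days),
                window_end=idx_date + pd.Timedelta(days=spec.post_days),
            ))
    attrition.add(
        "continuously eligible", len(members), len(excl_pass) - len(members)
    )
    return members, attrition


def cohort_to_frame(members: List[CohortMember]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "person_id": m.person_id,
                "index_date": m.index_date.strftime("%Y-%m-%d"),
                "index_cpt": m.index_cpt,
                "window_start": m.window_start.strftime("%Y-%m-%d"),
                "window_end": m.window_end.strftime("%Y-%m-%d"),
            }
            for m in members
        ],
        columns=["person_id", "index_date", "index_cpt", "window_start", "window_end"],
    )
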