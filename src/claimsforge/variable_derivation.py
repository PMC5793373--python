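"""Per-person analysis variables over the surveillance window.

Derives, for each cohort member: comorbidity flags from look-back scanning
of the shipped code sets; opioid utilization from therapeutic-class-flagged
pharmacy fills; visit counts by provider taxonomy, product line, and care
source (purchased claim lines are deduplicated to visits by distinct
(person, service date, provider)); total versus hip-related costs (direct
care contributes the full-cost decomposition, purchased care the paid
amount); and days from the index event to the first event of selected
categories.

The comorbidity look-back defaults to the 12-month pre-index window,
matching the eligibility look-back.  The shipped hip-related diagnosis set
is a package default, not a published list: the exclusion-table hip code
universe plus the hip/pelvis joint-pain codes 719.45 and 719.95.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .codebook import (
    CodeSet,
    CodeSystem,
    COMORBIDITY_LABELS,
    OPIOID_LABEL,
    builtin_registry,
    exclusion_union,
)
from .claims_store import Event, FULL_COST_COMPONENTS, RepositoryBundle, all_timelines
from .cohort_builder import CohortMember

logger = logging.getLogger(__name__)


def default_hip_dx_set() -> CodeSet:
    """Package-default hip-related diagnosis screen (synthetic, non-published).

    The published work names hip-related cost as a concept without printing
    its code list; this default unions the hip exclusion diagnoses with the
    ICD-9 hip/pelvis joint-pain codes.
    """
    base = exclusion_union()
    return CodeSet.from_text(
        "Hip-related dx (default)",
        base.pattern_texts() + ["719.45", "719.95"],
        CodeSystem.ICD9_DX,
    )


@dataclass
class ComorbidityProfile:
    person_id: str
    flags: Dict[str, bool]
    flag_dates: Dict[str, pd.Timestamp] = field(default_factory=dict)


@dataclass
class OpioidSummary:
    person_id: str
    n_fills: int = 0
    total_days_supply: int = 0
    first_fill_date: Optional[pd.Timestamp] = None
    continued_use: bool = False


@dataclass
class UtilizationSummary:
    person_id: str
    visits_by_taxonomy: Dict[str, int]
    visits_by_product_line: Dict[str, int]
    visits_by_source: Dict[str, int]
    total_cost: float
    hip_related_cost: float
    cost_by_category: Dict[Tuple[str, str], float]


def _in_window(ev: Event, window: Tuple[pd.Timestamp, pd.Timestamp]) -> bool:
    return window[0] <= ev.date <= window[1]


def flag_comorbidities(
    timeline: List[Event],
    registry: Optional[Dict[str, CodeSet]] = None,
    window: Optional[Tuple[pd.Timestamp, pd.Timestamp]] = None,
    labels: Iterable[str] = COMORBIDITY_LABELS,
    person_id: str = "",
) -> ComorbidityProfile:
    """Evaluate each comorbidity set against all in-window diagnosis codes.

    Each label is tested independently; a flag is true iff at least one
    diagnosis on an event inside the window matches the label's set, and
    ``flag_dates`` records the first matching date for true flags only.
    """
    reg = registry if registry is not None else builtin_registry()
    flags: Dict[str, bool] = {}
    dates: Dict[str, pd.Timestamp] = {}
    for label in labels:
        cs = reg[label]
        flags[label] = False
        for ev in timeline:
            if window is not None and not _in_window(ev, window):
                continue
            if ev.dx_codes and cs.matches_any(ev.dx_codes):
                flags[label] = True
                dates[label] = ev.date
                break  # timeline is date-ordered: first hit is earliest
    return ComorbidityProfile(person_id=person_id, flags=flags, flag_dates=dates)


def full_cost(cost_components: Dict[str, float]) -> float:
    """Sum the 14 direct-care full-cost subcomponents of one encounter."""
    unknown = set(cost_components) - set(FULL_COST_COMPONENTS)
    if unknown:
        raise ValueError(f"unknown full-cost component(s): {sorted(unknown)}")
    total = 0.0
    for name in FULL_COST_COMPONENTS:
        v = cost_components.get(name)
        if v is None or (isinstance(v, float) and pd.isna(v)):
            logger.warning("missing cost component %s treated as 0", name)
            v = 0.0
        if v < 0:
            raise ValueError(f"negative cost component {name}={v}")
        total += float(v)
    return total


def count_visits(events: List[Event]) -> Dict[str, int]:
    """Visit counts with purchased-claim-line deduplication.

    Direct-care encounters (inpatient stays, outpatient encounters) count
    one visit each.  Purchased claim lines are collapsed to visits by
    distinct (person, service date, provider): several billed line items —
    or several claims — from the same provider on the same day are one
    clinical visit.
    """
    direct = 0
    purchased_keys = set()
    for ev in events:
        if ev.source in ("inpatient", "outpatient", "purchased_institutional"):
            direct += 1
        elif ev.source == "purchased_lines":
            purchased_keys.add((ev.person_id, ev.date, ev.get("provider_id")))
    return {"direct": direct, "purchased": len(purchased_keys),
            "total": direct + len(purchased_keys)}


def summarize_costs(
    timeline: List[Event],
    window: Tuple[pd.Timestamp, pd.Timestamp],
    hip_dx_set: Optional[CodeSet] = None,
) -> Tuple[float, float, Dict[Tuple[str, str], float]]:
    """(total_cost, hip_related_cost, cost_by_category) over the window.

    Direct-care events contribute their full cost, purchased events the
    amount actually paid; prescriptions and ancillary records are outside
    the encounter cost roll-up.  An event is hip-related iff any of its
    diagnosis codes (in any position) matches ``hip_dx_set``.  Categories
    are keyed by (source, product line or provider taxonomy).
    """
    hip = hip_dx_set if hip_dx_set is not None else default_hip_dx_set()
    total = 0.0
    hip_total = 0.0
    by_cat: Dict[Tuple[str, str], float] = {}
    for ev in timeline:
        if ev.source in ("prescriptions", "ancillary"):
            continue
        if not _in_window(ev, window):
            continue
        cost = float(ev.cost)
        total += cost
        if ev.dx_codes and hip.matches_any(ev.dx_codes):
            hip_total += cost
        if ev.source == "outpatient":
            key = ("direct", str(ev.get("product_line", "")))
        elif ev.source == "inpatient":
            key = ("direct", str(ev.get("department", "")))
        elif ev.source == "purchased_lines":
            key = ("purchased", str(ev.get("provider_taxonomy", "")))
        else:
            key = ("purchased", "institutional")
        by_cat[key] = by_cat.get(key, 0.0) + cost
    return round(total, 2), round(hip_total, 2), {k: round(v, 2) for k, v in by_cat.items()}


def opioid_summary(
    prescriptions: List[Event],
    window: Tuple[pd.Timestamp, pd.Timestamp],
    index_date: Optional[pd.Timestamp] = None,
    continued_use_threshold_days: int = 90,
    opioid_set: Optional[CodeSet] = None,
    person_id: str = "",
) -> OpioidSummary:
    """Aggregate opiate-class pharmacy fills inside the window.

    A fill counts iff its therapeutic class matches the opiate classes
    (280808/280812 by default).  ``continued_use`` is true iff any flagged
    fill is dated more than ``continued_use_threshold_days`` days after the
    index date (a package-defined operationalization).
    """
    ops = opioid_set if opioid_set is not None else builtin_registry()[OPIOID_LABEL]
    out = OpioidSummary(person_id=person_id)
    for ev in prescriptions:
        if ev.source != "prescriptions" or not _in_window(ev, window):
            continue
        tclass = str(ev.get("therapeutic_class", ""))
        if not ops.matches_code(tclass):
            continue
        out.n_fills += 1
        out.total_days_supply += int(ev.get("days_supply", 0))
        if out.first_fill_date is None or ev.date < out.first_fill_date:
            out.first_fill_date = ev.date
        if index_date is not None and (ev.date - pd.Timestamp(index_date)).days > (
            continued_use_threshold_days
        ):
            out.continued_use = True
    return out


def time_to_first(
    timeline: List[Event],
    index_date: pd.Timestamp,
    category_matcher: Callable[[Event], bool],
) -> Optional[int]:
    """Days from index to the first matching event at or after index; None if none."""
    index_date = pd.Timestamp(index_date)
    best: Optional[int] = None
    for ev in timeline:
        delta = (ev.date - index_date).days
        if delta < 0 or not category_matcher(ev):
            continue
        if best is None or delta < best:
            best = delta
    return best


def person_encounter_costs(bundle: RepositoryBundle) -> pd.Series:
    """Total encounter cost per person over the whole repository, vectorized.

    Sums direct-care full costs (inpatient ``full_cost``, outpatient
    component sums) and purchased paid amounts; pharmacy and ancillary
    records are outside the encounter cost roll-up.  Persons with no
    encounters get 0.
    """
    pieces = []
    if not bundle.inpatient.empty:
        pieces.append(bundle.inpatient.groupby("person_id")["full_cost"].sum())
    if not bundle.outpatient.empty:
        comp = bundle.outpatient[list(FULL_COST_COMPONENTS)].astype(float).sum(axis=1)
        pieces.append(comp.groupby(bundle.outpatient["person_id"]).sum())
    if not bundle.purchased_institutional.empty:
        pieces.append(
            bundle.purchased_institutional.groupby("person_id")["paid_amount"].sum()
        )
    if not bundle.purchased_lines.empty:
        pieces.append(bundle.purchased_lines.groupby("person_id")["paid_amount"].sum())
    ids = bundle.persons["person_id"].astype(str)
    total = pd.Series(0.0, index=ids)
    for p in pieces:
        total = total.add(p.astype(float), fill_value=0.0)
    return total.reindex(ids).fillna(0.0)


# ready-made timing category matchers ---------------------------------------

def _has_cpt_prefix(ev: Event, prefixes: Tuple[str, ...]) -> bool:
    return any(str(c).startswith(prefixes) for c in ev.proc_codes)


TIMING_CATEGORIES: Dict[str, Callable[[Event], bool]] = {
    # CPT families: 97xxx physical-medicine/rehabilitation, 7xxxx imaging,
    # 20600-20611 arthrocentesis/injection
    "rehabilitation": lambda ev: _has_cpt_prefix(ev, ("97",)),
    "imaging": lambda ev: ev.source == "ancillary" and _has_cpt_prefix(ev, ("7",))
    or ev.source != "ancillary" and _has_cpt_prefix(ev, ("72", "73", "74", "76", "77")),
    "injection": lambda ev: _has_cpt_prefix(ev, ("206",)),
    "opioid_fill": lambda ev: ev.source == "prescriptions"
    and str(ev.get("therapeutic_class", "")) in ("280808", "280812"),
}


def derive_variables(
    bundle: RepositoryBundle,
    members: List[CohortMember],
    registry: Optional[Dict[str, CodeSet]] = None,
    hip_dx_set: Optional[CodeSet] = None,
    lookback_days: int = 365,
    continued_use_threshold_days: int = 90,
) -> pd.DataFrame:
    """One analysis row per cohort member: flags, utilization, costs, timing."""
    reg = registry if registry is not None else builtin_registry()
    hip = hip_dx_set if hip_dx_set is not None else default_hip_dx_set()
    timelines = all_timelines(bundle)
    rows = []
    for m in members:
        tl = timelines.get(m.person_id, [])
        lookback = (m.index_date - pd.Timedelta(days=lookback_days), m.index_date)
        window = (m.window_start, m.window_end)
        profile = flag_comorbidities(
            tl, reg, window=lookback, person_id=m.person_id
        )
        in_window = [ev for ev in tl if _in_window(ev, window)]
        visits = count_visits(in_window)
        total, hip_cost, by_cat = summarize_costs(tl, window, hip)
        opi = opioid_summary(
            tl, window, index_date=m.index_date,
            continued_use_threshold_days=continued_use_threshold_days,
            person_id=m.person_id,
        )
        row = {
            "person_id": m.person_id,
            "index_date": m.index_date.strftime("%Y-%m-%d"),
            "index_cpt": m.index_cpt,
        }
        for label in COMORBIDITY_LABELS:
            row[f"flag_{label}"] = bool(profile.flags.get(label, False))
        row.update({
            "visits_direct": visits["direct"],
            "visits_purchased": visits["purchased"],
            "visits_total": visits["total"],
            "total_cost": total,
            "hip_related_cost": hip_cost,
            "opioid_fills": opi.n_fills,
            "opioid_days_supply": opi.total_days_supply,
            "opioid_continued_use": opi.continued_use,
        })
        for cat, fn in TIMING_CATEGORIES.items():
            d = time_to_first(tl, m.index_date, fn)
            row[f"days_to_{cat}"] = d if d is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)
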