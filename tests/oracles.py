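"""Independent brute-force oracles used to cross-check the implementation.

Everything here re-derives answers from first principles with plain string
and date manipulation, deliberately sharing no logic with the package:
pattern expansion enumerates explicit code lists, cohort membership is
re-derived by scanning raw tables row by row, and eligibility coverage is
checked day by day.
"""

from __future__ import annotations

import datetime as dt
from typing import Dict, List, Optional, Set, Tuple

import pandas as pd


def category_universe(category: str) -> List[str]:
    """All printed-format codes of one category: bare, one- and two-decimal."""
    out = [category]
    out += [f"{category}.{d}" for d in range(10)]
    out += [f"{category}.{d:02d}" for d in range(100)]
    return out


def _norm(code: str) -> str:
    c = code.strip()
    if c and c[0] in "vVeE":
        c = c[0].upper() + c[1:]
    return c


def brute_expand(text: str) -> Set[str]:
    """Explicit code list for one printed ICD-9 pattern expression."""
    t = _norm(text)
    if "-" in t:
        a, b = (_norm(p) for p in t.split("-"))
        if a.endswith("x"):  # category range like 401.xx-405.xx
            lo, hi = int(a.split(".")[0]), int(b.split(".")[0])
            out: Set[str] = set()
            for c in range(lo, hi + 1):
                out.update(category_universe(f"{c:03d}"))
            return out
        cat = a.split(".")[0]
        da, db = a.split(".")[1], b.split(".")[1]
        return {f"{cat}.{str(d).zfill(len(da))}" for d in range(int(da), int(db) + 1)}
    if "." in t and t.split(".")[1].endswith("x"):
        cat, dec = t.split(".")
        prefix = dec.rstrip("x")
        full = category_universe(cat)
        if prefix:
            return {c for c in full if "." in c and c.split(".")[1].startswith(prefix)}
        return set(full)
    if "." in t:
        return {t}
    return set(category_universe(t))


def brute_expand_many(texts) -> Set[str]:
    out: Set[str] = set()
    for t in texts:
        out |= brute_expand(t)
    return out


# --- explicit printed code lists (typed independently of the package) -------

INCLUSION_CPTS = {"29914", "29915", "29916", "29862"}

EXCLUSION_PATTERNS = [
    "715.15", "715.25", "715.35", "715.95",
    "733.42",
    "820", "821",
    "730.85",
    "170.6", "170.7", "171.3",
    "714.0", "711.05",
]


def exclusion_codes() -> Set[str]:
    return brute_expand_many(EXCLUSION_PATTERNS)


# --- brute-force cohort membership ------------------------------------------

def _to_date(x) -> dt.date:
    return pd.Timestamp(x).date()


def bruteforce_cohort(
    bundle,
    age_range: Tuple[int, int] = (18, 50),
    pre_days: int = 365,
    post_days: int = 730,
    gap_tolerance_days: int = 0,
) -> Dict[str, Tuple[dt.date, str]]:
    """Re-derive cohort membership per person from the raw tables.

    Returns person_id -> (index_date, index_cpt) for members only.
    """
    excl = exclusion_codes()

    # index events: earliest dated qualifying procedure, smallest code on ties
    hits: Dict[str, List[Tuple[dt.date, str]]] = {}
    for _, r in bundle.inpatient.iterrows():
        for c in r["proc_codes"]:
            if c in INCLUSION_CPTS:
                hits.setdefault(str(r["person_id"]), []).append((_to_date(r["admit_date"]), c))
    for _, r in bundle.outpatient.iterrows():
        for c in r["cpt_codes"]:
            if c in INCLUSION_CPTS:
                hits.setdefault(str(r["person_id"]), []).append((_to_date(r["visit_date"]), c))
    for _, r in bundle.purchased_lines.iterrows():
        c = str(r["cpt_code"]).strip()
        if c in INCLUSION_CPTS:
            hits.setdefault(str(r["person_id"]), []).append((_to_date(r["service_date"]), c))

    births = {
        str(r["person_id"]): _to_date(r["birth_date"]) for _, r in bundle.persons.iterrows()
    }

    members: Dict[str, Tuple[dt.date, str]] = {}
    for pid, events in hits.items():
        index_date, index_cpt = min(events)

        born = births[pid]
        age = index_date.year - born.year - (
            (index_date.month, index_date.day) < (born.month, born.day)
        )
        if not (age_range[0] <= age <= age_range[1]):
            continue

        if _any_prior_exclusion_dx(bundle, pid, index_date, excl):
            continue

        window = [
            index_date + dt.timedelta(days=d) for d in range(-pre_days, post_days + 1)
        ]
        covered: Set[dt.date] = set()
        el = bundle.eligibility
        for _, r in el[el["person_id"].astype(str) == pid].iterrows():
            d = _to_date(r["start_date"])
            stop = _to_date(r["end_date"])
            while d <= stop:
                covered.add(d)
                d += dt.timedelta(days=1)
        if not _gaps_ok(window, covered, gap_tolerance_days):
            continue

        members[pid] = (index_date, index_cpt)
    return members


def _any_prior_exclusion_dx(bundle, pid, index_date, excl) -> bool:
    def norm(c):
        return _norm(c)

    tables = [
        (bundle.inpatient, "admit_date"),
        (bundle.outpatient, "visit_date"),
        (bundle.purchased_institutional, "admit_date"),
        (bundle.purchased_lines, "service_date"),
    ]
    for df, date_col in tables:
        if df.empty:
            continue
        sub = df[df["person_id"].astype(str) == pid]
        for _, r in sub.iterrows():
            if _to_date(r[date_col]) <= index_date:
                if any(norm(c) in excl for c in r["dx_codes"]):
                    return True
    return False


def _gaps_ok(window_days, covered, gap_tolerance_days) -> bool:
    run = 0
    for d in window_days:
        if d in covered:
            run = 0
        else:
            run += 1
            if run > gap_tolerance_days:
                return False
    return True
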