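"""Cohort selection: index events, the three filters, attrition, oracles."""

import numpy as np
import pandas as pd
import pytest

from claimsforge.claims_store import RepositoryBundle, empty_table
from claimsforge.cohort_builder import (
    CohortSpec,
    build_cohort,
    completed_age,
    find_index_events,
    has_prior_exclusion,
    is_continuously_eligible,
    passes_age_filter,
)
from claimsforge.claims_store import Event, all_timelines
from claimsforge.codebook import builtin_registry, exclusion_union

from oracles import bruteforce_cohort


def _mini_bundle(purchased_rows, outpatient_rows=()):
    b = RepositoryBundle.empty()
    b.persons = pd.DataFrame([
        {"person_id": "P1", "birth_date": pd.Timestamp("1980-01-01"),
         "sex": "M", "beneficiary_category": "active", "has_ohi": False},
    ])
    b.eligibility = pd.DataFrame([
        {"person_id": "P1", "start_date": pd.Timestamp("2008-01-01"),
         "end_date": pd.Timestamp("2013-12-31")},
    ])
    if purchased_rows:
        b.purchased_lines = pd.DataFrame(purchased_rows)
    if outpatient_rows:
        rows = []
        for r in outpatient_rows:
            row = dict(r)
            for c in empty_table("outpatient").columns:
                row.setdefault(c, 0.0)
            rows.append(row)
        b.outpatient = pd.DataFrame(rows)
    return b


def _line(claim, date, cpt, dx=("724.2",), provider="PRV1"):
    return {
        "claim_id": claim, "line_number": 1, "person_id": "P1",
        "service_date": pd.Timestamp(date), "dx_codes": list(dx), "cpt_code": cpt,
        "provider_taxonomy": "207Q00000X", "provider_id": provider,
        "paid_amount": 10.0,
    }


def test_index_is_earliest_qualifying_event():
    b = _mini_bundle([
        _line("C1", "2011-01-02", "29914"),
        _line("C2", "2010-03-15", "29916"),
        _line("C3", "2010-06-01", "99213"),
    ])
    reg = builtin_registry()
    idx = find_index_events(b, reg["FAI inclusion CPT"])
    assert idx == {"P1": (pd.Timestamp("2010-03-15"), "29916")}


def test_same_day_tie_breaks_to_smallest_code_regardless_of_row_order():
    rows = [_line("C1", "2010-03-15", "29916"), _line("C2", "2010-03-15", "29862")]
    reg = builtin_registry()
    for perm in (rows, rows[::-1]):
        idx = find_index_events(_mini_bundle(list(perm)), reg["FAI inclusion CPT"])
        assert idx["P1"] == (pd.Timestamp("2010-03-15"), "29862")


def test_person_without_inclusion_code_is_absent():
    b = _mini_bundle([_line("C1", "2010-03-15", "99213")])
    assert find_index_events(b, builtin_registry()["FAI inclusion CPT"]) == {}


@pytest.mark.parametrize(
    "birth,index,expected",
    [
        ("1992-06-01", "2010-06-01", True),   # turns 18 on the index day
        ("1992-06-02", "2010-06-01", False),  # 17, one day short
        ("1960-06-01", "2010-06-01", True),   # exactly 50: inclusive
        ("1959-06-01", "2010-06-01", False),  # 51
    ],
)
def test_age_filter_completed_years_inclusive(birth, index, expected):
    assert passes_age_filter(
        pd.Timestamp(birth), pd.Timestamp(index), (18, 50)
    ) is expected


def test_completed_age_handles_leap_days():
    assert completed_age(pd.Timestamp("2000-02-29"), pd.Timestamp("2018-02-28")) == 17
    assert completed_age(pd.Timestamp("2000-02-29"), pd.Timestamp("2018-03-01")) == 18


def _ev(date, dx):
    return Event(date=pd.Timestamp(date), source="outpatient", record_id="E",
                 person_id="P1", dx_codes=tuple(dx))


def test_prior_exclusion_window_closed_at_index():
    excl = exclusion_union()
    index = pd.Timestamp("2010-06-01")
    assert has_prior_exclusion([_ev("2010-05-02", ["715.35"])], excl, index)
    assert has_prior_exclusion([_ev("2010-06-01", ["733.42"])], excl, index)
    # codes strictly after the surgery never exclude
    assert not has_prior_exclusion([_ev("2010-08-30", ["733.42"])], excl, index)
    assert not has_prior_exclusion([], excl, index)


def _spans(*pairs):
    return pd.DataFrame({
        "person_id": ["P1"] * len(pairs),
        "start_date": pd.to_datetime([a for a, _ in pairs]),
        "end_date": pd.to_datetime([b for _, b in pairs]),
    })


def test_continuous_eligibility_cases():
    idx = pd.Timestamp("2011-01-01")
    full = _spans(("2009-06-01", "2013-06-01"))
    assert is_continuously_eligible(full, idx)

    # coverage missing exactly the last follow-up day
    short = _spans(("2009-06-01", idx + pd.Timedelta(days=729)))
    assert not is_continuously_eligible(short, idx)
    assert is_continuously_eligible(short, idx, gap_tolerance_days=1)

    # an interior 20-day gap passes only with tolerance
    gappy = _spans(("2009-06-01", "2011-06-30"), ("2011-07-21", "2013-06-01"))
    assert not is_continuously_eligible(gappy, idx)
    assert is_continuously_eligible(gappy, idx, gap_tolerance_days=30)

    assert not is_continuously_eligible(_spans(), idx)


def test_eligibility_agrees_with_day_by_day_scan():
    """Randomized spans versus a brute-force daily coverage check."""
    import datetime as dt

    rng = np.random.default_rng(123)
    idx = pd.Timestamp("2011-01-01")
    for _ in range(60):
        n_spans = int(rng.integers(1, 4))
        pairs = []
        for _ in range(n_spans):
            start = idx + pd.Timedelta(days=int(rng.integers(-500, 600)))
            pairs.append((start, start + pd.Timedelta(days=int(rng.integers(30, 700)))))
        spans = _spans(*pairs)
        tol = int(rng.integers(0, 40))
        got = is_continuously_eligible(spans, idx, gap_tolerance_days=tol)

        covered = set()
        for a, b in pairs:
            d = a.date()
            while d <= b.date():
                covered.add(d)
                d += dt.timedelta(days=1)
        run, ok = 0, True
        for off in range(-365, 731):
            if (idx + pd.Timedelta(days=off)).date() in covered:
                run = 0
            else:
                run += 1
                if run > tol:
                    ok = False
                    break
        assert got is ok


def test_build_cohort_recovers_planted_truth(small_repo):
    bundle, truth = small_repo
    members, attrition = build_cohort(bundle)
    assert {m.person_id for m in members} == truth.true_cohort
    for m in members:
        assert m.index_date == truth.true_index_dates[m.person_id]
        assert m.window_start == m.index_date - pd.Timedelta(days=365)
        assert m.window_end == m.index_date + pd.Timedelta(days=730)

    # attrition telescopes and matches the planted sabotage reasons
    df = attrition.to_frame()
    for k in range(1, len(df)):
        assert df.loc[k, "retained"] == df.loc[k - 1, "retained"] - df.loc[k, "removed"]
    reasons = list(truth.excluded.values())
    assert df.loc[1, "removed"] == reasons.count("age")
    assert df.loc[2, "removed"] == reasons.count("prior_exclusion")
    assert df.loc[3, "removed"] == reasons.count("eligibility_gap")


def test_build_cohort_empty_when_no_qualifying_codes():
    from claimsforge.synthetic_claims import GeneratorConfig, generate

    bundle, _ = generate(GeneratorConfig(n_persons=40, surgery_prevalence=0.0, seed=2))
    members, attrition = build_cohort(bundle)
    assert members == []
    assert attrition.to_frame()["retained"].tolist() == [0, 0, 0, 0]


def test_build_cohort_matches_bruteforce_scan(small_repo):
    bundle, _ = small_repo
    members, _ = build_cohort(bundle)
    oracle = bruteforce_cohort(bundle)
    assert {m.person_id for m in members} == set(oracle)
    for m in members:
        assert (m.index_date.date(), m.index_cpt) == oracle[m.person_id]


def test_final_membership_invariant_to_filter_order(small_repo):
    from itertools import permutations

    bundle, _ = small_repo
    spec = CohortSpec.default()
    timelines = all_timelines(bundle)
    idx = find_index_events(bundle, spec.inclusion_set, timelines=timelines)
    births = dict(zip(bundle.persons["person_id"].astype(str),
                      pd.to_datetime(bundle.persons["birth_date"])))
    elig = bundle.eligibility

    def f_age(pids):
        return {p for p in pids if passes_age_filter(births[p], idx[p][0], spec.age_range)}

    def f_excl(pids):
        return {p for p in pids
                if not has_prior_exclusion(timelines[p], spec.exclusion_set, idx[p][0])}

    def f_elig(pids):
        return {p for p in pids if is_continuously_eligible(
            elig[elig["person_id"].astype(str) == p], idx[p][0],
            spec.pre_days, spec.post_days, spec.gap_tolerance_days)}

    results = set()
    for order in permutations([f_age, f_excl, f_elig]):
        pids = set(idx)
        for f in order:
            pids = f(pids)
        results.add(frozenset(pids))
    assert len(results) == 1
    members, _ = build_cohort(bundle, spec, timelines=timelines)
    assert results.pop() == {m.person_id for m in members}


def test_cohort_independent_of_row_order(small_repo):
    bundle, _ = small_repo
    shuffled = bundle.copy()
    rng = np.random.default_rng(5)
    for t in ("outpatient", "purchased_lines", "inpatient", "eligibility"):
        df = shuffled.table(t)
        setattr(shuffled, t, df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True))
    m1, _ = build_cohort(bundle)
    m2, _ = build_cohort(shuffled)
    assert m1 == m2
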