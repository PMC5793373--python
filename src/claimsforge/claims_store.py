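"""Linked claims tables: schemas, fiscal-year CSV I/O, validation, timelines.

A repository bundle holds eight person-linked tables emulating a
multi-source claims warehouse:

* ``persons``                 — one row per beneficiary
* ``eligibility``             — enrollment coverage spans
* ``inpatient``               — direct-care hospital stays (SIDR-like)
* ``outpatient``              — direct-care ambulatory encounters (CAPER-like),
                                carrying the 14 full-cost subcomponents
* ``purchased_institutional`` — civilian institutional stays (TED-I-like)
* ``purchased_lines``         — civilian claim lines (TED-NI-like); several
                                lines may constitute one clinical visit
* ``prescriptions``           — outpatient pharmacy fills (PDTS-like)
* ``ancillary``               — lab/radiology procedures with accession links

Event tables are stored on disk as ``<table>_FY<year>.csv`` partitioned by
US federal fiscal year (Oct 1 – Sep 30); ``persons.csv`` and
``eligibility.csv`` are unpartitioned.  List-valued cells (diagnosis codes)
are semicolon-joined.  All dates are ISO-8601 calendar dates; the store
operates at day resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FULL_COST_COMPONENTS = (
    "FCCLNSAL", "FCLAB",
    "FCOST1", "FCOST2", "FCOST3", "FCOST4", "FCOST5", "FCOST6",
    "FCOTHANC", "FCOTHLBR", "FCPROFSAL", "FCRAD", "FCRX", "FCSUP",
)

EVENT_TABLES = (
    "inpatient", "outpatient", "purchased_institutional",
    "purchased_lines", "prescriptions", "ancillary",
)
ALL_TABLES = ("persons", "eligibility") + EVENT_TABLES

#: primary event-date column per event table (drives fiscal-year partitioning)
DATE_COLUMN = {
    "inpatient": "admit_date",
    "outpatient": "visit_date",
    "purchased_institutional": "admit_date",
    "purchased_lines": "service_date",
    "prescriptions": "fill_date",
    "ancillary": "procedure_date",
}

SCHEMAS: Dict[str, List[str]] = {
    "persons": ["person_id", "birth_date", "sex", "beneficiary_category", "has_ohi"],
    "eligibility": ["person_id", "start_date", "end_date"],
    "inpatient": [
        "encounter_id", "person_id", "admit_date", "discharge_date",
        "dx_codes", "proc_codes", "full_cost", "rwp", "department", "visit_count",
    ],
    "outpatient": [
        "encounter_id", "person_id", "visit_date", "dx_codes", "cpt_codes",
        "provider_taxonomy", "product_line", *FULL_COST_COMPONENTS,
        "pain_score", "visit_count",
    ],
    "purchased_institutional": [
        "encounter_id", "person_id", "admit_date", "discharge_date",
        "dx_codes", "proc_codes", "paid_amount",
    ],
    "purchased_lines": [
        "claim_id", "line_number", "person_id", "service_date", "dx_codes",
        "cpt_code", "provider_taxonomy", "provider_id", "paid_amount",
    ],
    "prescriptions": [
        "rx_id", "person_id", "fill_date", "generic_name",
        "therapeutic_class", "days_supply", "cost",
    ],
    "ancillary": [
        "record_id", "person_id", "proc_code", "accession_number",
        "procedure_date", "inpatient_flag",
    ],
}

_DATE_COLUMNS = {
    "persons": ["birth_date"],
    "eligibility": ["start_date", "end_date"],
    "inpatient": ["admit_date", "discharge_date"],
    "outpatient": ["visit_date"],
    "purchased_institutional": ["admit_date", "discharge_date"],
    "purchased_lines": ["service_date"],
    "prescriptions": ["fill_date"],
    "ancillary": ["procedure_date"],
}

_LIST_COLUMNS = {
    "inpatient": ["dx_codes", "proc_codes"],
    "outpatient": ["dx_codes", "cpt_codes"],
    "purchased_institutional": ["dx_codes", "proc_codes"],
    "purchased_lines": ["dx_codes"],
}

#: record-id column per event table (used for deterministic tie-breaks)
ID_COLUMN = {
    "inpatient": "encounter_id",
    "outpatient": "encounter_id",
    "purchased_institutional": "encounter_id",
    "purchased_lines": "claim_id",
    "prescriptions": "rx_id",
    "ancillary": "record_id",
}


class SchemaError(ValueError):
    pass


class LookupError_(KeyError):
    pass


def fiscal_year(date: pd.Timestamp) -> int:
    """US federal fiscal year: FY2010 runs 2009-10-01 through 2010-09-30."""
    d = pd.Timestamp(date)
    return d.year + 1 if d.month >= 10 else d.year


def empty_table(table: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in SCHEMAS[table]})
    for c in _DATE_COLUMNS.get(table, []):
        df[c] = pd.Series(dtype="datetime64[ns]")
    return df


@dataclass
class RepositoryBundle:
    """The eight linked tables constituting one claims repository."""

    persons: pd.DataFrame
    eligibility: pd.DataFrame
    inpatient: pd.DataFrame
    outpatient: pd.DataFrame
    purchased_institutional: pd.DataFrame
    purchased_lines: pd.DataFrame
    prescriptions: pd.DataFrame
    ancillary: pd.DataFrame
    read_errors: List[Tuple[str, dict, str]] = field(default_factory=list)

    @classmethod
    def empty(cls) -> "RepositoryBundle":
        return cls(**{t: empty_table(t) for t in ALL_TABLES})

    def table(self, name: str) -> pd.DataFrame:
        if name not in ALL_TABLES:
            raise KeyError(name)
        return getattr(self, name)

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {t: getattr(self, t) for t in ALL_TABLES}

    def copy(self) -> "RepositoryBundle":
        return RepositoryBundle(
            **{t: getattr(self, t).copy() for t in ALL_TABLES},
            read_errors=list(self.read_errors),
        )

    def counts(self) -> Dict[str, int]:
        return {t: len(getattr(self, t)) for t in ALL_TABLES}


@dataclass
class ValidationReport:
    """Per-table clean counts plus the error file (record, reason) entries."""

    clean_counts: Dict[str, int]
    error_records: Dict[str, List[Tuple[dict, str]]]
    immature_counts: Dict[str, int] = field(default_factory=dict)

    def n_errors(self, table: Optional[str] = None) -> int:
        if table is not None:
            return len(self.error_records.get(table, []))
        return sum(len(v) for v in self.error_records.values())


def merge_spans(spans: pd.DataFrame) -> pd.DataFrame:
    """Normalize eligibility spans: merge overlapping/abutting per person."""
    if spans.empty:
        return spans.copy()
    out = []
    for pid, grp in spans.sort_values(["person_id", "start_date"]).groupby(
        "person_id", sort=True
    ):
        cur_s, cur_e = None, None
        for s, e in zip(grp["start_date"], grp["end_date"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + pd.Timedelta(days=1):  # abutting counts as joined
                cur_e = max(cur_e, e)
            else:
                out.append((pid, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((pid, cur_s, cur_e))
    return pd.DataFrame(out, columns=["person_id", "start_date", "end_date"])


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _join_lists(df: pd.DataFrame, table: str) -> pd.DataFrame:
    df = df.copy()
    for c in _LIST_COLUMNS.get(table, []):
        df[c] = df[c].map(lambda v: ";".join(v) if isinstance(v, (list, tuple)) else (v or ""))
    return df


def _split_lists(df: pd.DataFrame, table: str) -> pd.DataFrame:
    for c in _LIST_COLUMNS.get(table, []):
        df[c] = df[c].map(
            lambda v: [] if (v is None or (isinstance(v, float) and np.isnan(v)) or v == "")
            else [s for s in str(v).split(";") if s]
        )
    return df


def write_repository(bundle: RepositoryBundle, directory: str | Path) -> None:
    """Write the bundle as fiscal-year-partitioned CSV under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for table in ("persons", "eligibility"):
        df = _format_dates(bundle.table(table), table)
        df.to_csv(directory / f"{table}.csv", index=False)
    for table in EVENT_TABLES:
        df = bundle.table(table)
        date_col = DATE_COLUMN[table]
        if df.empty:
            continue
        fys = df[date_col].map(fiscal_year)
        for fy, grp in df.groupby(fys, sort=True):
            out = _format_dates(_join_lists(grp, table), table)
            out.to_csv(directory / f"{table}_FY{fy}.csv", index=False)


def _format_dates(df: pd.DataFrame, table: str) -> pd.DataFrame:
    # canonical schema column order (extras like `immature` stay at the end)
    order = [c for c in SCHEMAS[table] if c in df.columns]
    order += [c for c in df.columns if c not in order]
    df = df[order].copy()
    for c in _DATE_COLUMNS.get(table, []):
        df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
    return df


def read_repository(directory: str | Path) -> RepositoryBundle:
    """Read a partitioned repository; concatenates all fiscal years per table.

    Missing mandatory columns raise :class:`SchemaError`; rows whose primary
    date fails to parse are routed to ``bundle.read_errors`` rather than
    aborting the load.  Eligibility spans are normalized (merged) on load.
    """
    directory = Path(directory)
    frames: Dict[str, pd.DataFrame] = {}
    read_errors: List[Tuple[str, dict, str]] = []

    for table in ("persons", "eligibility"):
        path = directory / f"{table}.csv"
        frames[table] = (
            _load_csv(path, table, read_errors) if path.exists() else empty_table(table)
        )

    for table in EVENT_TABLES:
        paths = sorted(directory.glob(f"{table}_FY*.csv"))
        if not paths:
            frames[table] = empty_table(table)
            continue
        parts = [_load_csv(p, table, read_errors) for p in paths]
        frames[table] = pd.concat(parts, ignore_index=True)

    frames["eligibility"] = merge_spans(frames["eligibility"])
    bundle = RepositoryBundle(**frames, read_errors=read_errors)
    for t in ALL_TABLES:
        logger.info("read %s: %d rows", t, len(frames[t]))
    return bundle


def _load_csv(
    path: Path, table: str, read_errors: List[Tuple[str, dict, str]]
) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    df = df[SCHEMAS[table]]
    for c in _DATE_COLUMNS.get(table, []):
        parsed = pd.to_datetime(df[c], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & (df[c] != "")
        for _, row in df[bad].iterrows():
            read_errors.append((table, row.to_dict(), f"unparseable date in {c}"))
        df = df[~bad]
        parsed = parsed[~bad]
        df = df.copy()
        df[c] = parsed
    df = _split_lists(df, table)
    int_cols = _INT_COLUMNS.get(table, [])
    for c in _numeric_columns(table):
        df[c] = pd.to_numeric(df[c], errors="coerce")
        if c in int_cols:
            df[c] = df[c].astype("Int64")  # nullable: blank pain scores stay blank
    return df.reset_index(drop=True)


_INT_COLUMNS = {
    "inpatient": ["visit_count"],
    "outpatient": ["pain_score", "visit_count"],
    "purchased_lines": ["line_number"],
    "prescriptions": ["days_supply"],
}


def _numeric_columns(table: str) -> List[str]:
    return {
        "inpatient": ["full_cost", "rwp", "visit_count"],
        "outpatient": [*FULL_COST_COMPONENTS, "pain_score", "visit_count"],
        "purchased_institutional": ["paid_amount"],
        "purchased_lines": ["line_number", "paid_amount"],
        "prescriptions": ["days_supply", "cost"],
        "ancillary": [],
        "persons": [],
        "eligibility": [],
    }[table]


# ---------------------------------------------------------------------------
# Validation (DHA-style error-file rules)
# ---------------------------------------------------------------------------

def validate_repository(
    bundle: RepositoryBundle,
    query_date: pd.Timestamp,
    maturity_days: int = 90,
    drop_immature: bool = False,
) -> Tuple[RepositoryBundle, ValidationReport]:
    """Apply the error-file rules and the data-maturity flag.

    Records with a blank encounter/claim identifier, with no diagnosis code,
    or (for encounter tables other than the direct-care outpatient file) no
    procedure/CPT code, and direct-care records with a visit count of zero,
    are moved to the error report.  Direct-care outpatient (CAPER-like)
    records are exempt from the CPT requirement.  Records whose event date
    falls within ``maturity_days`` before ``query_date`` are flagged
    ``immature`` — retained by default, dropped when ``drop_immature``.
    """
    query_date = pd.Timestamp(query_date)
    clean: Dict[str, pd.DataFrame] = {
        "persons": bundle.persons.copy(),
        "eligibility": bundle.eligibility.copy(),
    }
    errors: Dict[str, List[Tuple[dict, str]]] = {}
    immature_counts: Dict[str, int] = {}

    for table in EVENT_TABLES:
        df = bundle.table(table).copy().reset_index(drop=True)
        reasons = pd.Series([None] * len(df), dtype=object)

        id_col = ID_COLUMN[table]
        blank_id = df[id_col].astype(str).str.strip().isin(["", "nan", "None"])
        reasons[blank_id & reasons.isna()] = f"blank {id_col}"

        if table in _LIST_COLUMNS:  # encounter-type tables carry diagnoses
            no_dx = df["dx_codes"].map(len) == 0
            reasons[no_dx & reasons.isna()] = "blank ICD code"

        if table in ("inpatient", "purchased_institutional"):
            no_proc = df["proc_codes"].map(len) == 0
            reasons[no_proc & reasons.isna()] = "blank procedure code"
        elif table == "purchased_lines":
            no_cpt = df["cpt_code"].astype(str).str.strip().isin(["", "nan", "None"])
            reasons[no_cpt & reasons.isna()] = "blank CPT code"
        elif table == "ancillary":
            no_proc = df["proc_code"].astype(str).str.strip().isin(["", "nan", "None"])
            reasons[no_proc & reasons.isna()] = "blank procedure code"
        # outpatient (CAPER-like) is exempt from the CPT requirement

        if table in ("inpatient", "outpatient"):
            zero_visits = pd.to_numeric(df["visit_count"], errors="coerce") == 0
            reasons[zero_visits & reasons.isna()] = "visit count of zero"

        bad = reasons.notna()
        errors[table] = [
            (row.to_dict(), reason)
            for (_, row), reason in zip(df[bad].iterrows(), reasons[bad])
        ]
        kept = df[~bad].reset_index(drop=True)

        date_col = DATE_COLUMN[table]
        dates = pd.to_datetime(kept[date_col])
        immature = (dates > query_date - pd.Timedelta(days=maturity_days)) & (
            dates <= query_date
        )
        kept["immature"] = immature.to_numpy()
        immature_counts[table] = int(immature.sum())
        if drop_immature:
            kept = kept[~kept["immature"]].reset_index(drop=True)
        clean[table] = kept

        if errors[table]:
            logger.info("%s: %d record(s) routed to error file", table, len(errors[table]))

    report = ValidationReport(
        clean_counts={t: len(clean[t]) for t in ALL_TABLES},
        error_records=errors,
        immature_counts=immature_counts,
    )
    return RepositoryBundle(**clean, read_errors=list(bundle.read_errors)), report


# ---------------------------------------------------------------------------
# Person timelines
# ---------------------------------------------------------------------------

#: stable source ordering for same-day events
SOURCE_RANK = {t: i for i, t in enumerate(EVENT_TABLES)}


@dataclass(frozen=True)
class Event:
    """One dated record from any event table, tagged with its source."""

    date: pd.Timestamp
    source: str
    record_id: str
    person_id: str
    dx_codes: tuple = ()
    proc_codes: tuple = ()
    cost: float = 0.0
    payload: tuple = ()  # sorted (key, value) pairs of source-specific fields

    def get(self, key, default=None):
        return dict(self.payload).get(key, default)


def _row_events(table: str, df: pd.DataFrame) -> Iterable[Event]:
    date_col, id_col = DATE_COLUMN[table], ID_COLUMN[table]
    for _, row in df.iterrows():
        dx = tuple(row["dx_codes"]) if "dx_codes" in row else ()
        if table in ("inpatient", "purchased_institutional"):
            proc = tuple(row["proc_codes"])
            cost = float(row["full_cost"]) if table == "inpatient" else float(row["paid_amount"])
        elif table == "outpatient":
            proc = tuple(row["cpt_codes"])
            cost = float(sum(float(row[c]) for c in FULL_COST_COMPONENTS))
        elif table == "purchased_lines":
            proc = tuple([row["cpt_code"]]) if str(row["cpt_code"]).strip() else ()
            cost = float(row["paid_amount"])
        elif table == "prescriptions":
            proc, cost = (), float(row["cost"])
        else:  # ancillary
            proc = (row["proc_code"],) if str(row["proc_code"]).strip() else ()
            cost = 0.0
        payload_keys = {
            "outpatient": ["provider_taxonomy", "product_line"],
            "purchased_lines": ["provider_taxonomy", "provider_id", "line_number"],
            "prescriptions": ["therapeutic_class", "days_supply", "generic_name"],
            "inpatient": ["department"],
            "ancillary": ["accession_number", "inpatient_flag"],
            "purchased_institutional": [],
        }[table]
        yield Event(
            date=pd.Timestamp(row[date_col]),
            source=table,
            record_id=str(row[id_col]),
            person_id=str(row["person_id"]),
            dx_codes=dx,
            proc_codes=proc,
            cost=cost,
            payload=tuple(sorted((k, row[k]) for k in payload_keys)),
        )


def person_timeline(bundle: RepositoryBundle, person_id: str) -> List[Event]:
    """All events for one person across every table, in stable date order.

    Ties on the same calendar day are broken by (source-table rank,
    record id), so the result is independent of input row order.
    """
    if person_id not in set(bundle.persons["person_id"].astype(str)):
        raise LookupError_(f"unknown person_id: {person_id!r}")
    events: List[Event] = []
    for table in EVENT_TABLES:
        df = bundle.table(table)
        if df.empty:
            continue
        sub = df[df["person_id"].astype(str) == str(person_id)]
        events.extend(_row_events(table, sub))
    events.sort(key=lambda e: (e.date, SOURCE_RANK[e.source], e.record_id))
    return events


def all_timelines(bundle: RepositoryBundle) -> Dict[str, List[Event]]:
    """Timelines for every person in the population table, in one pass."""
    ids = [str(p) for p in bundle.persons["person_id"]]
    out: Dict[str, List[Event]] = {pid: [] for pid in ids}
    for table in EVENT_TABLES:
        df = bundle.table(table)
        if df.empty:
            continue
        for ev in _row_events(table, df):
            if ev.person_id in out:
                out[ev.person_id].append(ev)
    for pid in out:
        out[pid].sort(key=lambda e: (e.date, SOURCE_RANK[e.source], e.record_id))
    return out
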