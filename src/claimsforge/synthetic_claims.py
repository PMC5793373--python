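"""Seeded synthetic claims repositories with planted ground truth.

No real claims data is distributable, so studies of the downstream pipeline
run against generated repositories that reproduce the *structural* features
the pipeline assumes: person-level linkage across eight tables, fiscal-year
partitioning, multi-line purchased-care claims, ICD-9 diagnosis and CPT
procedure coding, therapeutic-class-coded prescriptions with days' supply,
and per-encounter full-cost subcomponents.

Every generated repository comes with a :class:`PlantedTruth` recording, by
construction, who belongs in the surgical cohort, each person's index date,
their comorbidity flags, and the per-comorbidity cost effects — so pipeline
output can be checked against a known answer rather than another
implementation.

A configurable fraction of surgery candidates is deliberately sabotaged
(eligibility gap, pre-index exclusion diagnosis) and recorded with the
reason, giving the cohort attrition table a ground truth; candidates whose
age falls outside the study band are recorded the same way.

Cost components are gamma distributed (non-negative and right-skewed, the
stylized shape of healthcare costs), and each person's encounter costs are
scaled by ``exp(sum of planted per-comorbidity log-scale effects)`` so that
a log-scale regression of total cost on comorbidity flags recovers the
planted weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .codebook import (
    COMORBIDITY_LABELS,
    FAI_INCLUSION_LABEL,
    OPIOID_LABEL,
    builtin_registry,
    exclusion_union,
    expand_pattern,
)
from .claims_store import (
    FULL_COST_COMPONENTS,
    RepositoryBundle,
    empty_table,
    merge_spans,
)


class ConfigError(ValueError):
    pass


class MissingnessSpecError(ValueError):
    pass


DEFAULT_COMORBIDITY_PREVALENCE: Dict[str, float] = {
    "Sleep Disorders": 0.10,
    "Mental Health": 0.20,
    "Substance Abuse": 0.08,
    "Tobacco Use": 0.25,
    "Metabolic Syndromes": 0.10,
    "Chronic Pain": 0.15,
    "Cardiovascular": 0.08,
    "Systemic Arthropathies": 0.04,
}

#: planted log-scale cost effect per comorbidity
DEFAULT_RISK_WEIGHTS: Dict[str, float] = {
    "Sleep Disorders": 0.15,
    "Mental Health": 0.25,
    "Substance Abuse": 0.20,
    "Tobacco Use": 0.10,
    "Metabolic Syndromes": 0.30,
    "Chronic Pain": 0.35,
    "Cardiovascular": 0.40,
    "Systemic Arthropathies": 0.50,
}

#: mean dollars per outpatient visit for each full-cost subcomponent
DEFAULT_COST_MODEL: Dict[str, float] = {
    "FCCLNSAL": 60.0, "FCPROFSAL": 40.0, "FCSUP": 25.0, "FCOTHLBR": 15.0,
    "FCRAD": 10.0, "FCLAB": 8.0, "FCRX": 5.0, "FCOTHANC": 5.0,
    "FCOST1": 30.0, "FCOST2": 0.0, "FCOST3": 0.0, "FCOST4": 0.0,
    "FCOST5": 0.0, "FCOST6": 0.0,
}

# background codes chosen to be inert: verified at generation time to match
# neither the exclusion screen, any comorbidity set, nor the hip-related set
_BENIGN_DX = ["724.2", "723.1", "719.46", "845.00", "847.2", "486", "465.9", "692.9"]
_BENIGN_CPT = ["99213", "99214", "97110", "97140", "20610", "72148", "73721"]
_HIP_SURGERY_DX = "719.45"  # hip/pelvis joint pain, carried on surgery encounters
_TAXONOMIES = ["207Q00000X", "207X00000X", "225100000X", "208100000X", "363L00000X"]
_PRODUCT_LINES = ["Primary Care", "Orthopaedics", "Physical Therapy", "Radiology"]
_DEPARTMENTS = ["Orthopaedics", "General Surgery", "Internal Medicine"]
_NONOPIOID_RX = [("ibuprofen", "062800"), ("naproxen", "062800"),
                 ("cyclobenzaprine", "122000"), ("omeprazole", "492000")]
_OPIOID_RX_NAMES = ["oxycodone", "hydrocodone/acetaminophen"]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic repository."""

    n_persons: int = 500
    date_window: Tuple[str, str] = ("2008-10-01", "2013-09-30")
    surgery_prevalence: float = 0.20
    comorbidity_prevalence: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE)
    )
    exclusion_dx_prevalence: float = 0.05
    eligibility_gap_rate: float = 0.10
    ohi_rate: float = 0.03
    opioid_rx_rate_post_surgery: float = 0.50
    mean_visits_per_person_year: float = 3.0
    cost_model: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COST_MODEL))
    true_risk_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_WEIGHTS)
    )
    sabotage_rate: float = 0.25
    purchased_fraction: float = 0.40
    pre_days: int = 365
    post_days: int = 730
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.surgery_prevalence, self.exclusion_dx_prevalence,
            self.eligibility_gap_rate, self.ohi_rate,
            self.opioid_rx_rate_post_surgery, self.sabotage_rate,
            self.purchased_fraction, *self.comorbidity_prevalence.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("all prevalences/rates must lie in [0, 1]")
        if self.n_persons < 1:
            raise ConfigError("n_persons must be >= 1")
        start, end = pd.Timestamp(self.date_window[0]), pd.Timestamp(self.date_window[1])
        if start + pd.Timedelta(days=self.pre_days + self.post_days) > end:
            raise ConfigError(
                "date window too short for any index date with full surveillance"
            )


@dataclass
class PlantedTruth:
    """Ground truth planted into a generated repository."""

    true_cohort: Set[str]
    true_index_dates: Dict[str, pd.Timestamp]
    true_comorbidity_flags: Dict[str, Dict[str, bool]]
    true_risk_weights: Dict[str, float]
    excluded: Dict[str, str]  # candidate person_id -> sabotage/exclusion reason

    def to_jsonable(self) -> dict:
        return {
            "true_cohort": sorted(self.true_cohort),
            "true_index_dates": {
                k: v.strftime("%Y-%m-%d") for k, v in sorted(self.true_index_dates.items())
            },
            "true_comorbidity_flags": {
                k: self.true_comorbidity_flags[k] for k in sorted(self.true_comorbidity_flags)
            },
            "true_risk_weights": self.true_risk_weights,
            "excluded": dict(sorted(self.excluded.items())),
        }


def _expansions(registry) -> Dict[str, List[str]]:
    """Concrete sampled-code pools per comorbidity label and exclusion screen."""
    pools: Dict[str, List[str]] = {}
    for label in COMORBIDITY_LABELS:
        codes: List[str] = []
        for p in registry[label].patterns:
            codes.extend(expand_pattern(p))
        pools[label] = sorted(set(codes))
    excl: List[str] = []
    for p in exclusion_union(registry).patterns:
        excl.extend(expand_pattern(p))
    pools["__exclusion__"] = sorted(set(excl))
    return pools


def _assert_benign(registry) -> None:
    screens = [registry[l] for l in COMORBIDITY_LABELS] + [exclusion_union(registry)]
    for dx in _BENIGN_DX:
        for s in screens:
            if s.matches_code(dx):  # pragma: no cover - generator self-check
                raise AssertionError(f"background dx {dx} collides with {s.label}")


def generate(config: GeneratorConfig) -> Tuple[RepositoryBundle, PlantedTruth]:
    """Generate one repository plus its planted truth. Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    registry = builtin_registry()
    _assert_benign(registry)
    pools = _expansions(registry)
    fai_cpts = [p.exact for p in registry[FAI_INCLUSION_LABEL].patterns]
    opioid_classes = [p.exact for p in registry[OPIOID_LABEL].patterns]

    win_start = pd.Timestamp(config.date_window[0])
    win_end = pd.Timestamp(config.date_window[1])
    idx_lo = win_start + pd.Timedelta(days=config.pre_days)
    idx_hi = win_end - pd.Timedelta(days=config.post_days)
    idx_span = (idx_hi - idx_lo).days
    window_days = (win_end - win_start).days
    years = window_days / 365.25

    rows: Dict[str, list] = {t: [] for t in (
        "persons", "eligibility", "inpatient", "outpatient",
        "purchased_institutional", "purchased_lines", "prescriptions", "ancillary",
    )}
    counters = {"enc": 0, "claim": 0, "rx": 0, "anc": 0}

    truth = PlantedTruth(
        true_cohort=set(),
        true_index_dates={},
        true_comorbidity_flags={},
        true_risk_weights=dict(config.true_risk_weights),
        excluded={},
    )

    def next_id(kind: str, prefix: str) -> str:
        counters[kind] += 1
        return f"{prefix}{counters[kind]:08d}"

    def day(base: pd.Timestamp, offset: int) -> pd.Timestamp:
        return base + pd.Timedelta(days=int(offset))

    def gamma_cost(mean: float, mult: float) -> float:
        if mean <= 0:
            return 0.0
        return round(float(rng.gamma(2.0, mean / 2.0) * mult), 2)

    def add_outpatient(pid, date, dx, cpts, mult, product_line=None, taxonomy=None):
        row = {
            "encounter_id": next_id("enc", "E"),
            "person_id": pid,
            "visit_date": date,
            "dx_codes": list(dx),
            "cpt_codes": list(cpts),
            "provider_taxonomy": taxonomy or _TAXONOMIES[rng.integers(len(_TAXONOMIES))],
            "product_line": product_line or _PRODUCT_LINES[rng.integers(len(_PRODUCT_LINES))],
            "pain_score": int(rng.integers(0, 11)) if rng.random() < 0.3 else "",
            "visit_count": 1,
        }
        for c in FULL_COST_COMPONENTS:
            row[c] = gamma_cost(config.cost_model.get(c, 0.0), mult)
        rows["outpatient"].append(row)
        return row

    def add_purchased_visit(pid, date, dx, cpt, mult):
        provider = f"PRV{int(rng.integers(1, 40)):04d}"
        n_lines = int(rng.integers(1, 5))
        claim_id = next_id("claim", "C")
        for ln in range(1, n_lines + 1):
            rows["purchased_lines"].append({
                "claim_id": claim_id,
                "line_number": ln,
                "person_id": pid,
                "service_date": date,
                "dx_codes": list(dx),
                "cpt_code": cpt if ln == 1 else _BENIGN_CPT[rng.integers(len(_BENIGN_CPT))],
                "provider_taxonomy": _TAXONOMIES[rng.integers(len(_TAXONOMIES))],
                "provider_id": provider,
                "paid_amount": gamma_cost(45.0, mult),
            })

    for i in range(config.n_persons):
        pid = f"P{i + 1:06d}"
        is_candidate = rng.random() < config.surgery_prevalence
        if is_candidate:
            index_date = day(idx_lo, rng.integers(0, idx_span + 1))
            ref = index_date
        else:
            index_date = None
            ref = day(win_start, window_days // 2)

        age = float(rng.uniform(16.0, 55.0))
        birth_date = ref - pd.Timedelta(days=int(round(age * 365.25)))
        rows["persons"].append({
            "person_id": pid,
            "birth_date": birth_date,
            "sex": "F" if rng.random() < 0.5 else "M",
            "beneficiary_category": ["active", "family", "retired"][rng.integers(3)],
            "has_ohi": bool(rng.random() < config.ohi_rate),
        })

        # comorbidity flags and planted cost multiplier
        flags = {
            label: bool(rng.random() < config.comorbidity_prevalence.get(label, 0.0))
            for label in COMORBIDITY_LABELS
        }
        truth.true_comorbidity_flags[pid] = flags
        mult = float(np.exp(sum(
            config.true_risk_weights.get(l, 0.0) for l, f in flags.items() if f
        )))

        # sabotage accounting for surgery candidates
        reason: Optional[str] = None
        if is_candidate:
            completed_age = (
                index_date.year - birth_date.year
                - ((index_date.month, index_date.day) < (birth_date.month, birth_date.day))
            )
            if not (18 <= completed_age <= 50):
                reason = "age"
            elif rng.random() < config.sabotage_rate:
                reason = "eligibility_gap" if rng.random() < 0.5 else "prior_exclusion"
            truth.true_index_dates[pid] = index_date
            if reason is None:
                truth.true_cohort.add(pid)
            else:
                truth.excluded[pid] = reason

        # eligibility spans
        if reason == "eligibility_gap":
            gap_start = day(index_date, int(rng.integers(30, config.post_days - 60)))
            rows["eligibility"].append(
                {"person_id": pid, "start_date": win_start, "end_date": day(gap_start, -1)}
            )
            rows["eligibility"].append(
                {"person_id": pid, "start_date": day(gap_start, 30), "end_date": win_end}
            )
        elif not is_candidate and rng.random() < config.eligibility_gap_rate:
            gap_start = day(win_start, rng.integers(0, max(window_days - 90, 1)))
            rows["eligibility"].append(
                {"person_id": pid, "start_date": win_start, "end_date": day(gap_start, -1)}
            )
            rows["eligibility"].append(
                {"person_id": pid, "start_date": day(gap_start, int(rng.integers(30, 91))),
                 "end_date": win_end}
            )
        else:
            rows["eligibility"].append(
                {"person_id": pid, "start_date": win_start, "end_date": win_end}
            )

        # index surgery encounter
        if is_candidate:
            cpt = fai_cpts[rng.integers(len(fai_cpts))]
            if rng.random() < 0.2:
                rows["inpatient"].append({
                    "encounter_id": next_id("enc", "E"),
                    "person_id": pid,
                    "admit_date": index_date,
                    "discharge_date": day(index_date, rng.integers(1, 4)),
                    "dx_codes": [_HIP_SURGERY_DX],
                    "proc_codes": [cpt],
                    "full_cost": gamma_cost(8000.0, mult),
                    "rwp": round(float(rng.uniform(0.8, 3.0)), 3),
                    "department": "Orthopaedics",
                    "visit_count": 1,
                })
            else:
                add_outpatient(
                    pid, index_date, [_HIP_SURGERY_DX], [cpt], mult,
                    product_line="Orthopaedics", taxonomy="207X00000X",
                )

        # pre-index exclusion sabotage / harmless post-index exclusion dx
        if reason == "prior_exclusion":
            dx = pools["__exclusion__"][rng.integers(len(pools["__exclusion__"]))]
            add_outpatient(pid, day(index_date, -int(rng.integers(1, config.pre_days))),
                           [dx], [_BENIGN_CPT[0]], mult)
        if pid in truth.true_cohort and rng.random() < config.exclusion_dx_prevalence:
            dx = pools["__exclusion__"][rng.integers(len(pools["__exclusion__"]))]
            add_outpatient(pid, day(index_date, int(rng.integers(31, config.post_days - 30))),
                           [dx], [_BENIGN_CPT[0]], mult)

        # utilization: a Poisson visit budget, the first visits of which carry
        # the planted comorbidity diagnoses (so flags add no extra visits and
        # the planted cost multiplier stays exactly recoverable).  Candidates'
        # comorbidity visits land inside the 12-month look-back so windowed
        # flagging reproduces the planted flags.
        planted_labels = [l for l in COMORBIDITY_LABELS if flags[l]]
        n_visits = max(
            int(rng.poisson(config.mean_visits_per_person_year * years)),
            len(planted_labels),
        )
        for v in range(n_visits):
            if v < len(planted_labels):
                pool = pools[planted_labels[v]]
                dx = [pool[rng.integers(len(pool))]]
                if is_candidate:
                    date = day(index_date, -int(rng.integers(10, config.pre_days - 30)))
                else:
                    date = day(win_start, rng.integers(0, window_days + 1))
            else:
                date = day(win_start, rng.integers(0, window_days + 1))
                dx = [_BENIGN_DX[rng.integers(len(_BENIGN_DX))]]
                if rng.random() < 0.3:
                    dx.append(_BENIGN_DX[rng.integers(len(_BENIGN_DX))])
            cpt = _BENIGN_CPT[rng.integers(len(_BENIGN_CPT))]
            if rng.random() < config.purchased_fraction:
                add_purchased_visit(pid, date, dx, cpt, mult)
            else:
                cpts = [] if rng.random() < 0.1 else [cpt]
                enc = add_outpatient(pid, date, dx, cpts, mult)
                if rng.random() < 0.2:
                    rows["ancillary"].append({
                        "record_id": next_id("anc", "A"),
                        "person_id": pid,
                        "proc_code": "72148" if rng.random() < 0.5 else "80053",
                        "accession_number": f"ACC-{enc['encounter_id']}",
                        "procedure_date": date,
                        "inpatient_flag": False,
                    })

        # prescriptions
        if is_candidate and rng.random() < config.opioid_rx_rate_post_surgery:
            n_fills = 1 + int(rng.poisson(1.5))
            offsets = np.sort(rng.integers(0, 181, size=n_fills))
            for off in offsets:
                rows["prescriptions"].append({
                    "rx_id": next_id("rx", "R"),
                    "person_id": pid,
                    "fill_date": day(index_date, int(off)),
                    "generic_name": _OPIOID_RX_NAMES[rng.integers(2)],
                    "therapeutic_class": opioid_classes[rng.integers(len(opioid_classes))],
                    "days_supply": int(rng.integers(5, 31)),
                    "cost": gamma_cost(15.0, 1.0),
                })
        for _ in range(int(rng.poisson(0.5 * years))):
            name, tclass = _NONOPIOID_RX[rng.integers(len(_NONOPIOID_RX))]
            rows["prescriptions"].append({
                "rx_id": next_id("rx", "R"),
                "person_id": pid,
                "fill_date": day(win_start, rng.integers(0, window_days + 1)),
                "generic_name": name,
                "therapeutic_class": tclass,
                "days_supply": int(rng.integers(7, 91)),
                "cost": gamma_cost(10.0, 1.0),
            })

    frames = {}
    for t, data in rows.items():
        frames[t] = pd.DataFrame(data) if data else empty_table(t)
        if data:
            frames[t] = frames[t].reindex(
                columns=[c for c in frames[t].columns], copy=False
            )
    frames["eligibility"] = merge_spans(frames["eligibility"])
    bundle = RepositoryBundle(**frames)
    return bundle, truth


# ---------------------------------------------------------------------------
# Missingness injection
# ---------------------------------------------------------------------------

@dataclass
class MissingnessSpec:
    """How to knock cells out of a table: mechanism, rate, and targets.

    MAR drives missingness through a logistic function of a fully observed
    driver column; NMAR drives it through the target's own (to-be-hidden)
    values.  ``slope`` controls mechanism strength on the standardized
    driver; the intercept is solved so the expected missing fraction equals
    ``rate``.
    """

    mechanism: str  # MCAR | MAR | NMAR
    rate: float
    target_columns: Sequence[str]
    driver_column: Optional[str] = None
    slope: float = 1.0

    def validate(self, table: pd.DataFrame) -> None:
        if self.mechanism not in ("MCAR", "MAR", "NMAR"):
            raise MissingnessSpecError(f"unknown mechanism {self.mechanism!r}")
        if not (0.0 <= self.rate <= 1.0):
            raise MissingnessSpecError("rate must lie in [0, 1]")
        for c in self.target_columns:
            if c not in table.columns:
                raise MissingnessSpecError(f"target column {c!r} not in table")
        if self.mechanism == "MAR":
            if self.driver_column is None:
                raise MissingnessSpecError("MAR requires a driver_column")
            if self.driver_column not in table.columns:
                raise MissingnessSpecError(f"driver {self.driver_column!r} not in table")
            if table[self.driver_column].isna().any():
                raise MissingnessSpecError("MAR driver must be fully observed")


def _calibrated_probs(values: np.ndarray, rate: float, slope: float) -> np.ndarray:
    """Logistic missingness probabilities with mean exactly ``rate``."""
    from scipy.optimize import brentq
    from scipy.special import expit

    sd = values.std()
    z = (values - values.mean()) / (sd if sd > 0 else 1.0)

    def mean_p(a):
        return expit(a + slope * z).mean() - rate

    a = brentq(mean_p, -40.0, 40.0)
    return expit(a + slope * z)


def inject_missingness(
    table: pd.DataFrame, spec: MissingnessSpec, seed: int
) -> Tuple[pd.DataFrame, float]:
    """Blank out target cells per the spec; returns (table, realized fraction)."""
    spec.validate(table)
    rng = np.random.default_rng(seed)
    out = table.copy()
    n = len(out)
    if n == 0 or spec.rate == 0.0:
        return out, 0.0

    n_missing = 0
    for col in spec.target_columns:
        if spec.mechanism == "MCAR":
            p = np.full(n, spec.rate)
        elif spec.mechanism == "MAR":
            p = _calibrated_probs(
                out[spec.driver_column].to_numpy(float), spec.rate, spec.slope
            )
        else:  # NMAR: driven by the target's own values
            p = _calibrated_probs(out[col].to_numpy(float), spec.rate, spec.slope)
        mask = rng.random(n) < p
        out.loc[mask, col] = np.nan
        n_missing += int(mask.sum())
    realized = n_missing / (n * len(spec.target_columns))
    return out, realized


def generate_regression_dataset(
    n: int,
    coefficients: Sequence[float],
    noise_sd: float,
    seed: int,
    rho: float = 0.3,
    intercept: float = 0.0,
) -> Tuple[pd.Series, pd.DataFrame]:
    """Fully observed linear-model dataset with equicorrelated normal covariates.

    ``outcome = intercept + X @ coefficients + Normal(0, noise_sd)``; the
    covariates share pairwise correlation ``rho``.  Requires
    ``n >= 10 * len(coefficients)``.
    """
    k = len(coefficients)
    if n < 10 * k:
        raise ConfigError(f"n={n} too small for {k} coefficients (need >= {10 * k})")
    rng = np.random.default_rng(seed)
    cov = np.full((k, k), rho) + (1.0 - rho) * np.eye(k)
    X = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    y = intercept + X @ np.asarray(coefficients, float) + rng.normal(0.0, noise_sd, n)
    Xdf = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(k)])
    return pd.Series(y, name="y"), Xdf
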