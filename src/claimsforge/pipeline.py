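"""End-to-end reproducible run: generate → validate → cohort → variables →
missingness diagnostics → risk adjustment, with a provenance manifest.

One global seed fans out to per-stage seeds by stable hashing of the stage
name, so stages stay decoupled: changing how one stage consumes randomness
never shifts another's stream.  Every output directory carries a manifest
with the config hash, per-stage status, and record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import claims_store, cohort_builder, missing_data, risk_adjustment
from . import synthetic_claims, variable_derivation
from .codebook import builtin_registry

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    query_date: str = "2014-06-30"
    generator: Dict = field(default_factory=dict)
    cohort: Dict = field(default_factory=dict)
    derive: Dict = field(default_factory=dict)
    missingness: List[Dict] = field(default_factory=list)
    imputation: Dict = field(default_factory=dict)
    risk: Dict = field(default_factory=dict)
    registry_overrides: Dict[str, List[str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise PipelineConfigError(str(exc)) from exc

    def canonical(self) -> str:
        # out_dir is a run location, not part of the scientific configuration
        d = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> Dict:
    """Execute all stages in order; halt on failure with a partial manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }

    def record(stage: str, status: str, **info):
        manifest["stages"].append({"stage": stage, "status": status, **info})
        logger.info("stage %s: %s %s", stage, status, info)

    try:
        registry = builtin_registry(overrides=config.registry_overrides or None)
    except KeyError as exc:
        record("load-config", "failed", error=str(exc))
        _write_manifest(out, manifest)
        raise PipelineConfigError(str(exc)) from exc
    record("load-config", "ok")

    # generate ------------------------------------------------------------
    gen_cfg = synthetic_claims.GeneratorConfig(
        **{**config.generator, "seed": stage_seed(config.seed, "generate")}
    )
    bundle, truth = synthetic_claims.generate(gen_cfg)
    repo_dir = out / "repo"
    claims_store.write_repository(bundle, repo_dir)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1, sort_keys=True)
    record("generate", "ok", n_persons=len(bundle.persons),
           true_cohort=len(truth.true_cohort))
    manifest["outputs"]["repo"] = "repo"
    manifest["outputs"]["truth"] = "truth.json"

    # validate ------------------------------------------------------------
    bundle = claims_store.read_repository(repo_dir)
    clean, report = claims_store.validate_repository(
        bundle, pd.Timestamp(config.query_date)
    )
    with open(out / "validation.json", "w") as fh:
        json.dump(
            {
                "clean_counts": report.clean_counts,
                "n_errors": {t: len(v) for t, v in report.error_records.items()},
                "immature_counts": report.immature_counts,
            },
            fh, indent=1, sort_keys=True,
        )
    record("validate", "ok", errors=report.n_errors())
    manifest["outputs"]["validation"] = "validation.json"

    # build-cohort --------------------------------------------------------
    spec = _cohort_spec(config.cohort, registry)
    timelines = claims_store.all_timelines(clean)
    members, attrition = cohort_builder.build_cohort(clean, spec, timelines=timelines)
    cohort_df = cohort_builder.cohort_to_frame(members)
    cohort_df.to_csv(out / "cohort.csv", index=False)
    attrition.to_frame().to_csv(out / "attrition.csv", index=False)
    record("build-cohort", "ok", members=len(members))
    manifest["outputs"]["cohort"] = "cohort.csv"
    manifest["outputs"]["attrition"] = "attrition.csv"

    # derive --------------------------------------------------------------
    variables = variable_derivation.derive_variables(
        clean, members, registry=registry, **config.derive
    )
    variables.to_csv(out / "variables.csv", index=False)
    record("derive", "ok", rows=len(variables))
    manifest["outputs"]["variables"] = "variables.csv"

    # missingness / sensitivity -------------------------------------------
    if config.missingness and len(variables) >= 30:
        imp_cfg = missing_data.ImputationConfig(
            **{**config.imputation, "seed": stage_seed(config.seed, "impute")}
        )
        model = missing_data.ModelSpec(
            outcome="total_cost",
            covariates=["visits_total", "opioid_days_supply"],
            log_outcome=True,
        )
        cols = [model.outcome] + model.covariates
        full = variables[cols].astype(float)
        reports = []
        for i, spec_dict in enumerate(config.missingness):
            mspec = synthetic_claims.MissingnessSpec(**spec_dict)
            miss, realized = synthetic_claims.inject_missingness(
                full, mspec, seed=stage_seed(config.seed, f"missingness-{i}")
            )
            bias = missing_data.sensitivity_analysis(
                full, miss, model, imp_cfg, run_mcar_test=True
            )
            rep = bias.to_jsonable()
            rep["mechanism"] = mspec.mechanism
            rep["rate"] = mspec.rate
            rep["realized_rate"] = realized
            reports.append(rep)
        with open(out / "bias.json", "w") as fh:
            json.dump(reports, fh, indent=1, sort_keys=True)
        record("sensitivity", "ok", n_specs=len(reports))
        manifest["outputs"]["bias"] = "bias.json"
    else:
        record("sensitivity", "skipped",
               reason="no missingness specs or cohort too small")

    # risk-adjust ---------------------------------------------------------
    flag_cols = [c for c in variables.columns if c.startswith("flag_")]
    varying = [c for c in flag_cols if variables[c].nunique() > 1]
    if len(variables) >= 10 * max(len(varying), 1) and varying:
        flags = variables[varying].astype(float)
        flags.columns = [c.removeprefix("flag_") for c in varying]
        model = risk_adjustment.fit_risk_weights(
            flags, variables["total_cost"].to_numpy(float),
            outcome_name="total_cost", **config.risk,
        )
        scores = []
        for _, row in variables.iterrows():
            prof = variable_derivation.ComorbidityProfile(
                person_id=row["person_id"],
                flags={l: bool(row[f"flag_{l}"]) for l in flags.columns},
            )
            s = risk_adjustment.score(prof, model)
            scores.append({"person_id": s.person_id, "score": round(s.score, 4),
                           "linear_predictor": round(s.linear_predictor, 6)})
        with open(out / "risk.json", "w") as fh:
            json.dump({"model": model.to_jsonable(), "scores": scores},
                      fh, indent=1, sort_keys=True)
        record("risk-adjust", "ok", n_flags=len(flags.columns))
        manifest["outputs"]["risk"] = "risk.json"
    else:
        record("risk-adjust", "skipped", reason="cohort too small to identify weights")

    _write_manifest(out, manifest)
    return manifest


def _cohort_spec(cfg: Dict, registry) -> cohort_builder.CohortSpec:
    from .codebook import exclusion_union, FAI_INCLUSION_LABEL

    inclusion_label = cfg.get("inclusion_label", FAI_INCLUSION_LABEL)
    if inclusion_label not in registry:
        raise PipelineConfigError(f"unknown code-set label: {inclusion_label!r}")
    exclusion_label = cfg.get("exclusion_label")
    if exclusion_label is not None and exclusion_label not in registry:
        raise PipelineConfigError(f"unknown code-set label: {exclusion_label!r}")
    return cohort_builder.CohortSpec(
        inclusion_set=registry[inclusion_label],
        exclusion_set=(
            registry[exclusion_label] if exclusion_label else exclusion_union(registry)
        ),
        age_range=tuple(cfg.get("age_range", (18, 50))),
        pre_days=int(cfg.get("pre_days", 365)),
        post_days=int(cfg.get("post_days", 730)),
        gap_tolerance_days=int(cfg.get("gap_tolerance_days", 0)),
    )


def _write_manifest(out: Path, manifest: Dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
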