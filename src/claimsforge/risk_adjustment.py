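"""Regression-based comorbidity risk adjustment for cost and visit outcomes.

A cross-sectional analogue of hierarchical-condition-category scoring: the
outcome (total cost or total visits over the surveillance window) is
regressed on the person's comorbidity-flag indicators — optionally with
pairwise flag interactions, capturing conditions acting "in combination" —
and the fitted coefficients become the per-comorbidity weights of a linear
risk score.  Costs are fitted on the log1p scale by default (they are
non-negative and heavily right-skewed); visit counts fit naturally on the
identity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .missing_data import LinearFit, fit_linear
from .variable_derivation import ComorbidityProfile


class UnidentifiableModelError(ValueError):
    pass


@dataclass
class RiskModel:
    outcome_name: str
    weights: Dict[str, float]
    intercept: float
    scale: str = "log"  # identity | log
    interaction_weights: Dict[Tuple[str, str], float] = field(default_factory=dict)
    weight_se: Dict[str, float] = field(default_factory=dict)
    n: int = 0

    def labels(self) -> List[str]:
        return list(self.weights)

    def to_jsonable(self) -> dict:
        return {
            "outcome_name": self.outcome_name,
            "intercept": self.intercept,
            "scale": self.scale,
            "weights": self.weights,
            "interaction_weights": {
                f"{a}*{b}": w for (a, b), w in self.interaction_weights.items()
            },
            "weight_se": self.weight_se,
            "n": self.n,
        }


@dataclass(frozen=True)
class RiskScore:
    person_id: str
    score: float
    linear_predictor: float


def _flags_frame(
    profiles: Sequence[ComorbidityProfile] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles.astype(float)
    labels = list(profiles[0].flags)
    return pd.DataFrame(
        [[float(p.flags[l]) for l in labels] for p in profiles],
        columns=labels,
    )


def fit_risk_weights(
    profiles: Sequence[ComorbidityProfile] | pd.DataFrame,
    outcomes: Sequence[float],
    outcome_name: str = "total_cost",
    scale: str = "log",
    interactions: bool = False,
) -> RiskModel:
    """Least-squares comorbidity weights from flag indicators and outcomes.

    ``scale="log"`` fits log1p(outcome) — weights are then approximate
    log-scale multiplicative cost effects; ``scale="identity"`` fits the
    raw outcome.  Flags that never vary in the sample (all false or all
    true) make the weight unidentifiable and raise.
    """
    X = _flags_frame(profiles)
    y = np.asarray(outcomes, dtype=float)
    if scale not in ("log", "identity"):
        raise ValueError(f"unknown scale {scale!r}")
    if np.any(y < 0):
        raise ValueError("outcomes must be non-negative")
    if len(X) < 10 * X.shape[1]:
        raise ValueError(
            f"need at least {10 * X.shape[1]} persons for {X.shape[1]} flags"
        )
    constant = [c for c in X.columns if X[c].nunique() < 2]
    if constant:
        raise UnidentifiableModelError(
            f"flag(s) without variation, weights unidentifiable: {constant}"
        )
    design = X.copy()
    pairs: List[Tuple[str, str]] = []
    if interactions:
        for a, b in combinations(X.columns, 2):
            col = X[a] * X[b]
            if col.nunique() > 1:
                design[f"{a}*{b}"] = col
                pairs.append((a, b))
    target = np.log1p(y) if scale == "log" else y
    fit: LinearFit = fit_linear(pd.Series(target), design)
    weights = {l: float(fit.params[l]) for l in X.columns}
    inter = {
        (a, b): float(fit.params[f"{a}*{b}"]) for a, b in pairs
    }
    return RiskModel(
        outcome_name=outcome_name,
        weights=weights,
        intercept=float(fit.params["const"]),
        scale=scale,
        interaction_weights=inter,
        weight_se={l: float(fit.bse[l]) for l in X.columns},
        n=fit.n,
    )


def score(profile: ComorbidityProfile, model: RiskModel) -> RiskScore:
    """Deterministic linear-predictor evaluation of one person's risk.

    On the log scale the score is returned on the outcome scale via
    expm1(linear predictor).
    """
    missing = [l for l in model.weights if l not in profile.flags]
    if missing:
        raise KeyError(f"profile missing flag(s) required by model: {missing}")
    lp = model.intercept + sum(
        w * float(profile.flags[l]) for l, w in model.weights.items()
    )
    for (a, b), w in model.interaction_weights.items():
        lp += w * float(profile.flags[a]) * float(profile.flags[b])
    value = float(np.expm1(lp)) if model.scale == "log" else float(lp)
    return RiskScore(person_id=profile.person_id, score=value, linear_predictor=float(lp))
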