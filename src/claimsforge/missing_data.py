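"""Missing-data workflow: pattern analysis, Little's MCAR test,
chained-equations multiple imputation, Rubin pooling, and relative-bias
sensitivity grading.

Little's MCAR test compares, for each distinct missingness pattern, the
observed-variable subvector means against the multivariate-normal maximum-
likelihood estimates obtained by EM under ignorable missingness:

    d^2 = sum_j  n_j (ybar_obs,j - mu_obs,j)' Sigma_obs,j^{-1} (ybar_obs,j - mu_obs,j)

with degrees of freedom ``sum_j p_j - p`` (p_j = observed variables in
pattern j).  Under MCAR and joint normality, d^2 is asymptotically
chi-square.

The imputation engine is chained equations (MICE): cells start at random
draws from each variable's observed marginal, then each incomplete variable
is cyclically re-imputed from a Bayesian linear regression on all other
variables, either by a stochastic normal draw or by predictive-mean
matching (the default for continuous data); m independent chains give m
completed datasets, combined across fits with Rubin's rules.

The sensitivity analysis refits the analysis regression on the fully
observed data (Bfull) and on the pooled imputed data (Bmissing) and grades
the per-coefficient relative bias ((Bfull - Bmissing)/Bfull) x 100% into
severity bands: <=5% negligible, <=10% minimal, <=20% moderate, <=30%
heavy, >30% severe (absolute value; boundaries fall to the lower band).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GRADE_BANDS: Tuple[Tuple[float, str], ...] = (
    (5.0, "negligible"),
    (10.0, "minimal"),
    (20.0, "moderate"),
    (30.0, "heavy"),
)
SEVERE = "severe"


# ---------------------------------------------------------------------------
# Missingness patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MissingnessPattern:
    observed_mask: Tuple[bool, ...]
    n_rows: int


def enumerate_patterns(data: pd.DataFrame) -> List[MissingnessPattern]:
    """Distinct observed-masks with row counts; counts conserve rows.

    All-missing rows form their own pattern (mask all-False); downstream
    analyses exclude it with a warning.
    """
    if data.shape[0] < 1 or data.shape[1] < 1:
        raise ValueError("need at least one row and one column")
    mask = data.notna().to_numpy()
    patterns: Dict[Tuple[bool, ...], int] = {}
    for row in mask:
        key = tuple(bool(v) for v in row)
        patterns[key] = patterns.get(key, 0) + 1
    if (False,) * data.shape[1] in patterns:
        warnings.warn("rows with every variable missing are excluded from tests")
    return [
        MissingnessPattern(observed_mask=k, n_rows=v)
        for k, v in sorted(patterns.items(), reverse=True)
    ]


# ---------------------------------------------------------------------------
# EM for the multivariate-normal mean and covariance under ignorable
# missingness (the ML estimates Little's test is built on)
# ---------------------------------------------------------------------------

def em_mean_cov(
    data: pd.DataFrame | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
    ridge: float = 1e-8,
) -> Tuple[np.ndarray, np.ndarray, bool]:
    """EM estimates (mean, ML covariance, converged) for data with NaNs.

    The observed-data log-likelihood is non-decreasing across iterations;
    convergence is declared when its increase falls below ``tol``.  Complete
    data converges in a single step to the sample mean and ML (divisor n)
    covariance.  A singular within-iteration covariance is ridge-regularized
    with a logged epsilon.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    keep = obs.any(axis=1)
    if not keep.all():
        X, obs = X[keep], obs[keep]
        n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two rows with any observed value")

    # group rows by pattern once
    groups: Dict[Tuple[bool, ...], np.ndarray] = {}
    for key in {tuple(r) for r in obs}:
        groups[key] = np.where((obs == np.array(key)).all(axis=1))[0]

    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    var = np.nanvar(X, axis=0)
    var = np.where(np.isnan(var) | (var <= 0), 1.0, var)
    sigma = np.diag(var)

    last_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        ll = 0.0
        for key, idx in groups.items():
            o = np.array(key)
            m = ~o
            Xo = X[np.ix_(idx, np.where(o)[0])]
            So = sigma[np.ix_(o, o)]
            try:
                So_inv = np.linalg.inv(So)
            except np.linalg.LinAlgError:
                logger.warning("singular covariance; adding ridge %g", ridge)
                So = So + ridge * np.eye(o.sum())
                So_inv = np.linalg.inv(So)
            dev = Xo - mu[o]
            sign, logdet = np.linalg.slogdet(So)
            if sign <= 0:
                So = So + ridge * np.eye(o.sum())
                sign, logdet = np.linalg.slogdet(So)
                So_inv = np.linalg.inv(So)
            ll += -0.5 * (
                len(idx) * (o.sum() * np.log(2 * np.pi) + logdet)
                + np.einsum("ij,jk,ik->", dev, So_inv, dev)
            )
            Xhat = np.empty((len(idx), p))
            Xhat[:, o] = Xo
            if m.any():
                B = sigma[np.ix_(m, o)] @ So_inv
                Xhat[:, m] = mu[m] + dev @ B.T
                C = sigma[np.ix_(m, m)] - B @ sigma[np.ix_(o, m)]
            s1 += Xhat.sum(axis=0)
            s2 += Xhat.T @ Xhat
            if m.any():
                mi = np.where(m)[0]
                s2[np.ix_(mi, mi)] += len(idx) * C
        mu_new = s1 / n
        sigma_new = s2 / n - np.outer(mu_new, mu_new)
        mu, sigma = mu_new, sigma_new
        if ll - last_ll < tol and np.isfinite(last_ll):
            converged = True
            break
        last_ll = ll
    return mu, sigma, converged


def em_loglik_path(
    data: pd.DataFrame | np.ndarray, n_iter: int = 25
) -> List[float]:
    """Observed-data log-likelihood after each of ``n_iter`` EM iterations."""
    X = np.asarray(data, dtype=float)
    lls: List[float] = []
    for k in range(1, n_iter + 1):
        mu, sigma, _ = em_mean_cov(X, tol=-1.0, max_iter=k)
        lls.append(_obs_loglik(X, mu, sigma))
    return lls


def _obs_loglik(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    obs = ~np.isnan(X)
    ll = 0.0
    for key in {tuple(r) for r in obs}:
        o = np.array(key)
        if not o.any():
            continue
        idx = np.where((obs == o).all(axis=1))[0]
        Xo = X[np.ix_(idx, np.where(o)[0])]
        ll += stats.multivariate_normal.logpdf(
            Xo, mean=mu[o], cov=sigma[np.ix_(o, o)], allow_singular=True
        ).sum()
    return float(ll)


# ---------------------------------------------------------------------------
# Little's MCAR test
# ---------------------------------------------------------------------------

@dataclass
class McarTestResult:
    statistic_d2: float
    df: int
    p_value: float
    n_patterns: int
    converged: bool


def little_mcar_test(data: pd.DataFrame) -> McarTestResult:
    """Chi-square test of MCAR against pattern-dependent means.

    Complete data yields d^2 = 0 with 0 degrees of freedom (reported
    p-value 1).  Rows missing every variable are excluded with a warning.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    keep = obs.any(axis=1)
    if not keep.all():
        warnings.warn("excluding rows with every variable missing")
        X, obs = X[keep], obs[keep]

    mu, sigma, converged = em_mean_cov(X)

    d2 = 0.0
    df = 0
    n_patterns = 0
    for key in {tuple(r) for r in obs}:
        o = np.array(key)
        idx = np.where((obs == o).all(axis=1))[0]
        n_patterns += 1
        ybar = X[np.ix_(idx, np.where(o)[0])].mean(axis=0)
        dev = ybar - mu[o]
        So = sigma[np.ix_(o, o)]
        d2 += len(idx) * float(dev @ np.linalg.solve(So, dev))
        df += int(o.sum())
    df -= p
    if df <= 0:
        return McarTestResult(0.0, 0, 1.0, n_patterns, converged)
    p_value = float(stats.chi2.sf(d2, df))
    return McarTestResult(float(d2), df, p_value, n_patterns, converged)


# ---------------------------------------------------------------------------
# Chained-equations multiple imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationConfig:
    m: int = 10
    max_iterations: int = 10
    seed: int = 0
    method: str = "pmm"  # pmm | norm; binary columns use logistic draws
    pmm_donors: int = 5

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.method not in ("pmm", "norm"):
            raise ValueError(f"unknown imputation method {self.method!r}")


def _bayes_linear_draw(
    Xo: np.ndarray, yo: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, float]:
    """Posterior draw (beta*, sigma*) for a normal linear model."""
    n, k = Xo.shape
    XtX = Xo.T @ Xo + 1e-8 * np.eye(k)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(n - k, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    L = np.linalg.cholesky(sigma2 * XtX_inv + 1e-12 * np.eye(k))
    beta_star = beta_hat + L @ rng.standard_normal(k)
    return beta_star, float(np.sqrt(sigma2))


def _pmm_draw(
    pred_obs: np.ndarray, y_obs: np.ndarray, pred_mis: np.ndarray,
    donors: int, rng: np.random.Generator,
) -> np.ndarray:
    """Predictive-mean matching: draw each imputation from the k observed
    values whose predictions sit nearest the missing case's prediction."""
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    sorted_y = y_obs[order]
    out = np.empty(len(pred_mis))
    k = min(donors, len(y_obs))
    for i, pm in enumerate(pred_mis):
        pos = np.searchsorted(sorted_pred, pm)
        lo = max(0, pos - k)
        hi = min(len(sorted_pred), pos + k)
        cand = np.arange(lo, hi)
        nearest = cand[np.argsort(np.abs(sorted_pred[cand] - pm), kind="stable")[:k]]
        out[i] = sorted_y[nearest[rng.integers(len(nearest))]]
    return out


def mice_impute(
    data: pd.DataFrame, config: Optional[ImputationConfig] = None
) -> List[pd.DataFrame]:
    """m completed copies of ``data`` via chained-equations imputation.

    Missing cells are initialized by random draws from each column's
    observed marginal, then cyclically re-imputed for ``max_iterations``
    sweeps; chains are independent (seed offsets).  Columns whose observed
    values are all 0/1 are imputed by logistic draws, other columns by the
    configured continuous method.  A column with no observed values is an
    error.
    """
    cfg = config if config is not None else ImputationConfig()
    num = data.astype(float)
    cols = list(num.columns)
    miss_cols = [c for c in cols if num[c].isna().any()]
    for c in miss_cols:
        if num[c].notna().sum() == 0:
            raise ValueError(f"column {c!r} has no observed values")
    if not miss_cols:
        return [data.copy() for _ in range(cfg.m)]

    obs_masks = {c: num[c].notna().to_numpy() for c in cols}
    X_full = num.to_numpy()
    ss = np.random.SeedSequence(cfg.seed)
    chain_seeds = ss.spawn(cfg.m)

    completed: List[pd.DataFrame] = []
    for chain in range(cfg.m):
        rng = np.random.default_rng(chain_seeds[chain])
        work = X_full.copy()
        for j, c in enumerate(cols):
            mis = ~obs_masks[c]
            if mis.any():
                pool = work[obs_masks[c], j]
                work[mis, j] = rng.choice(pool, size=mis.sum(), replace=True)
        for _ in range(cfg.max_iterations):
            for j, c in enumerate(cols):
                mis = ~obs_masks[c]
                if not mis.any():
                    continue
                others = [k for k in range(work.shape[1]) if k != j]
                D = np.column_stack([np.ones(len(work)), work[:, others]])
                Do, Dm = D[obs_masks[c]], D[mis]
                yo = work[obs_masks[c], j]
                observed_vals = np.unique(yo)
                is_binary = np.isin(observed_vals, (0.0, 1.0)).all()
                if is_binary:
                    work[mis, j] = _logistic_draw(Do, yo, Dm, rng)
                    continue
                beta_star, sigma_star = _bayes_linear_draw(Do, yo, rng)
                pred_mis = Dm @ beta_star
                if cfg.method == "norm":
                    work[mis, j] = pred_mis + rng.normal(0.0, sigma_star, mis.sum())
                else:
                    pred_obs = Do @ beta_star
                    work[mis, j] = _pmm_draw(
                        pred_obs, yo, pred_mis, cfg.pmm_donors, rng
                    )
        completed.append(pd.DataFrame(work, columns=cols, index=num.index))
    return completed


def _logistic_draw(
    Do: np.ndarray, yo: np.ndarray, Dm: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli draws at fitted logistic probabilities (ridge-stabilized)."""
    import statsmodels.api as sm

    try:
        fit = sm.GLM(yo, Do, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-4, L1_wt=0.0
        )
        p = np.clip(fit.predict(Dm), 1e-6, 1 - 1e-6)
    except Exception:  # perfectly separated or degenerate: marginal draw
        p = np.full(len(Dm), yo.mean())
    return (rng.random(len(Dm)) < p).astype(float)


# ---------------------------------------------------------------------------
# Regression fitting and Rubin pooling
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    params: pd.Series
    bse: pd.Series
    n: int
    df_resid: float


class RankDeficiencyError(ValueError):
    pass


def fit_linear(outcome: pd.Series, covariates: pd.DataFrame) -> LinearFit:
    """Ordinary least squares with intercept; errors on rank deficiency
    naming the collinear columns."""
    import statsmodels.api as sm

    X = sm.add_constant(covariates.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise RankDeficiencyError(f"design is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(np.asarray(outcome, float), X).fit()
    return LinearFit(
        params=pd.Series(fit.params, index=X.columns),
        bse=pd.Series(fit.bse, index=X.columns),
        n=int(fit.nobs),
        df_resid=float(fit.df_resid),
    )


def _collinear_columns(X: pd.DataFrame) -> List[str]:
    cols = list(X.columns)
    bad = []
    A = X.to_numpy()
    full_rank = np.linalg.matrix_rank(A)
    for i, c in enumerate(cols):
        sub = np.delete(A, i, axis=1)
        if np.linalg.matrix_rank(sub) == full_rank:
            bad.append(c)
    return bad or cols


@dataclass
class PooledFit:
    params: pd.Series
    total_variance: pd.Series
    within_variance: pd.Series
    between_variance: pd.Series
    m: int

    @property
    def bse(self) -> pd.Series:
        return np.sqrt(self.total_variance)


def pool_rubin(fits: Sequence[LinearFit]) -> PooledFit:
    """Rubin's rules: pooled estimate is the mean across imputations; total
    variance is within-mean plus (1 + 1/m) times between-variance."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to pool")
    layouts = {tuple(f.params.index) for f in fits}
    if len(layouts) != 1:
        raise ValueError("fits have mismatched coefficient layouts")
    m = len(fits)
    est = pd.concat([f.params for f in fits], axis=1)
    pooled = est.mean(axis=1)
    within = pd.concat([f.bse**2 for f in fits], axis=1).mean(axis=1)
    between = est.var(axis=1, ddof=1)
    total = within + (1.0 + 1.0 / m) * between
    return PooledFit(
        params=pooled, total_variance=total,
        within_variance=within, between_variance=between, m=m,
    )


# ---------------------------------------------------------------------------
# Relative bias and severity grading
# ---------------------------------------------------------------------------

def relative_bias(
    b_full: pd.Series | np.ndarray,
    b_missing: pd.Series | np.ndarray,
    zero_floor: float = 1e-8,
) -> pd.Series:
    """Per-coefficient ((Bfull - Bmissing)/Bfull) x 100%.

    Coefficients with |Bfull| below ``zero_floor`` are undefined (NaN) and
    excluded from downstream maxima with a warning.
    """
    bf = pd.Series(b_full).astype(float)
    bm = pd.Series(b_missing).astype(float)
    if len(bf) != len(bm):
        raise ValueError("coefficient vectors differ in length")
    bm.index = bf.index
    out = (bf - bm) / bf * 100.0
    tiny = bf.abs() < zero_floor
    if tiny.any():
        warnings.warn(
            f"relative bias undefined for near-zero reference coefficients: "
            f"{list(bf.index[tiny])}"
        )
        out[tiny] = np.nan
    return out


def grade_bias(pct: float) -> str:
    """Severity band of one absolute relative-bias percentage."""
    if not np.isfinite(pct):
        raise ValueError("bias percentage must be finite")
    a = abs(pct)
    for upper, grade in GRADE_BANDS:
        if a <= upper:
            return grade
    return SEVERE


@dataclass
class BiasReport:
    """Full-vs-imputed coefficient comparison with severity grades."""

    b_full: pd.Series
    b_missing: pd.Series
    pct_bias: pd.Series
    grades: Dict[str, str]
    max_abs_pct_bias: float
    mcar: Optional[McarTestResult] = None

    def to_jsonable(self) -> dict:
        return {
            "b_full": {str(k): float(v) for k, v in self.b_full.items()},
            "b_missing": {str(k): float(v) for k, v in self.b_missing.items()},
            "pct_bias": {
                str(k): (None if pd.isna(v) else float(v))
                for k, v in self.pct_bias.items()
            },
            "grades": self.grades,
            "max_abs_pct_bias": float(self.max_abs_pct_bias),
            "mcar": None if self.mcar is None else {
                "statistic_d2": self.mcar.statistic_d2,
                "df": self.mcar.df,
                "p_value": self.mcar.p_value,
                "n_patterns": self.mcar.n_patterns,
            },
        }


@dataclass
class ModelSpec:
    outcome: str
    covariates: List[str]
    log_outcome: bool = False


def sensitivity_analysis(
    full_data: pd.DataFrame,
    missing_data: pd.DataFrame,
    model: ModelSpec,
    config: Optional[ImputationConfig] = None,
    run_mcar_test: bool = False,
) -> BiasReport:
    """Grade how far imputation-based coefficients drift from the full-data fit.

    Bfull comes from the least-squares fit on the fully observed dataset;
    Bmissing from Rubin-pooled fits over the chained-equation imputations of
    the dataset with missing cells (outcome and covariates jointly enter the
    imputation model).  Bias is reported for the covariate coefficients (the
    intercept, typically near zero, is not graded).
    """
    cfg = config if config is not None else ImputationConfig()
    cols = [model.outcome] + list(model.covariates)
    full = full_data[cols].astype(float)
    if full.isna().any().any():
        raise ValueError("full dataset must have no missing cells")
    miss = missing_data[cols].astype(float)

    def transform(df: pd.DataFrame) -> Tuple[pd.Series, pd.DataFrame]:
        y = df[model.outcome]
        if model.log_outcome:
            y = np.log1p(y)
        return y, df[model.covariates]

    b_full_fit = fit_linear(*transform(full))
    imputations = mice_impute(miss, cfg)
    fits = [fit_linear(*transform(imp)) for imp in imputations]
    pooled = pool_rubin(fits)

    keys = list(model.covariates)
    pct = relative_bias(b_full_fit.params[keys], pooled.params[keys])
    grades = {k: (grade_bias(v) if np.isfinite(v) else "undefined") for k, v in pct.items()}
    finite = pct.dropna()
    max_abs = float(finite.abs().max()) if len(finite) else 0.0
    mcar = little_mcar_test(miss) if run_mcar_test else None
    return BiasReport(
        b_full=b_full_fit.params[keys],
        b_missing=pooled.params[keys],
        pct_bias=pct,
        grades=grades,
        max_abs_pct_bias=max_abs,
        mcar=mcar,
    )
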