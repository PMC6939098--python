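"""Cohort statistics: correlations, group tests, and three GLM families.

Associations between PVS morphometry and outcomes are modelled with a family
chosen by the outcome's measurement: linear models for ordinal-as-continuous
and continuous outcomes, binary logistic regression for risk factors, and
beta regression with a logit link for WMH volume as a proportion of ICV.
The PVS predictor is z-scored in every model so effect sizes are comparable;
continuous outcomes of linear models are z-scored as well.  Models are
compared by AIC/BIC against the visual-rating reference model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.api import OLS, Logit, add_constant
from statsmodels.othermod.betareg import BetaModel
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

__all__ = [
    "ModelResult",
    "zscore",
    "squeeze_transform",
    "fit_beta_regression",
    "fit_logistic",
    "fit_linear",
    "polyserial_corr",
    "pearson_corr",
    "welch_t",
    "chi_sq",
    "compare_models",
    "run_association_battery",
    "percentage",
]

_Z975 = stats.norm.ppf(0.975)

#: outcome name -> model family used by the association battery
OUTCOME_FAMILIES = {
    "fazekas_total": "linear",
    "age": "linear",
    "wmh_pct_icv": "beta",
    "hypertension": "logistic",
    "cholesterol": "logistic",
    "diabetes": "logistic",
    "cvd": "logistic",
    "stroke": "logistic",
}

DEFAULT_COVARIATES = ("age", "sex", "hypertension")


def percentage(count: int, total: int, decimals: int = 2) -> float:
    """Percentage ``100*count/total`` rounded to ``decimals`` places."""
    if total <= 0:
        raise ValueError("total must be positive")
    return float(round(100.0 * count / total, decimals))


def zscore(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance vector")
    return (x - x.mean()) / sd


def squeeze_transform(y, n: int) -> np.ndarray:
    """Map proportions in [0, 1) strictly into (0, 1): ``(y*(n-1) + 0.5) / n``.

    Affine and order-preserving, applied to the whole vector; ``n`` is the
    sample size.  With y = 0.5 the transform is the identity.
    """
    y = np.asarray(y, dtype=np.float64)
    if n < 2:
        raise ValueError("n must be >= 2")
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("proportions must lie in [0, 1]")
    return (y * (n - 1) + 0.5) / n


@dataclass
class ModelResult:
    """A fitted GLM with the standardized effect of the term of interest."""

    family: str  # linear | logistic | beta
    params: dict
    bse: dict
    effect_name: str
    effect: float  # standardized beta, or OR for logistic
    ci_low: float
    ci_high: float
    loglik: float
    n_params: int
    n: int
    label: str = ""
    phi: float | None = None  # beta-regression precision
    converged: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n) - 2.0 * self.loglik

    @property
    def significant(self) -> bool:
        """CI excludes the null value (0 for linear/beta coefficients, 1 for OR)."""
        null = 1.0 if self.family == "logistic" else 0.0
        return not (self.ci_low <= null <= self.ci_high)


def _design(X) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    if "const" not in X.columns:
        X = add_constant(X, has_constant="add")
    return X


def fit_linear(y, X, effect_name: str, label: str = "") -> ModelResult:
    """Least-squares fit; Wald 95% CI for the coefficient of ``effect_name``."""
    X = _design(X)
    y = np.asarray(y, dtype=np.float64)
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = OLS(y, X).fit()
    beta = float(res.params[effect_name])
    se = float(res.bse[effect_name])
    return ModelResult(
        family="linear",
        params=res.params.to_dict(),
        bse=res.bse.to_dict(),
        effect_name=effect_name,
        effect=beta,
        ci_low=beta - _Z975 * se,
        ci_high=beta + _Z975 * se,
        loglik=float(res.llf),
        n_params=X.shape[1] + 1,  # coefficients + error variance
        n=len(y),
        label=label,
    )


def fit_logistic(y, X, effect_name: str, label: str = "") -> ModelResult:
    """ML logistic fit; effect reported as OR with Wald 95% CI."""
    y = np.asarray(y, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is degenerate (single observed class)")
    X = _design(X)
    try:
        res = Logit(y, X).fit(disp=0)
    except PerfectSeparationError as err:
        raise ValueError(f"perfect separation in logistic model: {err}") from err
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge")
    beta = float(res.params[effect_name])
    se = float(res.bse[effect_name])
    return ModelResult(
        family="logistic",
        params=res.params.to_dict(),
        bse=res.bse.to_dict(),
        effect_name=effect_name,
        effect=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z975 * se)),
        ci_high=float(np.exp(beta + _Z975 * se)),
        loglik=float(res.llf),
        n_params=X.shape[1],
        n=len(y),
        label=label,
    )


def fit_beta_regression(y, X, effect_name: str, label: str = "") -> ModelResult:
    """Beta regression with logit mean link and constant precision phi.

    ``y`` must lie strictly in (0, 1); apply :func:`squeeze_transform` first
    if it touches the boundary.  Mean coefficients and log-phi are estimated
    jointly by ML; SEs come from the observed information.
    """
    y = np.asarray(y, dtype=np.float64)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError(
            "beta regression needs y strictly in (0, 1); apply squeeze_transform first"
        )
    X = _design(X)
    model = BetaModel(y, X)  # logit mean link, log precision link
    with warnings.catch_warnings():
        # convergence is checked explicitly below
        warnings.simplefilter("ignore", ConvergenceWarning)
        res = model.fit(disp=0)
        if not getattr(res, "mle_retvals", {}).get("converged", True):
            res = model.fit(method="bfgs", disp=0, maxiter=500)
            retvals = getattr(res, "mle_retvals", {})
            # BFGS reports precision loss even at a stationary point; accept
            # a solution whose gradient has effectively vanished
            grad = np.asarray(retvals.get("gopt", [np.inf]))
            if not retvals.get("converged", True) and np.abs(grad).max() > 1e-3:
                raise RuntimeError(f"beta regression did not converge: {retvals}")
    beta = float(res.params[effect_name])
    se = float(res.bse[effect_name])
    phi = float(np.exp(res.params.iloc[-1]))  # precision is log-linked
    return ModelResult(
        family="beta",
        params=res.params.to_dict(),
        bse=res.bse.to_dict(),
        effect_name=effect_name,
        effect=beta,
        ci_low=beta - _Z975 * se,
        ci_high=beta + _Z975 * se,
        loglik=float(res.llf),
        n_params=X.shape[1] + 1,  # mean coefficients + phi
        n=len(y),
        label=label,
        phi=phi,
    )


# ---------------------------------------------------------------------------
# correlations and group tests
# ---------------------------------------------------------------------------

def pearson_corr(x, y) -> dict:
    """Pearson r with Fisher-z 95% CI."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval()
    return {"r": float(res.statistic), "ci_low": float(ci.low),
            "ci_high": float(ci.high), "p": float(res.pvalue), "n": len(x)}


def polyserial_corr(ordinal, continuous, ci: str = "wald", n_boot: int = 500,
                    seed: int = 0) -> dict:
    """Two-step polyserial correlation between an ordinal and a continuous variable.

    Thresholds are set from the inverse-normal cumulative category
    proportions, then the latent bivariate-normal correlation rho is
    estimated by ML.  The 95% CI is Wald (observed information by finite
    differences) or bootstrap.
    """
    ordinal = np.asarray(ordinal)
    x = np.asarray(continuous, dtype=np.float64)
    levels, codes = np.unique(ordinal, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("ordinal variable must have at least 2 observed levels")
    if x.std() == 0:
        raise ValueError("zero-variance continuous input")

    props = np.bincount(codes) / len(codes)
    taus = np.concatenate([[-np.inf], stats.norm.ppf(np.cumsum(props)[:-1]), [np.inf]])
    z = (x - x.mean()) / x.std(ddof=0)
    hi, lo = taus[codes + 1], taus[codes]

    def negll(rho: float) -> float:
        s = np.sqrt(1.0 - rho * rho)
        p = stats.norm.cdf((hi - rho * z) / s) - stats.norm.cdf((lo - rho * z) / s)
        return -np.sum(np.log(np.clip(p, 1e-300, None)))

    opt = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded")
    rho = float(opt.x)

    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(x), size=len(x))
            try:
                reps.append(polyserial_corr(ordinal[idx], x[idx], ci="none")["r"])
            except ValueError:
                continue
        lo_ci, hi_ci = np.percentile(reps, [2.5, 97.5])
    elif ci == "wald":
        h = 1e-4
        d2 = (negll(rho + h) - 2.0 * negll(rho) + negll(rho - h)) / h ** 2
        se = 1.0 / np.sqrt(d2) if d2 > 0 else np.nan
        lo_ci, hi_ci = max(rho - _Z975 * se, -1.0), min(rho + _Z975 * se, 1.0)
    else:
        lo_ci = hi_ci = np.nan
    return {"r": rho, "ci_low": float(lo_ci), "ci_high": float(hi_ci), "n": len(x)}


def welch_t(a, b) -> dict:
    """Welch two-sample t-test with Welch-Satterthwaite df and mean-difference CI."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.std() == 0 and b.std() == 0:
        raise ValueError("zero-variance input")
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval()
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue),
            "ci_low": float(ci.low), "ci_high": float(ci.high)}


def chi_sq(table, correction: bool = False) -> dict:
    """Chi-squared test of independence (no continuity correction by default).

    For a 2x2 table a Wald 95% CI for the difference in row-wise proportions
    of the first column is included.
    """
    table = np.asarray(table, dtype=np.float64)
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    out = {"chi2": float(chi2), "p": float(p), "dof": int(dof)}
    if table.shape == (2, 2):
        n1, n2 = table[0].sum(), table[1].sum()
        p1, p2 = table[0, 0] / n1, table[1, 0] / n2
        se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
        out["prop_diff"] = float(p1 - p2)
        out["prop_diff_ci"] = (float(p1 - p2 - _Z975 * se), float(p1 - p2 + _Z975 * se))
    return out


# ---------------------------------------------------------------------------
# model comparison and the association battery
# ---------------------------------------------------------------------------

def compare_models(results: list[ModelResult], reference: ModelResult) -> dict:
    """AIC/BIC comparison of candidate models against a reference.

    A candidate is flagged as a practical improvement iff its BIC is lower by
    at least 10 and its AIC is smaller.  Non-overlapping effect CIs with the
    reference are flagged as a significant difference in effects.
    """
    report = {"reference": reference.label or reference.effect_name, "models": []}
    for res in results:
        if res.n != reference.n:
            raise ValueError(
                f"models must share n: {res.label or res.effect_name} has "
                f"n={res.n}, reference has n={reference.n}"
            )
        d_aic = res.aic - reference.aic
        d_bic = res.bic - reference.bic
        no_overlap = res.ci_low > reference.ci_high or res.ci_high < reference.ci_low
        report["models"].append({
            "label": res.label or res.effect_name,
            "delta_aic": float(d_aic),
            "delta_bic": float(d_bic),
            "practical_improvement": bool(d_bic <= -10.0 and d_aic < 0.0),
            "significant_effect_difference": bool(no_overlap),
            "effect": res.effect,
            "ci": (res.ci_low, res.ci_high),
        })
    return report


def _fit_family(family: str, y, X, effect_name: str, label: str, n: int) -> ModelResult:
    if family == "linear":
        return fit_linear(zscore(y), X, effect_name, label=label)
    if family == "logistic":
        return fit_logistic(y, X, effect_name, label=label)
    if family == "beta":
        return fit_beta_regression(squeeze_transform(y, n), X, effect_name, label=label)
    raise ValueError(f"unknown family {family!r}")


def run_association_battery(
    cohort: pd.DataFrame,
    pvs_measures: tuple[str, ...] = ("pvs_count", "pvs_volume", "pvs_mean_length",
                                    "pvs_mean_width", "pvs_mean_size"),
    outcomes: dict | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    include_visual_reference: bool = True,
) -> pd.DataFrame:
    """Fit every outcome x PVS-measure model and return a tidy results table.

    Covariates are age, sex and hypertension, each dropped from models where
    it is the outcome of interest.  Every PVS predictor (and the visual
    rating when used as reference) is z-scored.  Rows are complete cases.
    """
    outcomes = dict(outcomes or OUTCOME_FAMILIES)
    predictors = list(pvs_measures) + (["pvs_visual"] if include_visual_reference else [])
    cohort = cohort.dropna(subset=list({*predictors, *outcomes, *covariates})).copy()
    n = len(cohort)

    rows = []
    for outcome, family in outcomes.items():
        covs = [c for c in covariates if c != outcome]
        for measure in predictors:
            X = cohort[covs].copy()
            X[measure] = zscore(cohort[measure])
            res = _fit_family(family, cohort[outcome].to_numpy(), X, measure,
                              label=f"{outcome}~{measure}", n=n)
            rows.append({
                "outcome": outcome,
                "family": family,
                "pvs_measure": measure,
                "effect": res.effect,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "significant": res.significant,
                "loglik": res.loglik,
                "aic": res.aic,
                "bic": res.bic,
                "phi": res.phi,
                "n": res.n,
            })
    return pd.DataFrame(rows)
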