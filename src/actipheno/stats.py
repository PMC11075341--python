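"""Association analysis: descriptives, contingency odds ratios, logistic ladder.

Reproduces the statistical surface of the behavior-depression analysis:
per-behavior descriptive statistics with one-way ANOVA (continuous) and
Pearson chi-square (categorical) omnibus tests, crude 2x2 odds ratios against
the morning-dominant reference, a sequential multivariable logistic ladder
(crude, then + age, BMI, gender, work situation, total activity cumulatively)
and one-covariate-at-a-time sensitivity models.  Inference is Wald throughout:
OR = exp(beta), 95% CI = exp(beta +/- 1.96 SE), two-sided normal p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    MalformedInputError,
    RankDeficiencyError,
    SeparationError,
    ZeroCellError,
)

Z_CRIT = 1.959964  # two-sided 95% normal quantile

REFERENCE_BEHAVIOR = "M dominant"
GENDER_REFERENCE = "Female"
WORK_REFERENCE = "Working"
WORK_LEVELS = ["Working", "WithJobNotAtWork", "LookingForWork", "NotWorking"]

COVARIATE_ORDER = ["age", "bmi", "gender", "work", "total_activity"]
ALPHA = 0.05


def total_activity(hourly_week: np.ndarray) -> float:
    """Mean daily total count over a complete 7-day week."""
    w = np.asarray(hourly_week, dtype=float)
    if w.ndim != 2 or w.shape[0] != 7:
        raise MalformedInputError("expected a 7 x 24 hourly week")
    return float(w.sum() / 7.0)


def total_activity_per_participant(hourly: pd.DataFrame) -> pd.Series:
    """total_activity for every participant in a long hourly table."""
    hour_cols = [c for c in hourly.columns if c.startswith("h") and c[1:].isdigit()]
    sums = hourly.groupby("participant_id", sort=True)[hour_cols].sum().sum(axis=1)
    n_days = hourly.groupby("participant_id", sort=True).size()
    if (n_days != 7).any():
        raise MalformedInputError("total_activity requires complete 7-day weeks")
    return (sums / 7.0).rename("total_activity")


def build_contingency(behaviors: pd.Series, depressed: pd.Series) -> pd.DataFrame:
    """Behavior x depression counts (columns: yes, no), missing rows excluded."""
    df = pd.DataFrame({"behavior": behaviors, "depressed": depressed}).dropna()
    table = pd.crosstab(df["behavior"], df["depressed"].astype(bool))
    for col in (True, False):
        if col not in table.columns:
            table[col] = 0
    out = pd.DataFrame({"yes": table[True], "no": table[False]})
    out.index.name = "behavior"
    return out


def contingency_from_margins(
    group_sizes: dict[str, int], prevalence_pct: dict[str, float]
) -> pd.DataFrame:
    """Reconstruct a behavior x depression table from group sizes and printed
    prevalence percentages (counts = round(prevalence/100 * n))."""
    rows = {}
    for b, n in group_sizes.items():
        yes = int(round(prevalence_pct[b] / 100.0 * n))
        rows[b] = {"yes": yes, "no": n - yes}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "behavior"
    return out


def crude_odds_ratio(
    table: pd.DataFrame, behavior: str, reference: str = REFERENCE_BEHAVIOR
) -> tuple[float, float, float]:
    """2x2 odds ratio (behavior vs reference) with the Wald 95% CI."""
    a, b = float(table.loc[behavior, "yes"]), float(table.loc[behavior, "no"])
    c, d = float(table.loc[reference, "yes"]), float(table.loc[reference, "no"])
    if min(a, b, c, d) == 0:
        raise ZeroCellError("zero cell in 2x2 table; odds ratio undefined")
    log_or = np.log((a / b) / (c / d))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        float(np.exp(log_or)),
        float(np.exp(log_or - Z_CRIT * se)),
        float(np.exp(log_or + Z_CRIT * se)),
    )


@dataclass
class LogisticFit:
    """One fitted logistic model on the Wald scale."""

    model_id: str
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    n: int
    converged: bool
    or_: pd.Series = field(init=False)
    ci_low: pd.Series = field(init=False)
    ci_high: pd.Series = field(init=False)
    p: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.or_ = np.exp(self.params)
        self.ci_low = np.exp(self.params - Z_CRIT * self.bse)
        self.ci_high = np.exp(self.params + Z_CRIT * self.bse)
        z = self.params / self.bse
        self.p = pd.Series(2.0 * sps.norm.sf(np.abs(z)), index=self.params.index)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.params.index,
                "coef": self.params.values,
                "se": self.bse.values,
                "or": self.or_.values,
                "ci_low": self.ci_low.values,
                "ci_high": self.ci_high.values,
                "p": self.p.values,
            }
        )


def build_design(
    cohort: pd.DataFrame,
    terms: list[str],
    reference_behavior: str = REFERENCE_BEHAVIOR,
) -> pd.DataFrame:
    """Dummy-coded design matrix (no intercept column; fit adds it).

    behavior and work are dummy-coded against their reference levels
    (M dominant; "Working"); gender is an indicator for Male (reference
    Female); age, BMI and total activity enter continuous and unscaled.
    """
    cols: dict[str, np.ndarray] = {}
    for term in terms:
        if term == "behavior":
            levels = [b for b in cohort["behavior"].unique() if b != reference_behavior]
            for lev in sorted(levels):
                cols[f"behavior[{lev}]"] = (cohort["behavior"] == lev).astype(float).to_numpy()
        elif term == "gender":
            cols["gender[Male]"] = (cohort["gender"] == "Male").astype(float).to_numpy()
        elif term == "work":
            for lev in WORK_LEVELS:
                if lev == WORK_REFERENCE:
                    continue
                cols[f"work[{lev}]"] = (cohort["work"] == lev).astype(float).to_numpy()
        elif term in ("age", "bmi", "total_activity"):
            cols[term] = cohort[term].to_numpy(dtype=float)
        else:
            raise MalformedInputError(f"unknown model term {term!r}")
    return pd.DataFrame(cols, index=cohort.index)


def fit_logistic(outcome: pd.Series | np.ndarray, design: pd.DataFrame, model_id: str = "fit") -> LogisticFit:
    """Maximum-likelihood logistic fit (Newton/IRLS) with Wald standard errors."""
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, [0, 1]).all():
        raise MalformedInputError("outcome must be binary 0/1")
    if len(y) <= design.shape[1] + 1:
        raise MalformedInputError("need more observations than model terms")
    if y.min() == y.max():
        raise SeparationError("outcome is constant; no MLE exists")
    X = sm.add_constant(design, prepend=True, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise RankDeficiencyError("design matrix is rank deficient")
    # standardize columns for IRLS conditioning; the affine reparametrization
    # is undone exactly on the way out (coefficients and SEs divide by scale)
    loc = design.mean(axis=0)
    scale = design.std(axis=0).replace(0.0, 1.0)
    Xs = sm.add_constant((design - loc) / scale, prepend=True, has_constant="add")
    try:
        model = sm.GLM(y, Xs, family=sm.families.Binomial())
        res = model.fit(maxiter=100, tol=1e-10)  # IRLS
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not getattr(res, "converged", True):
        raise SeparationError("logistic fit did not converge (possible separation)")
    if not np.all(np.isfinite(res.bse)) or np.any(res.bse.drop("const") / scale > 1e4):
        raise SeparationError("unstable standard errors (possible separation)")
    params = res.params.drop("const") / scale
    bse = res.bse.drop("const") / scale
    return LogisticFit(model_id, list(design.columns), params, bse, int(len(y)), True)


@dataclass
class FailedFit:
    """Placeholder for a model whose MLE was inestimable (e.g. separation)."""

    model_id: str
    terms: list[str]
    error: str
    converged: bool = False


def _fit_or_fail(outcome, design, model_id, on_error):
    try:
        return fit_logistic(outcome, design, model_id)
    except (SeparationError, RankDeficiencyError) as exc:
        if on_error == "raise":
            raise
        return FailedFit(model_id, list(design.columns), str(exc))


def sequential_models(
    cohort: pd.DataFrame,
    reference_behavior: str = REFERENCE_BEHAVIOR,
    on_error: str = "raise",
) -> list[LogisticFit]:
    """The six-model ladder: crude, then covariates added cumulatively.

    Model 1: behavior only; Models 2-6 add age, BMI, gender, work situation
    and total activity in that order.  With on_error="skip" a model whose MLE
    is inestimable (small strata can separate at desk scale) is returned as a
    FailedFit instead of aborting the ladder.
    """
    fits = []
    terms = ["behavior"]
    fits.append(
        fit_logistic(cohort["depressed"], build_design(cohort, terms, reference_behavior), "Model 1")
    )
    for i, cov in enumerate(COVARIATE_ORDER, start=2):
        terms = terms + [cov]
        fits.append(
            _fit_or_fail(
                cohort["depressed"],
                build_design(cohort, terms, reference_behavior),
                f"Model {i}",
                on_error,
            )
        )
    return fits


def sensitivity_models(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    reference_behavior: str = REFERENCE_BEHAVIOR,
    on_error: str = "raise",
) -> list[LogisticFit]:
    """Behavior plus exactly one covariate per model (residual-confounding check)."""
    covs = COVARIATE_ORDER if covariates is None else covariates
    if not covs:
        raise MalformedInputError("sensitivity analysis needs at least one covariate")
    return [
        _fit_or_fail(
            cohort["depressed"],
            build_design(cohort, ["behavior", cov], reference_behavior),
            f"behavior+{cov}",
            on_error,
        )
        for cov in covs
    ]


def _anova(groups: list[np.ndarray]) -> tuple[float, float]:
    usable = [g[~np.isnan(g)] for g in groups]
    if any(len(g) < 2 for g in usable):
        return float("nan"), float("nan")
    if np.ptp(np.concatenate(usable)) == 0:
        return 0.0, 1.0  # no variance anywhere: F = 0, p = 1 by convention
    f, p = sps.f_oneway(*usable)
    return float(f), float(p)


def _chi2(table: np.ndarray) -> tuple[float, float]:
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.size == 0 or min(t.shape) < 2:
        return float("nan"), float("nan")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def cohort_summary(cohort: pd.DataFrame, behavior_order: list[str] | None = None) -> dict:
    """Per-behavior descriptives with omnibus tests (the Table-1 surface)."""
    order = behavior_order or sorted(cohort["behavior"].unique())
    groups = {b: cohort[cohort["behavior"] == b] for b in order}
    summary: dict = {"behaviors": order, "n": {b: int(len(g)) for b, g in groups.items()}}
    total = len(cohort)
    summary["pct"] = {b: 100.0 * len(g) / total for b, g in groups.items()}

    continuous = [c for c in ("age", "bmi", "total_activity") if c in cohort.columns]
    summary["continuous"] = {}
    for var in continuous:
        f, p = _anova([g[var].to_numpy(dtype=float) for g in groups.values()])
        summary["continuous"][var] = {
            "mean": {b: float(np.nanmean(g[var])) for b, g in groups.items()},
            "sd": {b: float(np.nanstd(g[var], ddof=1)) for b, g in groups.items()},
            "F": f,
            "p": p,
            "significant": bool(p < ALPHA) if np.isfinite(p) else None,
        }

    summary["categorical"] = {}
    cat_specs = {"gender": ["Male", "Female"], "work": WORK_LEVELS}
    if "depressed" in cohort.columns:
        cat_specs["depressed"] = [True, False]
    for var, levels in cat_specs.items():
        if var not in cohort.columns:
            continue
        counts = np.array(
            [[int((groups[b][var] == lev).sum()) for lev in levels] for b in order]
        )
        chi2, p = _chi2(counts)
        pct = {
            b: {
                str(lev): 100.0 * counts[i, j] / counts[i].sum() if counts[i].sum() else 0.0
                for j, lev in enumerate(levels)
            }
            for i, b in enumerate(order)
        }
        summary["categorical"][var] = {
            "levels": [str(lev) for lev in levels],
            "counts": counts.tolist(),
            "pct": pct,
            "chi2": chi2,
            "p": p,
            "significant": bool(p < ALPHA) if np.isfinite(p) else None,
        }
    return summary


def table2_frame(fits: list[LogisticFit]) -> pd.DataFrame:
    """Long-format model/term table of ORs, CIs and p-values."""
    rows = []
    for fit in fits:
        if isinstance(fit, FailedFit):
            rows.append({"model": fit.model_id, "term": "(not estimable)",
                         "or": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan})
            continue
        for term in fit.params.index:
            rows.append(
                {
                    "model": fit.model_id,
                    "term": term,
                    "or": round(float(fit.or_[term]), 4),
                    "ci_low": round(float(fit.ci_low[term]), 4),
                    "ci_high": round(float(fit.ci_high[term]), 4),
                    "p": round(float(fit.p[term]), 4),
                }
            )
    return pd.DataFrame(rows)
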