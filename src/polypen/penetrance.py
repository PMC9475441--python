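"""Penetrance of standardized polygenic scores: decile prevalence curves,
decile-contrast odds ratios, per-SD associations, and hospitalization-count
models.

All regression contrasts use a logistic model of case status on the quantity
of interest plus the standard covariate set (age, age^2, sex, six ancestry
principal components); hospitalization counts default to an ordinary
least-squares fit of the raw count (a Poisson alternative is available).
Confidence intervals are Wald intervals, symmetric on the log-OR scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ["age", "age2", "sex_male", "pc1", "pc2", "pc3", "pc4", "pc5", "pc6"]


@dataclass(frozen=True)
class AssociationResult:
    """One association estimate with its Wald 95% CI.

    ``estimate`` is an odds ratio for logistic families and a regression
    coefficient (per SD of score) for linear/Poisson families.
    """

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    contrast: str
    covariates: str
    family: str

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")
        if self.n <= 0:
            raise ValueError("n must be positive")


def build_covariates(subjects: pd.DataFrame) -> pd.DataFrame:
    """Design columns from a covariate table: age, age^2, male indicator and
    six PCs."""
    out = pd.DataFrame(index=subjects.index)
    out["age"] = subjects["age"].astype(float)
    out["age2"] = out["age"] ** 2
    out["sex_male"] = (subjects["sex"] == "male").astype(float)
    for j in range(1, 7):
        out[f"pc{j}"] = subjects[f"pc{j}"].astype(float)
    return out


def _fit_logit(y: np.ndarray, X: pd.DataFrame, term: str):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        res = model.fit(disp=False, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels raises variously
        raise RuntimeError(
            f"logistic fit failed for term {term!r} ({exc}); consider an exact or "
            "penalized fallback"
        ) from exc
    if not res.mle_retvals.get("converged", True) or np.isnan(res.bse[term]):
        raise RuntimeError(
            f"logistic fit did not converge for term {term!r} (possible complete "
            "separation); consider an exact or penalized fallback"
        )
    return res


def _logit_result(res, term: str, n: int, contrast: str, covs: str) -> AssociationResult:
    b, se = float(res.params[term]), float(res.bse[term])
    return AssociationResult(
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(b - 1.959963984540054 * se)),
        ci_high=float(np.exp(b + 1.959963984540054 * se)),
        p_value=float(res.pvalues[term]),
        n=n,
        contrast=contrast,
        covariates=covs,
        family="logistic",
    )


def assign_deciles(scores: pd.Series) -> pd.Series:
    """Decile index 1..10 from empirical quantile cut points; scores equal to
    a cut point fall in the lower decile."""
    cuts = np.quantile(scores.to_numpy(), np.arange(0.1, 1.0, 0.1))
    dec = (scores.to_numpy()[:, None] > cuts[None, :]).sum(axis=1) + 1
    return pd.Series(dec, index=scores.index, name="decile")


def decile_prevalence(scores: pd.Series, status: pd.Series) -> pd.DataFrame:
    """Case prevalence within each decile of the score.

    ``status`` holds case/control/excluded labels (or booleans); excluded
    subjects are dropped before the decile cut points are computed, so the
    deciles partition exactly the analyzable sample.
    """
    df = _analyzable(scores, status)
    if len(df) < 10:
        raise ValueError("need at least 10 scored, statused subjects")
    df["decile"] = assign_deciles(df["score"])
    rows = []
    for d in range(1, 11):
        sub = df[df["decile"] == d]
        n, k = len(sub), int(sub["case"].sum())
        rows.append(
            {"decile": d, "n": n, "n_cases": k,
             "prevalence": k / n if n else float("nan")}
        )
    return pd.DataFrame(rows).set_index("decile")


def _analyzable(scores: pd.Series, status: pd.Series) -> pd.DataFrame:
    common = scores.index.intersection(status.index)
    s = status.loc[common]
    if s.dtype == bool:
        case = s
        keep = common
    else:
        keep = common[(s == "case") | (s == "control")]
        case = s.loc[keep] == "case"
    return pd.DataFrame({"score": scores.loc[keep], "case": case.astype(bool)})


def decile_odds_ratio(
    scores: pd.Series,
    status: pd.Series,
    covariates: pd.DataFrame | None = None,
    contrast: str = "top_vs_bottom_decile",
) -> AssociationResult:
    """Odds ratio contrasting the top score decile against the bottom decile
    or against the remaining 90%, from a logistic fit with the standard
    covariate set (or none)."""
    if contrast not in ("top_vs_bottom_decile", "top_decile_vs_rest"):
        raise ValueError(f"unknown contrast {contrast!r}")
    df = _analyzable(scores, status)
    df["decile"] = assign_deciles(df["score"])
    if contrast == "top_vs_bottom_decile":
        df = df[df["decile"].isin((1, 10))]
    df["top"] = (df["decile"] == 10).astype(float)
    for grp, sub in df.groupby("top"):
        if sub["case"].nunique() < 2:
            raise ValueError(
                f"contrast group top={int(grp)} lacks both cases and controls"
            )
    X = df[["top"]]
    covs = "none"
    if covariates is not None:
        X = X.join(covariates.loc[df.index, COVARIATE_COLUMNS])
        covs = "age+age2+sex+6PCs"
    res = _fit_logit(df["case"].to_numpy(dtype=float), X, "top")
    return _logit_result(res, "top", len(df), contrast, covs)


def per_sd_association(
    scores: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    contrast: str = "per_sd",
) -> AssociationResult:
    """Odds ratio per SD-unit increase of a standardized score for a binary
    outcome (case status or, e.g., an ever-inpatient flag)."""
    df = _analyzable(scores, outcome)
    X = df[["score"]]
    covs = "none"
    if covariates is not None:
        X = X.join(covariates.loc[df.index, COVARIATE_COLUMNS])
        covs = "age+age2+sex+6PCs"
    res = _fit_logit(df["case"].to_numpy(dtype=float), X, "score")
    return _logit_result(res, "score", len(df), contrast, covs)


def hospitalization_association(
    scores: pd.Series,
    hospitalizations: pd.Series,
    covariates: pd.DataFrame | None = None,
    comorbidity_count: pd.Series | None = None,
    family: str = "linear",
) -> AssociationResult:
    """Association between a standardized score and the number of
    hospitalizations among cases.

    Default family is ordinary least squares on the raw count (beta per SD of
    score); ``family='poisson'`` fits a log-link count model instead. Pass
    ``comorbidity_count`` (e.g., distinct non-psychiatric phecodes per
    subject) to adjust for overall illness burden.
    """
    common = scores.index.intersection(hospitalizations.index)
    y = hospitalizations.loc[common].astype(float)
    if y.var(ddof=0) == 0:
        raise ValueError("hospitalization counts have zero variance")
    X = pd.DataFrame({"score": scores.loc[common]})
    covs = "none"
    if covariates is not None:
        X = X.join(covariates.loc[common, COVARIATE_COLUMNS])
        covs = "age+age2+sex+6PCs"
    if comorbidity_count is not None:
        X["comorbidities"] = comorbidity_count.loc[common].astype(float)
        covs += "+comorbidities"
    Xc = sm.add_constant(X, has_constant="add")
    if family == "linear":
        res = sm.OLS(y, Xc).fit()
    elif family == "poisson":
        res = sm.GLM(y, Xc, family=sm.families.Poisson()).fit()
    else:
        raise ValueError(f"unknown family {family!r}")
    b, se = float(res.params["score"]), float(res.bse["score"])
    z = 1.959963984540054
    return AssociationResult(
        estimate=b, ci_low=b - z * se, ci_high=b + z * se,
        p_value=float(res.pvalues["score"]), n=len(common),
        contrast="per_sd_hospitalizations", covariates=covs, family=family,
    )


def comorbidity_counts(
    phecode_events: pd.DataFrame,
    subjects: pd.Index,
    exclude_phecodes: frozenset[str] = frozenset(
        {"295.1", "295.2", "295.3", "296.1", "296.2"}
    ),
) -> pd.Series:
    """Number of distinct non-psychiatric phecodes per subject."""
    ev = phecode_events[~phecode_events["phecode"].isin(exclude_phecodes)]
    counts = ev.groupby("subject_id")["phecode"].nunique()
    return counts.reindex(subjects, fill_value=0).astype(int)


# ---------------------------------------------------------------------------
# quadrature oracle for the liability-threshold model
# ---------------------------------------------------------------------------

def liability_decile_prevalence_oracle(
    r2: float, prevalence: float, n_points: int = 4001
) -> np.ndarray:
    """Expected case prevalence per score decile under the liability-threshold
    model, by one-dimensional Gaussian quadrature.

    The score z explains a fraction ``r2`` of unit liability variance; disease
    occurs when liability exceeds T = Phi^-1(1 - prevalence), so
    P(case | z) = Phi((sqrt(r2) z - T) / sqrt(1 - r2)). Each decile's expected
    prevalence is the average of that curve over the decile's z range.
    """
    r = np.sqrt(r2)
    T = stats.norm.ppf(1.0 - prevalence)
    edges = stats.norm.ppf(np.linspace(0.0, 1.0, 11))
    out = np.empty(10)
    for d in range(10):
        lo = -10.0 if d == 0 else edges[d]
        hi = 10.0 if d == 9 else edges[d + 1]
        z = np.linspace(lo, hi, n_points)
        p_case = stats.norm.cdf((r * z - T) / np.sqrt(1.0 - r2))
        w = stats.norm.pdf(z)
        out[d] = np.trapezoid(p_case * w, z) / np.trapezoid(w, z)
    return out


def liability_top_bottom_or_oracle(r2: float, prevalence: float) -> float:
    """Population top-vs-bottom-decile odds ratio implied by the quadrature
    curve."""
    prev = liability_decile_prevalence_oracle(r2, prevalence)
    top, bot = prev[9], prev[0]
    return (top / (1 - top)) / (bot / (1 - bot))


def plot_decile_curve(tables: dict[str, pd.DataFrame], path: str, title: str = "") -> None:
    """Write a decile-prevalence curve (one line per labelled group) to SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, tab in tables.items():
        ax.plot(tab.index, 100 * tab["prevalence"], marker="o", label=label)
    ax.set_xlabel("PRS decile")
    ax.set_ylabel("case prevalence (%)")
    ax.set_xticks(range(1, 11))
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
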