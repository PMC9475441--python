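"""Phenome-wide association of a standardized polygenic score against all
phecodes.

Per phecode, cases carry two or more code events, controls carry zero, and
single-code subjects are excluded; the association is a logistic regression of
case status on the score with age, age^2, sex and six ancestry principal
components as covariates. Two-sided p-values are flagged significant at 1e-5
(no further multiple-testing correction; Bonferroni and Benjamini-Hochberg
columns are emitted for information only). Sensitivity analyses either add
lifetime-diagnosis / ever-prescribed indicator covariates or drop subjects
with any lifetime code from the listed phecode sets before case assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .penetrance import COVARIATE_COLUMNS, _fit_logit

logger = logging.getLogger(__name__)

SIGNIFICANCE_THRESHOLD = 1e-5
DEFAULT_MIN_CASES = 100


@dataclass(frozen=True)
class SensitivitySpec:
    """One sensitivity analysis: extra adjustment covariates (phecode sets
    and/or drug classes) and/or lifetime-diagnosis exclusion sets."""

    adjust_for_phecodes: dict[str, frozenset[str]] = field(default_factory=dict)
    adjust_for_drug_classes: tuple[str, ...] = ()
    exclude_subjects_with: frozenset[str] = frozenset()

    @property
    def label(self) -> str:
        parts = []
        if self.adjust_for_phecodes or self.adjust_for_drug_classes:
            adj = sorted(self.adjust_for_phecodes) + sorted(self.adjust_for_drug_classes)
            parts.append("adjusted:" + "+".join(adj))
        if self.exclude_subjects_with:
            parts.append("excluded:" + "+".join(sorted(self.exclude_subjects_with)))
        return "; ".join(parts) if parts else "primary"


def _phecode_count_matrix(phecode_events: pd.DataFrame, subjects: pd.Index) -> pd.DataFrame:
    counts = (
        phecode_events.groupby(["subject_id", "phecode"]).size().unstack(fill_value=0)
    )
    return counts.reindex(subjects, fill_value=0)


def run_phewas(
    scores: pd.Series,
    phecode_events: pd.DataFrame,
    covariates: pd.DataFrame,
    min_cases: int = DEFAULT_MIN_CASES,
    extra_covariates: pd.DataFrame | None = None,
    analysis_label: str = "primary",
    phecode_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Test one standardized score against every phecode in the event stream.

    Returns one row per phecode with OR per SD, Wald 95% CI, p, case/control/
    excluded counts and a ``tested`` flag; phecodes below ``min_cases`` (or
    with non-converging fits) keep their counts but carry NaN statistics.
    """
    subjects = scores.index
    counts = _phecode_count_matrix(phecode_events, subjects)
    categories = {}
    if phecode_map is not None:
        categories = (
            phecode_map.drop_duplicates("phecode").set_index("phecode")["category"].to_dict()
        )
    X_base = pd.DataFrame({"score": scores}).join(
        covariates.loc[subjects, COVARIATE_COLUMNS]
    )
    if extra_covariates is not None:
        X_base = X_base.join(extra_covariates.loc[subjects])
    rows = []
    for phecode in counts.columns:
        c = counts[phecode]
        case = c >= 2
        control = c == 0
        n_cases, n_controls = int(case.sum()), int(control.sum())
        row = {
            "phecode": phecode,
            "category": categories.get(phecode, ""),
            "n_cases": n_cases,
            "n_controls": n_controls,
            "n_excluded": int(len(subjects) - n_cases - n_controls),
            "analysis": analysis_label,
            "tested": False,
            "or_per_sd": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "p": np.nan, "significant": False, "note": "",
        }
        if n_cases < min_cases:
            row["note"] = f"skipped: {n_cases} cases < min_cases={min_cases}"
            logger.info("phecode %s %s", phecode, row["note"])
            rows.append(row)
            continue
        keep = case | control
        y = case[keep].to_numpy(dtype=float)
        X = X_base.loc[keep.index[keep]]
        try:
            res = _fit_logit(y, X, "score")
        except RuntimeError as exc:
            row["note"] = f"fit failed: {exc}"
            logger.warning("phecode %s %s", phecode, row["note"])
            rows.append(row)
            continue
        b, se = float(res.params["score"]), float(res.bse["score"])
        z = 1.959963984540054
        row.update(
            tested=True,
            or_per_sd=float(np.exp(b)),
            ci_low=float(np.exp(b - z * se)),
            ci_high=float(np.exp(b + z * se)),
            p=float(res.pvalues["score"]),
        )
        row["significant"] = row["p"] < SIGNIFICANCE_THRESHOLD
        rows.append(row)
    out = pd.DataFrame(rows)
    tested = out["tested"].to_numpy()
    out["p_bonferroni"] = np.nan
    out["p_fdr_bh"] = np.nan
    if tested.any():
        p = out.loc[tested, "p"].to_numpy()
        out.loc[tested, "p_bonferroni"] = np.minimum(p * tested.sum(), 1.0)
        out.loc[tested, "p_fdr_bh"] = multipletests(p, method="fdr_bh")[1]
    return out


def sensitivity_phewas(
    scores: pd.Series,
    phecode_events: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: SensitivitySpec,
    prescriptions: pd.DataFrame | None = None,
    min_cases: int = DEFAULT_MIN_CASES,
    phecode_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run a PheWAS under a sensitivity specification.

    Adjustment sets become 0/1 covariates (any lifetime code in the phecode
    set; ever prescribed the drug class). Exclusion sets drop subjects with
    >=1 lifetime code from any listed phecode before case/control assignment.
    """
    subjects = scores.index
    extra = pd.DataFrame(index=subjects)
    for name, phe_set in spec.adjust_for_phecodes.items():
        hit = phecode_events[phecode_events["phecode"].isin(phe_set)]
        extra[f"dx_{name}"] = (
            subjects.isin(hit["subject_id"].unique()).astype(float)
        )
    if spec.adjust_for_drug_classes:
        if prescriptions is None:
            raise ValueError("drug-class adjustment requires a prescription table")
        for cls in spec.adjust_for_drug_classes:
            ever = prescriptions.loc[
                prescriptions["drug_class"] == cls, "subject_id"
            ].unique()
            extra[f"rx_{cls}"] = subjects.isin(ever).astype(float)
    keep = subjects
    if spec.exclude_subjects_with:
        hit = phecode_events[
            phecode_events["phecode"].isin(spec.exclude_subjects_with)
        ]["subject_id"].unique()
        keep = subjects[~subjects.isin(hit)]
        logger.info(
            "sensitivity exclusion removed %d of %d subjects",
            len(subjects) - len(keep), len(subjects),
        )
    events = phecode_events[phecode_events["subject_id"].isin(keep)]
    return run_phewas(
        scores.loc[keep],
        events,
        covariates,
        min_cases=min_cases,
        extra_covariates=extra.loc[keep] if len(extra.columns) else None,
        analysis_label=spec.label,
        phecode_map=phecode_map,
    )


def category_effect_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of the odds ratio among significant results,
    per disease category (the null reference OR = 1 is carried along for
    plotting). Empty when nothing is significant."""
    if results.empty:
        raise ValueError("results table is empty")
    sig = results[results["significant"] & results["tested"]]
    rows = []
    for cat, grp in sig.groupby("category"):
        ors = grp["or_per_sd"].to_numpy()
        rows.append(
            {
                "category": cat,
                "n_significant": len(ors),
                "or_q1": float(np.quantile(ors, 0.25)),
                "or_median": float(np.quantile(ors, 0.5)),
                "or_q3": float(np.quantile(ors, 0.75)),
                "null_or": 1.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["category", "n_significant", "or_q1", "or_median", "or_q3", "null_or"]
    ).set_index("category")


def plot_category_boxes(results: pd.DataFrame, path: str) -> None:
    """Category-level boxplot of significant odds ratios (null OR dotted)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sig = results[results["significant"] & results["tested"]]
    cats = sorted(sig["category"].unique())
    data = [sig.loc[sig["category"] == c, "or_per_sd"].to_numpy() for c in cats]
    fig, ax = plt.subplots(figsize=(6, 0.5 + 0.4 * max(len(cats), 1)))
    if data:
        ax.boxplot(data, vert=False, tick_labels=cats)
    ax.axvline(1.0, linestyle=":", color="grey")
    ax.set_xlabel("OR per SD of PRS")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
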