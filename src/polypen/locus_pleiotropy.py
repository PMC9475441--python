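"""Direction-concordance tests for genome-wide-significant source-disorder
loci against a target phenotype.

Each LD-independent locus is oriented to its source risk allele (source log-OR
made positive), tested one variant at a time by logistic regression of the
target case status on risk-allele dosage plus the standard covariates, and
labelled convergent (target coefficient >= 0) or reversed. Whether the number
of reversed (or convergent) loci exceeds the 50% chance expectation is judged
by an exact two-sided binomial test with a Clopper-Pearson interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .penetrance import COVARIATE_COLUMNS, _fit_logit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DirectionTestResult:
    """Exact binomial test of a direction count against a null proportion."""

    n_total: int
    n_discordant: int
    proportion: float
    ci_low: float
    ci_high: float
    p_value: float
    null_p: float = 0.5

    def __post_init__(self):
        if not (0 <= self.n_discordant <= self.n_total):
            raise ValueError("count outside [0, n_total]")
        if not (0.0 <= self.ci_low <= self.ci_high <= 1.0):
            raise ValueError("confidence interval outside [0, 1]")


def orient_to_risk_allele(weights: pd.DataFrame) -> pd.DataFrame:
    """Flip negative-weight loci so every source effect is risk-allele
    oriented (positive log-OR); a ``flipped`` column records which alt-dosage
    columns must be reflected (2 - dosage) downstream."""
    out = weights.copy()
    out["flipped"] = out["weight"] < 0
    out["weight"] = out["weight"].abs()
    return out


def test_locus_directions(
    loci: pd.DataFrame,
    genotypes: pd.DataFrame,
    target_status: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-locus logistic regression of target status on risk-allele dosage.

    ``loci`` is a WeightTable restricted to the clumped genome-wide-
    significant set (oriented here if not already). Returns a LocusEffectTable
    with the source and target log-ORs, the target p-value and the direction
    label; monomorphic loci are dropped and logged.
    """
    oriented = loci if "flipped" in loci.columns else orient_to_risk_allele(loci)
    keep = target_status[(target_status == "case") | (target_status == "control")] \
        if target_status.dtype == object else target_status
    if keep.dtype == object:
        y_all = (keep == "case").astype(float)
    else:
        y_all = keep.astype(float)
    common = genotypes.index.intersection(y_all.index)
    y = y_all.loc[common].to_numpy()
    rows = []
    for locus in oriented.itertuples(index=False):
        dos = genotypes.loc[common, locus.variant_id].to_numpy(dtype=float)
        if locus.flipped:
            dos = 2.0 - dos
        if np.nanstd(dos) == 0:
            logger.warning("locus %s is monomorphic in cohort; dropped", locus.variant_id)
            continue
        X = pd.DataFrame({"dosage": dos}, index=common)
        if covariates is not None:
            X = X.join(covariates.loc[common, COVARIATE_COLUMNS])
        res = _fit_logit(y, X, "dosage")
        beta = float(res.params["dosage"])
        rows.append(
            {
                "variant_id": locus.variant_id,
                "source_beta": float(locus.weight),
                "target_beta": beta,
                "target_p": float(res.pvalues["dosage"]),
                "direction": "convergent" if beta >= 0 else "reversed",
            }
        )
    return pd.DataFrame(rows)


def direction_binomial_test(
    n_discordant: int, n_total: int, null_p: float = 0.5
) -> DirectionTestResult:
    """Exact two-sided binomial test of a direction count.

    The two-sided p sums the probabilities of all outcomes no more likely than
    the observed count (minimum-likelihood convention); the 95% CI is the
    exact Clopper-Pearson interval.
    """
    if n_total < 1 or not (0 <= n_discordant <= n_total):
        raise ValueError("require 0 <= n_discordant <= n_total, n_total >= 1")
    if not (0.0 < null_p < 1.0):
        raise ValueError("null_p must lie in (0, 1)")
    res = binomtest(n_discordant, n_total, null_p)
    ci = res.proportion_ci(confidence_level=0.95, method="exact")
    return DirectionTestResult(
        n_total=n_total,
        n_discordant=n_discordant,
        proportion=n_discordant / n_total,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(res.pvalue),
        null_p=null_p,
    )


def plot_locus_effects(effects: pd.DataFrame, path: str, title: str = "") -> None:
    """Forest-style plot of per-locus target effects (null effect dotted)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = effects.sort_values("target_beta").reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(5, 0.5 + 0.12 * len(order)))
    colors = np.where(order["direction"] == "reversed", "tab:red", "tab:blue")
    ax.scatter(order["target_beta"], range(len(order)), s=8, c=colors)
    ax.axvline(0.0, linestyle=":", color="grey")
    ax.set_xlabel("target log-OR per risk allele")
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
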