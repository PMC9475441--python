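"""Common-factor decomposition of the three-disorder genetic covariance and
per-SNV common vs disorder-specific effects.

With three indicators and one factor the model is just-identified (six free
parameters, six observed moments), so the loadings have the closed form
lambda_1 = sqrt(S12 * S13 / S23) (and cyclic permutations) with residual
variances theta_i = S_ii - lambda_i^2; the model-implied covariance reproduces
the input exactly. Per-SNV associations beta (one per disorder) are projected
onto the factor by generalized least squares,
b_F = (lambda' V^-1 lambda)^-1 lambda' V^-1 beta, with disorder-specific
effects as the residuals beta - lambda * b_F; the decomposition reconstructs
beta exactly by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_LABELS: tuple[str, ...] = ("SCZ", "BIP", "MDD")


def validate_covariance(S: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.shape != (3, 3):
        raise ValueError("genetic covariance must be 3x3")
    if not np.allclose(S, S.T, atol=tol):
        raise ValueError("genetic covariance must be symmetric")
    if np.any(np.diag(S) <= 0):
        raise ValueError("diagonal genetic variances must be positive")
    if np.min(np.linalg.eigvalsh(S)) < -1e-6:
        raise ValueError("genetic covariance is not positive semi-definite")
    return S


@dataclass(frozen=True)
class FactorSolution:
    """Loadings and residual variances of the single common factor."""

    loadings: np.ndarray
    residual_variances: np.ndarray
    labels: tuple[str, ...] = DEFAULT_LABELS

    def implied_covariance(self) -> np.ndarray:
        lam = self.loadings
        return np.outer(lam, lam) + np.diag(self.residual_variances)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"loading": self.loadings, "residual_variance": self.residual_variances},
            index=list(self.labels),
        )


def fit_common_factor(
    S: np.ndarray, labels: tuple[str, ...] = DEFAULT_LABELS, heywood_tol: float = 1e-10
) -> FactorSolution:
    """Closed-form just-identified single-factor fit to a 3x3 genetic
    covariance.

    Requires nonzero off-diagonals whose product is positive (a sign pattern
    a single factor can generate). The factor sign is fixed by constraining
    the first loading to be positive. Negative residual variances (Heywood
    cases) raise rather than being truncated.
    """
    S = validate_covariance(S)
    off = np.array([S[0, 1], S[0, 2], S[1, 2]])
    if np.any(off == 0):
        raise ValueError(
            "off-diagonal genetic covariances must be nonzero "
            f"(got S12={off[0]}, S13={off[1]}, S23={off[2]}); the closed-form "
            "loading diverges as any of them approaches zero"
        )
    if np.prod(off) <= 0:
        raise ValueError(
            "sign-inconsistent off-diagonal covariances "
            f"(S12={off[0]}, S13={off[1]}, S23={off[2]}): a single factor "
            "implies S12*S13*S23 > 0"
        )
    lam = np.array(
        [
            np.sqrt(S[0, 1] * S[0, 2] / S[1, 2]),
            np.sqrt(S[0, 1] * S[1, 2] / S[0, 2]),
            np.sqrt(S[0, 2] * S[1, 2] / S[0, 1]),
        ]
    )
    # recover signs: lambda_1 > 0 by convention, others from sign(S1j)
    lam[1] *= np.sign(S[0, 1])
    lam[2] *= np.sign(S[0, 2])
    theta = np.diag(S) - lam**2
    bad = np.flatnonzero(theta < -heywood_tol)
    if bad.size:
        raise ValueError(
            "Heywood case: negative residual variance for "
            + ", ".join(f"{labels[i]} (theta={theta[i]:.4g})" for i in bad)
        )
    theta = np.maximum(theta, 0.0)
    return FactorSolution(loadings=lam, residual_variances=theta, labels=labels)


@dataclass(frozen=True)
class SNVFactorEffect:
    """GLS decomposition of one SNV's three disorder associations into a
    common-factor effect and disorder-specific residuals."""

    b_factor: float
    se_factor: float
    residuals: np.ndarray
    sampling_cov: np.ndarray = field(repr=False)

    @property
    def p_factor(self) -> float:
        z = self.b_factor / self.se_factor
        return float(2 * stats.norm.sf(abs(z)))


def snv_factor_effects(
    beta: np.ndarray, V: np.ndarray, solution: FactorSolution
) -> SNVFactorEffect:
    """Project a 3-vector of SNV-disorder associations onto the common factor.

    b_F = (lambda' V^-1 lambda)^-1 lambda' V^-1 beta with standard error
    (lambda' V^-1 lambda)^-1/2; residuals are beta - lambda * b_F and satisfy
    lambda*b_F + residual = beta exactly.
    """
    beta = np.asarray(beta, dtype=float).reshape(3)
    V = np.asarray(V, dtype=float)
    if V.shape != (3, 3):
        raise ValueError("sampling covariance must be 3x3")
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular sampling covariance") from exc
    if np.min(np.linalg.eigvalsh((V + V.T) / 2)) <= 0:
        raise ValueError("sampling covariance must be positive definite")
    lam = solution.loadings
    precision = float(lam @ Vinv @ lam)
    b_f = float(lam @ Vinv @ beta) / precision
    return SNVFactorEffect(
        b_factor=b_f,
        se_factor=precision ** -0.5,
        residuals=beta - lam * b_f,
        sampling_cov=V,
    )


def default_sampling_covariance(
    se: np.ndarray, overlap_correlation: float = 0.0
) -> np.ndarray:
    """Sampling covariance of a SNV's three association estimates: diagonal of
    squared standard errors with an optional uniform cross-trait correlation
    for overlapping GWAS samples."""
    se = np.asarray(se, dtype=float).reshape(3)
    if not (-1.0 < overlap_correlation < 1.0):
        raise ValueError("overlap correlation must lie in (-1, 1)")
    V = np.outer(se, se) * overlap_correlation
    np.fill_diagonal(V, se**2)
    return V


def build_factor_weight_tables(
    stats_tables: dict[str, pd.DataFrame],
    solution: FactorSolution,
    variant_ids: list[str] | None = None,
    overlap_correlation: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Decompose every SNV and emit weight tables for latent-factor PRSs.

    ``stats_tables`` maps each disorder label to its harmonized summary-stats
    table (columns variant_id, chromosome, position, effect_allele /
    alt-aligned beta, se, frequency). Returns one common-factor WeightTable
    plus one disorder-specific WeightTable per label, all in the scoring
    WeightTable format so latent PRSs flow through the identical C+T path.
    P-values come from the Wald statistics of b_F and of the residuals.
    """
    labels = solution.labels
    base = stats_tables[labels[0]].set_index("variant_id")
    if variant_ids is None:
        variant_ids = list(base.index)
    betas = np.column_stack(
        [
            stats_tables[lab].set_index("variant_id").loc[variant_ids, "beta"].to_numpy()
            for lab in labels
        ]
    )
    ses = np.column_stack(
        [
            stats_tables[lab].set_index("variant_id").loc[variant_ids, "se"].to_numpy()
            for lab in labels
        ]
    )
    meta = base.loc[variant_ids, ["chromosome", "position", "effect_allele", "frequency"]]
    common_rows, spec_rows = [], {lab: [] for lab in labels}
    lam = solution.loadings
    for i, vid in enumerate(variant_ids):
        V = default_sampling_covariance(ses[i], overlap_correlation)
        eff = snv_factor_effects(betas[i], V, solution)
        m = meta.loc[vid]
        common_rows.append(
            {
                "variant_id": vid, "chromosome": m.chromosome,
                "position": int(m.position), "effect_allele": m.effect_allele,
                "weight": eff.b_factor, "p": eff.p_factor,
                "frequency": float(m.frequency),
            }
        )
        # residual sampling covariance: (I - lam h') V (I - lam h')'
        Vinv = np.linalg.inv(V)
        h = (Vinv @ lam) / float(lam @ Vinv @ lam)
        A = np.eye(3) - np.outer(lam, h)
        rvar = np.diag(A @ V @ A.T)
        for d, lab in enumerate(labels):
            r = float(eff.residuals[d])
            se_r = float(np.sqrt(max(rvar[d], 0.0)))
            p = float(2 * stats.norm.sf(abs(r) / se_r)) if se_r > 0 else 1.0
            spec_rows[lab].append(
                {
                    "variant_id": vid, "chromosome": m.chromosome,
                    "position": int(m.position), "effect_allele": m.effect_allele,
                    "weight": r, "p": p, "frequency": float(m.frequency),
                }
            )
    common = pd.DataFrame(common_rows)
    specific = {lab: pd.DataFrame(rows) for lab, rows in spec_rows.items()}
    return common, specific
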