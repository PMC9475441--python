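"""Clumping + thresholding polygenic risk scores.

Given GWAS summary statistics (per-variant log odds ratios) and target
genotypes, the scoring path is: harmonize effect alleles to the target panel,
drop the MHC (and any other configured exclusion region), greedily clump to an
LD-independent index set (best p first, removing neighbours within a +/-500 kb
window whose dosage r^2 exceeds 0.1), then for each p-value threshold sum
risk-allele dosages weighted by their log-OR, and finally standardize scores
to mean 0 / SD 1 within ancestry group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: extended MHC span conventionally excluded from psychiatric PRS
DEFAULT_MHC: tuple[str, int, int] = ("6", 25_000_000, 34_000_000)

#: default p-value threshold grid for C+T scoring
DEFAULT_P_THRESHOLDS: tuple[float, ...] = (
    5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0
)

AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class ClumpConfig:
    r2_threshold: float = 0.1
    window_kb: float = 500.0
    exclusion_regions: tuple[tuple[str, int, int], ...] = (DEFAULT_MHC,)
    p_thresholds: tuple[float, ...] = DEFAULT_P_THRESHOLDS

    def __post_init__(self):
        if not (0.0 < self.r2_threshold < 1.0):
            raise ValueError("r2_threshold must lie in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if list(self.p_thresholds) != sorted(self.p_thresholds) or not self.p_thresholds:
            raise ValueError("p_thresholds must be a nonempty ascending list")
        for chrom, start, end in self.exclusion_regions:
            if start >= end:
                raise ValueError(f"malformed exclusion region {chrom}:{start}-{end}")


def harmonize_alleles(
    stats: pd.DataFrame, variants: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Align summary-statistics effect alleles to the target panel's alt allele.

    Returns a WeightTable (variant_id, chromosome, position, effect_allele,
    weight, p, frequency — weight applies to the alt-allele dosage) and a
    report counting each harmonization category. The weight sign is flipped
    when the effect allele matches the target ref; strand-ambiguous (A/T, C/G)
    pairs and allele-set mismatches are dropped.
    """
    tgt = variants.set_index("variant_id")
    report = {"matched": 0, "flipped": 0, "ambiguous": 0, "mismatch": 0, "absent": 0}
    rows = []
    for s in stats.itertuples(index=False):
        if s.variant_id not in tgt.index:
            report["absent"] += 1
            continue
        v = tgt.loc[s.variant_id]
        pair = frozenset((s.effect_allele, s.other_allele))
        if pair in AMBIGUOUS_PAIRS:
            report["ambiguous"] += 1
            continue
        if pair != frozenset((v.ref_allele, v.alt_allele)):
            report["mismatch"] += 1
            continue
        if s.effect_allele == v.alt_allele:
            weight, freq = s.beta, s.frequency
            report["matched"] += 1
        else:
            weight, freq = -s.beta, 1.0 - s.frequency
            report["flipped"] += 1
        rows.append(
            {
                "variant_id": s.variant_id,
                "chromosome": v.chromosome,
                "position": int(v.position),
                "effect_allele": v.alt_allele,
                "weight": float(weight),
                "p": float(s.p),
                "frequency": float(freq),
            }
        )
    if not rows:
        raise ValueError(f"no variants survived allele harmonization: {report}")
    weights = pd.DataFrame(rows)
    if weights["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids after harmonization")
    logger.info("harmonization report: %s", report)
    return weights, report


def exclude_regions(
    table: pd.DataFrame, regions: tuple[tuple[str, int, int], ...]
) -> pd.DataFrame:
    """Drop rows whose (chromosome, position) falls inside any closed region
    [start, end]."""
    keep = np.ones(len(table), dtype=bool)
    for chrom, start, end in regions:
        if start >= end:
            raise ValueError(f"malformed region {chrom}:{start}-{end}")
        hit = (
            (table["chromosome"].astype(str) == str(chrom))
            & (table["position"] >= start)
            & (table["position"] <= end)
        )
        keep &= ~hit.to_numpy()
    return table.loc[keep].reset_index(drop=True)


def ld_clump(
    weights: pd.DataFrame,
    ref_genotypes: pd.DataFrame,
    config: ClumpConfig = ClumpConfig(),
) -> list[str]:
    """Greedy LD clumping against a reference genotype panel.

    Repeatedly retain the remaining variant with the smallest p (ties broken
    by chromosome, position, variant_id) and discard all others on the same
    chromosome within +/- window_kb whose squared Pearson dosage correlation
    with it exceeds ``r2_threshold``. Returns retained variant ids sorted by
    (chromosome, position).
    """
    missing = set(weights["variant_id"]) - set(ref_genotypes.columns)
    if missing:
        raise ValueError(f"variants absent from reference panel: {sorted(missing)}")
    w = weights.sort_values(
        ["p", "chromosome", "position", "variant_id"], kind="stable"
    ).reset_index(drop=True)
    window_bp = config.window_kb * 1000.0
    G = ref_genotypes[w["variant_id"]].to_numpy(dtype=float)
    chrom = w["chromosome"].astype(str).to_numpy()
    pos = w["position"].to_numpy()
    active = np.ones(len(w), dtype=bool)
    retained: list[int] = []
    for i in range(len(w)):
        if not active[i]:
            continue
        retained.append(i)
        active[i] = False
        near = active & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        idx = np.flatnonzero(near)
        if idx.size:
            gi = G[:, i]
            for j in idx:
                r = np.corrcoef(gi, G[:, j])[0, 1]
                if np.isnan(r):
                    r = 0.0
                if r * r > config.r2_threshold:
                    active[j] = False
    kept = w.iloc[retained].sort_values(["chromosome", "position"], kind="stable")
    return kept["variant_id"].tolist()


def compute_prs(
    genotypes: pd.DataFrame,
    weights: pd.DataFrame,
    p_thresholds: tuple[float, ...] = DEFAULT_P_THRESHOLDS,
) -> pd.DataFrame:
    """Raw clumping+thresholding scores: one column per p-value threshold t,
    score(subject, t) = sum over variants with p <= t of dosage * weight.
    Missing dosages contribute the mean 2 * frequency * weight.
    """
    if not len(p_thresholds):
        raise ValueError("p_thresholds must be nonempty")
    w = weights[weights["variant_id"].isin(genotypes.columns)]
    G = genotypes[w["variant_id"]].to_numpy(dtype=float)
    fill = 2.0 * w["frequency"].to_numpy()
    G = np.where(np.isnan(G), fill[None, :], G)
    out = {}
    pvals = w["p"].to_numpy()
    wt = w["weight"].to_numpy()
    for t in p_thresholds:
        mask = pvals <= t
        out[f"p{t:g}"] = G[:, mask] @ wt[mask]
    return pd.DataFrame(out, index=genotypes.index)


def standardize_scores(
    scores: pd.DataFrame, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Standardize each score column to mean 0 / SD 1 within group.

    Uses the population-SD convention (divide by n). ``groups`` maps
    subject_id -> group label; omit it to standardize over the whole cohort.
    """
    if groups is None:
        groups = pd.Series("all", index=scores.index)
    groups = groups.reindex(scores.index)
    if groups.isna().any():
        raise ValueError("some scored subjects have no group label")
    out = scores.copy().astype(float)
    for g, idx in scores.groupby(groups).groups.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        block = scores.loc[idx]
        sd = block.std(ddof=0)
        zero = sd[sd == 0]
        if len(zero):
            raise ValueError(
                f"zero score variance in group {g!r}, column(s) {list(zero.index)}"
            )
        out.loc[idx] = (block - block.mean()) / sd
    return out
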