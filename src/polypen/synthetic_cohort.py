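"""Synthetic cohort generator: genotypes, GWAS summary statistics, liability-threshold
diagnoses, and noisy EHR billing-code / prescription streams.

The generator emulates the data substrate of a health-system biobank study of
three genetically correlated psychiatric disorders (schizophrenia, bipolar
disorder, major depression):

* genotypes are biallelic SNVs in block-diagonal linkage disequilibrium,
  produced by thresholding correlated latent Gaussians per haplotype so that
  marginal genotype frequencies follow Hardy-Weinberg proportions;
* each disorder's liability is the sum of a shared common-factor component
  (with loading ``lambda_d``), disorder-specific variant effects, and
  disorder-specific environmental noise, standardized to unit variance;
  diagnosis occurs when liability exceeds the threshold implied by the
  disorder's population prevalence;
* GWAS summary statistics are the true *marginal* (LD-convolved) per-variant
  effects plus sampling noise at a configurable training-GWAS size;
* the EHR coding process emits disorder-concordant billing codes per clinical
  encounter with imperfect sensitivity, schizophrenia<->bipolar cross-coding,
  inpatient flags, background codes for ~40 non-psychiatric phecodes, and
  medication records concordant with diagnosis.

All randomness flows through explicit integer seeds; identical seed and
configuration give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DISORDERS: tuple[str, ...] = ("SCZ", "BIP", "MDD")

#: phecode families used by the coding process (schizophrenia codes split
#: across the three schizophrenia-spectrum phecodes)
PSYCH_PHECODES: dict[str, tuple[str, ...]] = {
    "SCZ": ("295.1", "295.2", "295.3"),
    "BIP": ("296.1",),
    "MDD": ("296.2",),
}
#: within-family phecode emission weights (schizophrenia mostly codes 295.1)
PSYCH_PHECODE_WEIGHTS: dict[str, tuple[float, ...]] = {
    "SCZ": (0.7, 0.1, 0.2),
    "BIP": (1.0,),
    "MDD": (1.0,),
}
DRUG_CLASS_FOR: dict[str, str] = {
    "SCZ": "antipsychotic",
    "BIP": "mood_stabilizer",
    "MDD": "antidepressant",
}
DRUG_CLASSES: tuple[str, ...] = ("antipsychotic", "mood_stabilizer", "antidepressant")


def load_phecode_map(path: str | None = None) -> pd.DataFrame:
    """Load an ICD->phecode map (columns: icd_code, phecode, category, ...).

    With no ``path`` the bundled miniature synthetic vocabulary is used: a
    desk-scale stand-in for the full ICD/phecode tables with the five
    psychiatric phecodes plus ~40 non-psychiatric ones.
    """
    if path is None:
        ref = resources.files("polypen.data").joinpath("synthetic_phecode_map.csv")
        with resources.as_file(ref) as p:
            pmap = pd.read_csv(p, dtype=str)
    else:
        pmap = pd.read_csv(path, dtype=str)
    required = {"icd_code", "phecode", "category"}
    missing = required - set(pmap.columns)
    if missing:
        raise ValueError(f"phecode map missing columns: {sorted(missing)}")
    return pmap


# ---------------------------------------------------------------------------
# variants and genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDBlockSpec:
    """Block-diagonal LD structure: ``sizes[i]`` consecutive variants share a
    latent (haplotype-scale) equicorrelation ``correlations[i]``."""

    sizes: tuple[int, ...]
    correlations: tuple[float, ...]

    def __post_init__(self):
        if len(self.sizes) != len(self.correlations):
            raise ValueError("sizes and correlations must have equal length")
        for i, r in enumerate(self.correlations):
            if not (0.0 <= r < 1.0):
                raise ValueError(f"block {i}: correlation {r} outside [0, 1)")

    @property
    def n_variants(self) -> int:
        return int(sum(self.sizes))

    def block_slices(self) -> list[slice]:
        out, start = [], 0
        for s in self.sizes:
            out.append(slice(start, start + s))
            start += s
        return out


def make_variant_table(
    n_variants: int,
    seed: int,
    n_chromosomes: int = 2,
    spacing_bp: int = 50_000,
    freq_range: tuple[float, float] = (0.05, 0.5),
) -> pd.DataFrame:
    """Build a VariantTable skeleton with evenly spaced positions and random
    alt-allele frequencies (ref/alt drawn to avoid strand-ambiguous pairs
    except for a small fraction, so harmonization has work to do)."""
    rng = np.random.default_rng(seed)
    per_chrom = int(np.ceil(n_variants / n_chromosomes))
    chroms, positions = [], []
    for c in range(1, n_chromosomes + 1):
        k = min(per_chrom, n_variants - len(chroms))
        chroms += [str(c)] * k
        positions += [spacing_bp * (i + 1) for i in range(k)]
        if len(chroms) >= n_variants:
            break
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]
    alleles = [pairs[i] for i in rng.integers(0, len(pairs), n_variants)]
    freqs = rng.uniform(*freq_range, n_variants)
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(n_variants)],
            "chromosome": chroms,
            "position": positions,
            "ref_allele": [a[0] for a in alleles],
            "alt_allele": [a[1] for a in alleles],
            "alt_frequency": freqs,
        }
    )


def validate_variant_table(variants: pd.DataFrame) -> None:
    if (variants["ref_allele"] == variants["alt_allele"]).any():
        raise ValueError("ref allele equals alt allele for some variants")
    if not variants["alt_frequency"].between(0, 1, inclusive="neither").all():
        raise ValueError("alt frequencies must lie strictly in (0, 1)")
    for chrom, grp in variants.groupby("chromosome"):
        if not grp["position"].is_monotonic_increasing or grp["position"].duplicated().any():
            raise ValueError(f"positions not strictly increasing on chromosome {chrom}")


def simulate_genotypes(
    n_subjects: int,
    variants: pd.DataFrame,
    ld_blocks: LDBlockSpec,
    seed: int,
) -> pd.DataFrame:
    """Simulate a subjects x variants dosage matrix (values in {0, 1, 2}).

    Two independent haplotypes are drawn per subject; within an LD block each
    haplotype is a latent equicorrelated Gaussian vector thresholded at
    Phi^-1(alt_frequency), so marginal genotypes are Hardy-Weinberg and
    between-variant dosage correlation is governed by the latent correlation.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if ld_blocks.n_variants != len(variants):
        raise ValueError(
            f"LD spec covers {ld_blocks.n_variants} variants, table has {len(variants)}"
        )
    validate_variant_table(variants)
    rng = np.random.default_rng(seed)
    freqs = variants["alt_frequency"].to_numpy()
    thresholds = stats.norm.ppf(freqs)
    dosage = np.zeros((n_subjects, len(variants)), dtype=np.int8)
    for sl, r in zip(ld_blocks.block_slices(), ld_blocks.correlations):
        m = sl.stop - sl.start
        # equicorrelated MVN via one shared factor: z = sqrt(r)*f + sqrt(1-r)*e
        for _hap in range(2):
            f = rng.standard_normal((n_subjects, 1))
            e = rng.standard_normal((n_subjects, m))
            z = np.sqrt(r) * f + np.sqrt(1.0 - r) * e
            dosage[:, sl] += (z < thresholds[sl]).astype(np.int8)
    geno = pd.DataFrame(
        dosage,
        index=pd.Index([f"S{i + 1:06d}" for i in range(n_subjects)], name="subject_id"),
        columns=variants["variant_id"].to_numpy(),
    )
    logger.info("simulated genotypes: %d subjects x %d variants (seed=%d)",
                n_subjects, len(variants), seed)
    return geno


def haplotype_indicator_correlation(p1: float, p2: float, latent_r: float) -> float:
    """Correlation between two thresholded-Gaussian allele indicators with
    alt frequencies ``p1``, ``p2`` and latent correlation ``latent_r``.

    Dosages are sums of two iid haplotype indicators, so this also equals the
    theoretical dosage correlation.
    """
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    p11 = stats.multivariate_normal.cdf(
        [t1, t2], mean=[0.0, 0.0], cov=[[1.0, latent_r], [latent_r, 1.0]]
    )
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def dosage_correlation_matrix(variants: pd.DataFrame, ld_blocks: LDBlockSpec) -> np.ndarray:
    """Theoretical block-diagonal dosage correlation matrix implied by the
    latent-Gaussian thresholding model."""
    freqs = variants["alt_frequency"].to_numpy()
    n = len(variants)
    R = np.eye(n)
    for sl, r in zip(ld_blocks.block_slices(), ld_blocks.correlations):
        if r == 0.0:
            continue
        idx = range(sl.start, sl.stop)
        for i in idx:
            for j in idx:
                if j > i:
                    rij = haplotype_indicator_correlation(freqs[i], freqs[j], r)
                    R[i, j] = R[j, i] = rij
    return R


# ---------------------------------------------------------------------------
# liability model
# ---------------------------------------------------------------------------

@dataclass
class TrueLiabilityModel:
    """Ground-truth multivariate liability model.

    liability_d = lambda_d * F + b_d . x_std + specific_sd_d * eps_d, with the
    common factor F = a . x_std + env noise scaled to unit variance, and x_std
    the dosages standardized by their theoretical mean/SD. Unit liability
    variance per disorder requires
    lambda_d^2 + (b_d' R b_d) + specific_sd_d^2 = 1 (variants carrying factor
    effects and disorder-specific effects live in disjoint LD blocks, so there
    is no cross term).
    """

    loadings: np.ndarray                # (3,)
    specific_sd: np.ndarray             # (3,)
    prevalences: np.ndarray             # (3,)
    factor_effects: np.ndarray          # (n_variants,) joint effects on F
    specific_effects: np.ndarray        # (3, n_variants) joint effects
    factor_env_sd: float                # env part of F, var(F) == 1
    disorders: tuple[str, ...] = DISORDERS

    @property
    def thresholds(self) -> np.ndarray:
        return stats.norm.ppf(1.0 - self.prevalences)

    def variance_budget(self, R: np.ndarray) -> pd.DataFrame:
        """Per-disorder decomposition of the liability variance; each row
        must total 1 for a valid model."""
        rows = []
        for d, disorder in enumerate(self.disorders):
            b = self.specific_effects[d]
            rows.append(
                {
                    "disorder": disorder,
                    "factor": self.loadings[d] ** 2,
                    "specific_genetic": float(b @ R @ b),
                    "specific_env": self.specific_sd[d] ** 2,
                }
            )
        out = pd.DataFrame(rows).set_index("disorder")
        out["total"] = out.sum(axis=1)
        return out

    def validate(self, R: np.ndarray, tol: float = 1e-6) -> None:
        if not np.all((self.prevalences > 0) & (self.prevalences < 1)):
            raise ValueError("prevalences must lie in (0, 1)")
        budget = self.variance_budget(R)
        if not np.allclose(budget["total"], 1.0, atol=tol):
            raise ValueError(
                "liability variance budget violated (must total 1 per disorder):\n"
                f"{budget.round(4)}"
            )
        fg = self.factor_effects @ R @ self.factor_effects
        if not np.isclose(fg + self.factor_env_sd**2, 1.0, atol=tol):
            raise ValueError(
                f"common factor variance {fg + self.factor_env_sd**2:.4f} != 1"
            )

    def marginal_effects(self, R: np.ndarray, disorder: str) -> np.ndarray:
        """True GWAS (marginal) per-variant effects on the disorder's
        liability: LD convolves joint effects, beta_marg = R (lambda*a + b)."""
        d = self.disorders.index(disorder)
        joint = self.loadings[d] * self.factor_effects + self.specific_effects[d]
        return R @ joint


def make_liability_model(
    variants: pd.DataFrame,
    ld_blocks: LDBlockSpec,
    seed: int,
    loadings: tuple[float, float, float] = (0.8, 0.6, 0.4),
    prevalences: tuple[float, float, float] = (0.046, 0.077, 0.413),
    factor_h2: float = 0.5,
    specific_h2: tuple[float, float, float] = (0.10, 0.10, 0.10),
    n_causal_factor: int | None = None,
    n_causal_specific: int | None = None,
) -> tuple[TrueLiabilityModel, np.ndarray]:
    """Construct a valid liability model and the theoretical dosage
    correlation matrix it was normalized against.

    ``factor_h2`` is the genetic fraction of common-factor variance;
    ``specific_h2[d]`` the disorder-specific genetic variance. Causal variants
    for the factor and for each disorder are drawn from disjoint LD blocks so
    the variance budget decomposes exactly. Default prevalences are
    health-system lifetime rates for schizophrenia, bipolar disorder and
    major depression (4.6%, 7.7%, 41.3%).
    """
    lam = np.asarray(loadings, dtype=float)
    K = np.asarray(prevalences, dtype=float)
    sh2 = np.asarray(specific_h2, dtype=float)
    resid = 1.0 - lam**2 - sh2
    if np.any(resid < 0):
        raise ValueError("loadings^2 + specific_h2 exceed unit variance")
    R = dosage_correlation_matrix(variants, ld_blocks)
    slices = ld_blocks.block_slices()
    if len(slices) < 4:
        raise ValueError("need >= 4 LD blocks to house disjoint causal sets")
    rng = np.random.default_rng(seed)
    # round-robin block assignment: factor gets blocks 0,4,8,..., SCZ 1,5,..., etc.
    groups: list[list[int]] = [[], [], [], []]
    for bi, sl in enumerate(slices):
        groups[bi % 4].extend(range(sl.start, sl.stop))
    n = len(variants)

    def draw_effects(idx: list[int], target_var: float, k: int | None) -> np.ndarray:
        if k is not None:
            idx = list(rng.choice(idx, size=min(k, len(idx)), replace=False))
        b = np.zeros(n)
        b[idx] = rng.standard_normal(len(idx))
        v = b @ R @ b
        if target_var > 0 and v > 0:
            b *= np.sqrt(target_var / v)
        else:
            b[:] = 0.0
        return b

    a = draw_effects(groups[0], factor_h2, n_causal_factor)
    spec = np.vstack(
        [draw_effects(groups[1 + d], sh2[d], n_causal_specific) for d in range(3)]
    )
    model = TrueLiabilityModel(
        loadings=lam,
        specific_sd=np.sqrt(resid),
        prevalences=K,
        factor_effects=a,
        specific_effects=spec,
        factor_env_sd=float(np.sqrt(max(0.0, 1.0 - factor_h2))),
    )
    model.validate(R)
    return model, R


def standardize_dosages(genotypes: pd.DataFrame, variants: pd.DataFrame) -> np.ndarray:
    freqs = variants.set_index("variant_id").loc[genotypes.columns, "alt_frequency"].to_numpy()
    return (genotypes.to_numpy(dtype=float) - 2 * freqs) / np.sqrt(2 * freqs * (1 - freqs))


def simulate_liability_phenotypes(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    model: TrueLiabilityModel,
    seed: int,
    R: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw liabilities and threshold them into diagnoses.

    Returns a DiagnosisTruth frame with the common-factor value, one liability
    column and one boolean case column per disorder.
    """
    if R is not None:
        model.validate(R)
    rng = np.random.default_rng(seed)
    x = standardize_dosages(genotypes, variants)
    n = x.shape[0]
    factor = x @ model.factor_effects + model.factor_env_sd * rng.standard_normal(n)
    out = pd.DataFrame({"subject_id": genotypes.index, "factor": factor})
    T = model.thresholds
    for d, disorder in enumerate(model.disorders):
        liab = (
            model.loadings[d] * factor
            + x @ model.specific_effects[d]
            + model.specific_sd[d] * rng.standard_normal(n)
        )
        out[f"liability_{disorder}"] = liab
        out[f"case_{disorder}"] = liab > T[d]
    out = out.set_index("subject_id")
    logger.info(
        "simulated diagnoses (seed=%d): prevalences %s",
        seed,
        {d: float(out[f"case_{d}"].mean()) for d in model.disorders},
    )
    return out


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_summary_stats(
    model: TrueLiabilityModel,
    variants: pd.DataFrame,
    n_gwas: int,
    seed: int,
    disorder: str = "SCZ",
    R: np.ndarray | None = None,
    ld_blocks: LDBlockSpec | None = None,
) -> pd.DataFrame:
    """Simulate a training-GWAS summary-statistics table for one disorder.

    The reported effect is the true marginal (LD-convolved) liability-scale
    effect plus Gaussian noise with SE = 1/sqrt(2 p (1-p) n_gwas); p-values
    come from the Wald z statistic. The effect allele is the alt allele.
    """
    if n_gwas < 100:
        raise ValueError("n_gwas must be >= 100")
    if R is None:
        if ld_blocks is None:
            raise ValueError("supply either R or ld_blocks")
        R = dosage_correlation_matrix(variants, ld_blocks)
    rng = np.random.default_rng(seed)
    beta_true = model.marginal_effects(R, disorder)
    freqs = variants["alt_frequency"].to_numpy()
    se = 1.0 / np.sqrt(2 * freqs * (1 - freqs) * n_gwas)
    beta_hat = beta_true + se * rng.standard_normal(len(variants))
    z = beta_hat / se
    return pd.DataFrame(
        {
            "variant_id": variants["variant_id"],
            "chromosome": variants["chromosome"],
            "position": variants["position"],
            "effect_allele": variants["alt_allele"],
            "other_allele": variants["ref_allele"],
            "beta": beta_hat,
            "se": se,
            "p": 2 * stats.norm.sf(np.abs(z)),
            "frequency": freqs,
        }
    )


# ---------------------------------------------------------------------------
# subjects / covariates
# ---------------------------------------------------------------------------

def simulate_subjects(
    subject_ids: pd.Index | list[str],
    seed: int,
    ancestry_groups: tuple[str, ...] = ("EUR", "AFR"),
    ancestry_probs: tuple[float, ...] = (0.79, 0.21),
    male_fraction: float = 0.9,
    age_mean: float = 61.0,
    age_sd: float = 14.0,
) -> pd.DataFrame:
    """Covariate table: age, sex, ancestry group and six genetic PCs. PC1 is
    offset by ancestry group to mimic population structure; defaults mirror a
    predominantly male, older veteran cohort."""
    rng = np.random.default_rng(seed)
    n = len(subject_ids)
    grp = rng.choice(ancestry_groups, size=n, p=ancestry_probs)
    age = np.clip(rng.normal(age_mean, age_sd, n), 18, 95).round(1)
    sex = np.where(rng.random(n) < male_fraction, "male", "female")
    pcs = rng.standard_normal((n, 6)) * 0.02
    offsets = {g: i * 0.1 for i, g in enumerate(ancestry_groups)}
    pcs[:, 0] += np.vectorize(offsets.get)(grp)
    out = pd.DataFrame(
        {"subject_id": list(subject_ids), "age": age, "sex": sex, "ancestry_group": grp}
    )
    for j in range(6):
        out[f"pc{j + 1}"] = pcs[:, j]
    return out.set_index("subject_id")


# ---------------------------------------------------------------------------
# EHR coding process
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingModel:
    """Parameters of the synthetic EHR coding process.

    Per clinical encounter a true case emits a disorder-concordant billing
    code with probability ``sensitivity[d]``; schizophrenia and bipolar cases
    emit each other's codes at ``cross_coding``; non-cases emit psychiatric
    codes at ``background_psych_rate`` and everyone emits each non-psychiatric
    phecode's codes at a per-phecode rate. Dates are integer day offsets
    (only ordering matters downstream).
    """

    sensitivity: dict[str, float] = field(
        default_factory=lambda: {"SCZ": 0.45, "BIP": 0.45, "MDD": 0.45}
    )
    cross_coding: float = 0.11
    encounter_mean: float = 10.0
    encounter_min: int = 1
    inpatient_prob: float = 0.15
    severity_inpatient_slope: float = 0.10
    background_psych_rate: float = 0.002
    background_rate_range: tuple[float, float] = (0.005, 0.05)
    med_prob_case: float = 0.9
    med_prob_control: dict[str, float] = field(
        default_factory=lambda: {
            "antipsychotic": 0.05,
            "mood_stabilizer": 0.05,
            "antidepressant": 0.30,
        }
    )
    max_day: int = 3650

    def __post_init__(self):
        rates = [
            *self.sensitivity.values(), self.cross_coding, self.inpatient_prob,
            self.background_psych_rate, self.med_prob_case,
            *self.med_prob_control.values(),
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all coding-model rates must lie in [0, 1]")
        if self.encounter_mean < self.encounter_min:
            raise ValueError("encounter_mean must be >= encounter_min")
        if self.encounter_min < 0 or self.encounter_mean <= 0:
            raise ValueError("encounter distribution is empty")


def _icd_for_phecode(pmap: pd.DataFrame) -> dict[str, list[str]]:
    return {ph: grp["icd_code"].tolist() for ph, grp in pmap.groupby("phecode")}


def simulate_ehr_stream(
    truth: pd.DataFrame,
    coding: CodingModel,
    seed: int,
    phecode_map: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit CodeEventTable and PrescriptionTable for a DiagnosisTruth frame.

    Returns ``(events, prescriptions)``; events have columns subject_id,
    date (int day offset), icd_code, setting; prescriptions have subject_id,
    date, drug_class. Rows are sorted by subject then date.
    """
    pmap = load_phecode_map() if phecode_map is None else phecode_map
    icd_for = _icd_for_phecode(pmap)
    rng = np.random.default_rng(seed)
    subjects = truth.index.to_numpy()
    n = len(subjects)

    n_enc = coding.encounter_min + rng.poisson(
        coding.encounter_mean - coding.encounter_min, n
    )
    n_enc = np.maximum(n_enc, 1)
    subj_idx = np.repeat(np.arange(n), n_enc)
    dates = rng.integers(0, coding.max_day, size=subj_idx.size)
    # sort encounters within subject by date (stable on subject index)
    order = np.lexsort((dates, subj_idx))
    subj_idx, dates = subj_idx[order], dates[order]

    # per-subject inpatient probability grows with illness severity
    severity = np.zeros(n)
    for d in DISORDERS:
        liab = truth[f"liability_{d}"].to_numpy()
        case = truth[f"case_{d}"].to_numpy()
        excess = np.where(case, liab - stats.norm.ppf(1 - max(case.mean(), 1e-9)), 0.0)
        severity = np.maximum(severity, excess)
    p_inpt = np.clip(
        coding.inpatient_prob + coding.severity_inpatient_slope * severity, 0.0, 1.0
    )
    inpatient = rng.random(subj_idx.size) < p_inpt[subj_idx]

    ev_subj: list[np.ndarray] = []
    ev_date: list[np.ndarray] = []
    ev_phe: list[np.ndarray] = []
    ev_inpt: list[np.ndarray] = []

    def emit(mask: np.ndarray, family: str):
        if not mask.any():
            return
        codes = PSYCH_PHECODES[family]
        w = PSYCH_PHECODE_WEIGHTS[family]
        chosen = rng.choice(codes, size=int(mask.sum()), p=w)
        ev_subj.append(subj_idx[mask])
        ev_date.append(dates[mask])
        ev_phe.append(chosen)
        ev_inpt.append(inpatient[mask])

    cross_from = {"SCZ": "BIP", "BIP": "SCZ"}
    for d in DISORDERS:
        case = truth[f"case_{d}"].to_numpy()[subj_idx]
        hit = case & (rng.random(subj_idx.size) < coding.sensitivity[d])
        emit(hit, d)
        # background false positives among non-cases
        bg = (~case) & (rng.random(subj_idx.size) < coding.background_psych_rate)
        emit(bg, d)
    for src, dst in cross_from.items():
        case = truth[f"case_{src}"].to_numpy()[subj_idx]
        x = case & (rng.random(subj_idx.size) < coding.cross_coding)
        emit(x, dst)

    # background non-psychiatric codes, one stable rate per phecode
    psych = {p for fam in PSYCH_PHECODES.values() for p in fam}
    nonpsych = sorted(p for p in icd_for if p not in psych)
    rate_rng = np.random.default_rng(seed + 1)
    rates = rate_rng.uniform(*coding.background_rate_range, len(nonpsych))
    for phe, rate in zip(nonpsych, rates):
        mask = rng.random(subj_idx.size) < rate
        if mask.any():
            ev_subj.append(subj_idx[mask])
            ev_date.append(dates[mask])
            ev_phe.append(np.full(int(mask.sum()), phe, dtype=object))
            ev_inpt.append(inpatient[mask])

    if ev_subj:
        all_subj = np.concatenate(ev_subj)
        all_date = np.concatenate(ev_date)
        all_phe = np.concatenate(ev_phe)
        all_inpt = np.concatenate(ev_inpt)
    else:
        all_subj = np.array([], dtype=int)
        all_date = np.array([], dtype=int)
        all_phe = np.array([], dtype=object)
        all_inpt = np.array([], dtype=bool)

    icd = np.array(
        [icd_for[p][rng.integers(0, len(icd_for[p]))] for p in all_phe], dtype=object
    )
    events = pd.DataFrame(
        {
            "subject_id": subjects[all_subj],
            "date": all_date,
            "icd_code": icd,
            "setting": np.where(all_inpt, "inpatient", "outpatient"),
        }
    ).sort_values(["subject_id", "date"], kind="stable").reset_index(drop=True)

    # prescriptions: class-concordant for cases, background for controls
    rx_rows = []
    for d in DISORDERS:
        cls = DRUG_CLASS_FOR[d]
        case = truth[f"case_{d}"].to_numpy()
        gets = np.where(case, coding.med_prob_case, coding.med_prob_control[cls])
        got = rng.random(n) < gets
        days = rng.integers(0, coding.max_day, size=int(got.sum()))
        rx_rows.append(
            pd.DataFrame(
                {"subject_id": subjects[got], "date": days, "drug_class": cls}
            )
        )
    prescriptions = (
        pd.concat(rx_rows, ignore_index=True)
        .sort_values(["subject_id", "date"], kind="stable")
        .reset_index(drop=True)
    )
    logger.info(
        "simulated EHR stream (seed=%d): %d code events, %d prescriptions",
        seed, len(events), len(prescriptions),
    )
    return events, prescriptions


def hospitalization_counts(events: pd.DataFrame, subjects: pd.Index) -> pd.Series:
    """Number of distinct inpatient days per subject (proxy for number of
    hospitalizations)."""
    inpt = events[events["setting"] == "inpatient"]
    counts = inpt.groupby("subject_id")["date"].nunique()
    return counts.reindex(subjects, fill_value=0).astype(int)


# ---------------------------------------------------------------------------
# file interfaces
# ---------------------------------------------------------------------------

SUMSTATS_COLUMNS = ["CHR", "POS", "ID", "A1", "A2", "BETA", "SE", "P", "FRQ"]


def write_vcf(path: str, genotypes: pd.DataFrame, variants: pd.DataFrame) -> None:
    """Write dosages as a minimal biallelic VCF 4.2 with GT fields."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in variants["chromosome"].unique():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.index)
            + "\n"
        )
        G = genotypes.to_numpy()
        for j, row in enumerate(variants.itertuples(index=False)):
            gts = "\t".join(gt_map[int(g)] for g in G[:, j])
            fh.write(
                f"{row.chromosome}\t{row.position}\t{row.variant_id}\t"
                f"{row.ref_allele}\t{row.alt_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a biallelic VCF into (GenotypeMatrix, VariantTable) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    var_rows, dosages = [], []
    for rec in vcf:
        var_rows.append(
            {
                "variant_id": rec.ID,
                "chromosome": str(rec.CHROM),
                "position": int(rec.POS),
                "ref_allele": rec.REF,
                "alt_allele": rec.ALT[0],
            }
        )
        gts = rec.genotype.array()[:, :2]
        dosages.append((gts > 0).sum(axis=1))
    variants = pd.DataFrame(var_rows)
    geno = pd.DataFrame(
        np.column_stack(dosages) if dosages else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="subject_id"),
        columns=variants["variant_id"].to_numpy() if len(variants) else [],
    )
    variants["alt_frequency"] = geno.mean(axis=0).to_numpy() / 2 if len(variants) else []
    return geno, variants


def write_summary_stats(path: str, stats_table: pd.DataFrame) -> None:
    out = pd.DataFrame(
        {
            "CHR": stats_table["chromosome"],
            "POS": stats_table["position"],
            "ID": stats_table["variant_id"],
            "A1": stats_table["effect_allele"],
            "A2": stats_table["other_allele"],
            "BETA": stats_table["beta"],
            "SE": stats_table["se"],
            "P": stats_table["p"],
            "FRQ": stats_table["frequency"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = set(SUMSTATS_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"summary stats file missing columns: {sorted(missing)}")
    return raw.rename(
        columns={
            "CHR": "chromosome", "POS": "position", "ID": "variant_id",
            "A1": "effect_allele", "A2": "other_allele", "BETA": "beta",
            "SE": "se", "P": "p", "FRQ": "frequency",
        }
    )
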