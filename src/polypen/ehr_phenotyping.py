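"""EHR phenotyping: ICD -> phecode mapping, case/control/excluded assignment,
the prevailing-diagnosis rule for schizophrenia-vs-bipolar code conflicts, and
validation against gold-standard diagnoses.

Case definitions follow the billing-code convention for biobank phenotyping:
a subject is a case for a phenotype when they carry at least ``min_code_count``
relevant code events (optionally restricted to inpatient encounters), a
control when they carry zero relevant codes in any setting, and excluded
otherwise. Subjects with both schizophrenia- and bipolar-family codes are
resolved to a single prevailing diagnosis: the mode of their five most recent
relevant code entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import PSYCH_PHECODES, load_phecode_map

logger = logging.getLogger(__name__)

SCZ_PHECODES = frozenset(PSYCH_PHECODES["SCZ"])   # 295.1 / 295.2 / 295.3
BIP_PHECODES = frozenset(PSYCH_PHECODES["BIP"])   # 296.1
MDD_PHECODES = frozenset(PSYCH_PHECODES["MDD"])   # 296.2


@dataclass(frozen=True)
class CaseCriterion:
    """One EHR case definition: phenotype label, qualifying phecode set,
    minimum number of code events, optional inpatient restriction."""

    phenotype: str
    phecodes: frozenset[str]
    min_code_count: int = 2
    inpatient_required: bool = False

    def __post_init__(self):
        if self.min_code_count < 1:
            raise ValueError("min_code_count must be >= 1")
        if not self.phecodes:
            raise ValueError("criterion phecode set is empty")


def default_criteria() -> list[CaseCriterion]:
    """The standard grid of criteria: >=1 code, >=2 codes, and inpatient >=2
    for each of the three disorders (schizophrenia pools its spectrum codes)."""
    out = []
    for label, codes in (("SCZ", SCZ_PHECODES), ("BIP", BIP_PHECODES), ("MDD", MDD_PHECODES)):
        out.append(CaseCriterion(f"{label}_ge1", codes, min_code_count=1))
        out.append(CaseCriterion(f"{label}_ge2", codes, min_code_count=2))
        out.append(CaseCriterion(f"{label}_inpt", codes, min_code_count=2,
                                 inpatient_required=True))
    return out


def map_icd_to_phecode(
    events: pd.DataFrame, phecode_map: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Annotate each billing-code event with its phecode and disease category.

    Unmapped ICD codes are dropped from the returned table but counted in the
    report (and logged), never silently discarded.
    """
    pmap = load_phecode_map() if phecode_map is None else phecode_map
    lookup = pmap.drop_duplicates("icd_code").set_index("icd_code")[["phecode", "category"]]
    merged = events.join(lookup, on="icd_code")
    unmapped = merged["phecode"].isna()
    report = {
        "n_events": int(len(events)),
        "n_mapped": int((~unmapped).sum()),
        "n_unmapped": int(unmapped.sum()),
    }
    if report["n_unmapped"]:
        logger.warning(
            "%d of %d events carry ICD codes absent from the phecode map",
            report["n_unmapped"], report["n_events"],
        )
    return merged.loc[~unmapped].reset_index(drop=True), report


def phecode_counts(
    phecode_events: pd.DataFrame, phecodes: frozenset[str], inpatient_only: bool = False
) -> pd.Series:
    """Count qualifying code events per subject (each dated event counts)."""
    ev = phecode_events[phecode_events["phecode"].isin(phecodes)]
    if inpatient_only:
        ev = ev[ev["setting"] == "inpatient"]
    return ev.groupby("subject_id").size()


def assign_case_status(
    phecode_events: pd.DataFrame,
    criterion: CaseCriterion,
    subjects: pd.Index,
) -> pd.Series:
    """Resolve each subject to case / control / excluded under one criterion.

    case: qualifying events >= min_code_count (inpatient events only when the
    criterion requires inpatient status); control: zero relevant codes in any
    setting; excluded: anything in between — including subjects with only
    outpatient codes under an inpatient criterion, so that controls are always
    fully code-free.
    """
    any_counts = phecode_counts(phecode_events, criterion.phecodes).reindex(
        subjects, fill_value=0
    )
    if criterion.inpatient_required:
        qual = phecode_counts(
            phecode_events, criterion.phecodes, inpatient_only=True
        ).reindex(subjects, fill_value=0)
    else:
        qual = any_counts
    status = pd.Series("excluded", index=subjects, name=criterion.phenotype, dtype=object)
    status[qual >= criterion.min_code_count] = "case"
    status[any_counts == 0] = "control"
    return status


def prevailing_diagnosis(
    phecode_events: pd.DataFrame,
    scz_phecodes: frozenset[str] = SCZ_PHECODES,
    bip_phecodes: frozenset[str] = BIP_PHECODES,
) -> pd.Series:
    """Resolve subjects carrying both schizophrenia- and bipolar-family codes.

    For each such subject, take the (up to) five most recent relevant code
    entries by date and return the majority family. With fewer than five
    entries the mode of all available entries is used; a tie is broken by the
    family of the single most recent entry. Subjects with codes from only one
    family are not returned (their assignment is unambiguous).
    """
    relevant = phecode_events[
        phecode_events["phecode"].isin(scz_phecodes | bip_phecodes)
    ].copy()
    relevant["family"] = np.where(
        relevant["phecode"].isin(scz_phecodes), "SCZ", "BIP"
    )
    out = {}
    for subj, grp in relevant.groupby("subject_id"):
        fams = set(grp["family"])
        if len(fams) < 2:
            continue
        recent = grp.sort_values("date", kind="stable").tail(5)
        n_scz = int((recent["family"] == "SCZ").sum())
        n_bip = len(recent) - n_scz
        if n_scz != n_bip:
            out[subj] = "SCZ" if n_scz > n_bip else "BIP"
        else:
            out[subj] = recent["family"].iloc[-1]
    return pd.Series(out, name="prevailing", dtype=object)


def misclassification_report(
    phecode_events: pd.DataFrame,
    truth: pd.DataFrame,
    min_code_count: int = 2,
) -> pd.DataFrame:
    """Schizophrenia<->bipolar cross-coding before and after prevailing-
    diagnosis resolution.

    ``before``: fraction of true cases of one disorder carrying
    >= min_code_count codes of the *other* disorder's family. ``after``:
    fraction of true cases whose final assignment (prevailing diagnosis for
    dual-coded subjects, otherwise their own qualifying family) is the wrong
    family.
    """
    counts = {
        "SCZ": phecode_counts(phecode_events, SCZ_PHECODES),
        "BIP": phecode_counts(phecode_events, BIP_PHECODES),
    }
    prevailing = prevailing_diagnosis(phecode_events)
    rows = []
    for disorder, other in (("SCZ", "BIP"), ("BIP", "SCZ")):
        true_cases = truth.index[truth[f"case_{disorder}"]]
        own = counts[disorder].reindex(true_cases, fill_value=0)
        cross = counts[other].reindex(true_cases, fill_value=0)
        before = float((cross >= min_code_count).mean())
        assigned = pd.Series("none", index=true_cases, dtype=object)
        assigned[cross >= min_code_count] = other
        assigned[own >= min_code_count] = disorder
        # dual-coded subjects take the prevailing diagnosis instead
        dual = true_cases[((own >= 1) & (cross >= 1)).to_numpy()]
        resolved = prevailing.reindex(dual).dropna()
        assigned.loc[resolved.index] = resolved
        after = float((assigned == other).mean())
        rows.append(
            {
                "disorder": disorder,
                "n_true_cases": int(len(true_cases)),
                "multiple_coding_rate": before,
                "misclassified_after_resolution": after,
            }
        )
    return pd.DataFrame(rows).set_index("disorder")


def validate_against_gold(
    status: pd.Series, truth_case: pd.Series
) -> dict[str, float | dict]:
    """Sensitivity / specificity of an EHR case definition against gold truth.

    Sensitivity = detected cases / true cases (excluded subjects count as not
    detected); specificity = labelled controls / true non-cases. Confusion
    counts cover every overlapping subject, so they sum to the gold totals.
    """
    common = status.index.intersection(truth_case.index)
    if not len(common):
        raise ValueError("no subject overlap between status and gold standard")
    s, t = status.loc[common], truth_case.loc[common].astype(bool)
    confusion = {
        "true_case": {
            lab: int(((s == lab) & t).sum()) for lab in ("case", "control", "excluded")
        },
        "true_noncase": {
            lab: int(((s == lab) & ~t).sum()) for lab in ("case", "control", "excluded")
        },
    }
    n_cases, n_non = int(t.sum()), int((~t).sum())
    if n_cases == 0:
        logger.warning("no true cases in overlap; sensitivity undefined")
        sens = float("nan")
    else:
        sens = confusion["true_case"]["case"] / n_cases
    spec = confusion["true_noncase"]["control"] / n_non if n_non else float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "n_true_cases": n_cases,
        "n_true_noncases": n_non,
        "confusion": confusion,
    }


def split_half_roc(
    phecode_events: pd.DataFrame,
    truth: pd.DataFrame,
    criteria: list[CaseCriterion],
    truth_column_for: dict[str, str],
    n_repeats: int = 20,
    seed: int = 0,
    max_resample: int = 100,
) -> pd.DataFrame:
    """Split-half cross-validation of EHR case criteria.

    Subjects are randomly halved (stratified by the criterion's true
    diagnosis); sensitivity and specificity are estimated on each half. The
    returned frame gives mean / min / max across repeats per criterion, plus
    the 50/50 random-prediction reference value 0.5.
    """
    rng = np.random.default_rng(seed)
    subjects = truth.index
    rows = []
    for crit in criteria:
        tcol = truth_column_for[crit.phenotype]
        t = truth[tcol].astype(bool)
        if t.sum() < 2 or (~t).sum() < 2:
            raise ValueError(f"need >=2 subjects per truth class for {crit.phenotype}")
        status = assign_case_status(phecode_events, crit, subjects)
        sens_list, spec_list = [], []
        for _ in range(n_repeats):
            for _try in range(max_resample):
                half = np.zeros(len(subjects), dtype=bool)
                for cls in (True, False):
                    idx = np.flatnonzero(t.to_numpy() == cls)
                    take = rng.permutation(idx)[: len(idx) // 2]
                    half[take] = True
                ok = True
                for mask in (half, ~half):
                    sub = t[mask]
                    if sub.sum() == 0 or (~sub).sum() == 0:
                        ok = False
                if ok:
                    break
                logger.info("split lacked a truth class; resampling")
            for mask in (half, ~half):
                rep = validate_against_gold(status[mask], t[mask])
                sens_list.append(rep["sensitivity"])
                spec_list.append(rep["specificity"])
        rows.append(
            {
                "criterion": crit.phenotype,
                "min_code_count": crit.min_code_count,
                "inpatient_required": crit.inpatient_required,
                "sensitivity_mean": float(np.mean(sens_list)),
                "sensitivity_min": float(np.min(sens_list)),
                "sensitivity_max": float(np.max(sens_list)),
                "specificity_mean": float(np.mean(spec_list)),
                "specificity_min": float(np.min(spec_list)),
                "specificity_max": float(np.max(spec_list)),
                "random_reference": 0.5,
            }
        )
    return pd.DataFrame(rows).set_index("criterion")
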