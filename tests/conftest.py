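"""Shared fixtures: one small simulated cohort reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polypen import synthetic_cohort as sc


@pytest.fixture(scope="session")
def ld_spec():
    return sc.LDBlockSpec(sizes=(6,) * 8, correlations=(0.8, 0.4, 0.0, 0.6) * 2)


@pytest.fixture(scope="session")
def variants(ld_spec):
    return sc.make_variant_table(ld_spec.n_variants, seed=7)


@pytest.fixture(scope="session")
def cohort(ld_spec, variants):
    """A 4000-subject cohort with genotypes, ground-truth diagnoses, EHR
    stream, covariates and one disorder's summary statistics."""
    geno = sc.simulate_genotypes(4000, variants, ld_spec, seed=1)
    model, R = sc.make_liability_model(variants, ld_spec, seed=2)
    truth = sc.simulate_liability_phenotypes(geno, variants, model, seed=3)
    events, rx = sc.simulate_ehr_stream(truth, sc.CodingModel(), seed=6)
    subjects = sc.simulate_subjects(geno.index, seed=5)
    sumstats = sc.simulate_summary_stats(
        model, variants, n_gwas=100_000, seed=4, disorder="SCZ", R=R
    )
    return {
        "genotypes": geno,
        "variants": variants,
        "model": model,
        "R": R,
        "truth": truth,
        "events": events,
        "prescriptions": rx,
        "subjects": subjects,
        "sumstats": sumstats,
    }


@pytest.fixture(scope="session")
def phecode_events(cohort):
    from polypen import ehr_phenotyping as ep

    pev, _ = ep.map_icd_to_phecode(cohort["events"])
    return pev


def manual_truth(case_flags: dict[str, np.ndarray], subject_ids=None) -> pd.DataFrame:
    """Build a DiagnosisTruth frame directly from boolean case flags (for
    coding-process tests that need full control over who is a case)."""
    n = len(next(iter(case_flags.values())))
    if subject_ids is None:
        subject_ids = [f"T{i:05d}" for i in range(n)]
    out = pd.DataFrame({"subject_id": subject_ids}).set_index("subject_id")
    out["factor"] = 0.0
    for d in sc.DISORDERS:
        flags = np.asarray(case_flags.get(d, np.zeros(n, dtype=bool)))
        out[f"liability_{d}"] = np.where(flags, 3.0, -1.0)
        out[f"case_{d}"] = flags
    return out
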