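import pytest

from oncoact import (
    SimConfig,
    assess_patient,
    classify_alterations,
    compute_cohort_tmb,
    default_pathways,
    filter_variants,
    generate,
    is_vus,
)


def pipeline_products(cohort):
    """Run filter -> classify -> assess -> TMB in memory."""
    retained, report = filter_variants(cohort.variants)
    qualified = classify_alterations(retained, cohort.cnvs)
    relevant = [a for a in qualified if not is_vus(a)]
    by_patient = {pid: [] for pid in cohort.patient_ids()}
    for a in relevant:
        by_patient[a.patient_id].append(a)
    specs = default_pathways()
    calls = []
    for pid in cohort.patient_ids():
        calls.extend(assess_patient(by_patient[pid], specs, pid))
    tmb_results = compute_cohort_tmb(cohort, retained)
    return {
        "retained": retained,
        "filter_report": report,
        "qualified": qualified,
        "relevant": relevant,
        "calls": calls,
        "tmb": tmb_results,
        "specs": specs,
    }


@pytest.fixture(scope="session")
def study_cohort():
    """Default synthetic cohort at the study sizes (37/22/23), seed 42."""
    return generate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def study_results(study_cohort):
    return pipeline_products(study_cohort)


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort (2000 per subtype) for frequency-recovery checks."""
    return generate(
        SimConfig(
            seed=123,
            n_per_subtype={"HGS": 2000, "ENDOMETRIOID": 2000, "CLEAR_CELL": 2000},
        )
    )


@pytest.fixture(scope="session")
def big_results(big_cohort):
    return pipeline_products(big_cohort)
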