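import pytest

from oncoact import (
    DRUG_TARGETS,
    CopyNumberCall,
    VariantCall,
    assess_parp,
    assess_patient,
    assess_target,
    classify_alterations,
    default_pathways,
    default_roles,
    is_vus,
)
from oncoact.pathways import PathwayConfigError, load_pathways


@pytest.fixture(scope="module")
def specs():
    return default_pathways()


@pytest.fixture(scope="module")
def by_target(specs):
    return {t: s for s in specs for t in s.drug_targets}


def alterations(*calls):
    """Qualify a mixture of shorthand (gene, kind) pairs for patient P1."""
    variants, cnvs = [], []
    for gene, kind in calls:
        if kind == "gain":
            cnvs.append(CopyNumberCall("P1", gene, 5.0))
        elif kind == "loss":
            cnvs.append(CopyNumberCall("P1", gene, 1.0))
        elif kind == "trunc":
            variants.append(VariantCall("P1", gene, "nonsense", "R100*", 40.0))
        elif kind == "oncogenic":
            variants.append(
                VariantCall("P1", gene, "missense", "A100V", 40.0,
                            oncokb_class="oncogenic")
            )
        elif kind == "acmg":
            variants.append(
                VariantCall("P1", gene, "frameshift", "Q100fs", 40.0,
                            acmg_class="pathogenic")
            )
        elif kind == "vus":
            variants.append(VariantCall("P1", gene, "missense", "A100V", 40.0))
    qualified = classify_alterations(variants, cnvs, default_roles())
    return [a for a in qualified if not is_vus(a)]


def test_topology_loads_and_validates(specs):
    assert len(specs) == 6
    targets = [t for s in specs for t in s.drug_targets]
    assert sorted(targets) == sorted(DRUG_TARGETS)
    genes = {g for s in specs for g in s.genes}
    assert len(genes) == 54
    for s in specs:
        for t in s.drug_targets:
            assert not (s.upstream_of[t] & s.downstream_of[t])


def test_parp_brca1(by_target):
    call = assess_parp(alterations(("BRCA1", "acmg")), by_target["PARP"])
    assert call.verdict == "actionable"
    assert [a.gene for a in call.sensitizing] == ["BRCA1"]
    assert call.negating == []


def test_parp_no_evidence(by_target):
    call = assess_parp([], by_target["PARP"])
    assert call.verdict == "no_evidence"
    assert call.sensitizing == [] and call.negating == []


def test_parp_multiple_sensitizers(by_target):
    call = assess_parp(
        alterations(("ARID1A", "trunc"), ("PTEN", "loss")), by_target["PARP"]
    )
    assert call.verdict == "actionable"
    assert sorted(a.gene for a in call.sensitizing) == ["ARID1A", "PTEN"]


def test_parp_cannot_be_impaired(by_target):
    # synthetic lethality: downstream negation does not exist for PARP
    alts = alterations(("BRCA1", "acmg"), ("PIK3CA", "oncogenic"),
                       ("KRAS", "oncogenic"), ("CCNE1", "gain"))
    assert assess_parp(alts, by_target["PARP"]).verdict == "actionable"


def test_pten_invisible_to_pik3ca_target(by_target):
    call = assess_target("PIK3CA", alterations(("PTEN", "loss")),
                         by_target["PIK3CA"])
    assert call.verdict == "no_evidence"
    assert call.sensitizing == [] and call.negating == []


def test_pten_sensitizes_akt1_and_mtor(by_target):
    alts = alterations(("PTEN", "loss"))
    assert assess_target("AKT1", alts, by_target["AKT1"]).verdict == "actionable"
    assert assess_target("MTOR", alts, by_target["MTOR"]).verdict == "actionable"


def test_downstream_akt_gain_impairs_pik3ca(by_target):
    alts = alterations(("PIK3CA", "oncogenic"), ("AKT1", "gain"))
    assert assess_target("PIK3CA", alts, by_target["PIK3CA"]).verdict == "impaired"
    assert assess_target("AKT1", alts, by_target["AKT1"]).verdict == "actionable"
    assert assess_target("MTOR", alts, by_target["MTOR"]).verdict == "actionable"


def test_rb1_loss_impairs_cdk4_6(by_target):
    alts = alterations(("CCND1", "gain"), ("RB1", "loss"))
    call = assess_target("CDK4_6", alts, by_target["CDK4_6"])
    assert call.verdict == "impaired"
    assert [a.gene for a in call.negating] == ["RB1"]


def test_ccne1_gain_impairs_cdk4_6(by_target):
    alts = alterations(("CDKN2A", "loss"), ("CCNE1", "gain"))
    assert assess_target("CDK4_6", alts, by_target["CDK4_6"]).verdict == "impaired"


def test_kras_mutation_cascade(specs):
    calls = {c.drug_target: c for c in assess_patient(
        alterations(("KRAS", "oncogenic")), specs, "P1")}
    assert calls["KRAS"].verdict == "actionable"
    assert calls["MEK1_2"].verdict == "actionable"
    assert calls["PIK3CA"].verdict == "no_evidence"
    assert calls["AKT1"].verdict == "no_evidence"


def test_nf1_loss_sensitizes_kras_and_mek(specs):
    calls = {c.drug_target: c for c in assess_patient(
        alterations(("NF1", "trunc")), specs, "P1")}
    assert calls["KRAS"].verdict == "actionable"
    assert calls["MEK1_2"].verdict == "actionable"


def test_mek_alteration_negates_kras_but_sensitizes_itself(specs):
    calls = {c.drug_target: c for c in assess_patient(
        alterations(("MAP2K1", "gain")), specs, "P1")}
    assert calls["KRAS"].verdict == "impaired"
    assert calls["MEK1_2"].verdict == "actionable"


def test_rtk_target_negated_by_downstream_pathway(specs):
    calls = {c.drug_target: c for c in assess_patient(
        alterations(("ERBB2", "gain"), ("PIK3CA", "oncogenic")), specs, "P1")}
    assert calls["ERBB2"].verdict == "impaired"
    assert calls["PIK3CA"].verdict == "actionable"


def test_zero_alterations_gives_14_no_evidence(specs):
    calls = assess_patient([], specs, "P0")
    assert len(calls) == 14
    assert all(c.verdict == "no_evidence" for c in calls)
    assert all(c.patient_id == "P0" for c in calls)


def test_vus_never_contribute(specs):
    calls = assess_patient(alterations(("PIK3CA", "vus")), specs, "P1")
    assert all(c.verdict == "no_evidence" for c in calls)


def test_unknown_target_rejected(by_target):
    with pytest.raises(PathwayConfigError):
        assess_target("PARP", [], by_target["SMO"])


def test_fourteen_calls_per_patient(study_cohort, study_results):
    calls = study_results["calls"]
    assert len(calls) == 14 * len(study_cohort.patients)
    per_patient = {}
    for c in calls:
        per_patient.setdefault(c.patient_id, []).append(c.drug_target)
    for targets in per_patient.values():
        assert sorted(targets) == sorted(DRUG_TARGETS)


def test_verdict_structural_invariants(study_results):
    for c in study_results["calls"]:
        if c.verdict == "actionable":
            assert c.sensitizing and not c.negating
        elif c.verdict == "impaired":
            assert c.negating
        else:
            assert not c.sensitizing and not c.negating


def test_missing_exception_rejected(tmp_path):
    bad = tmp_path / "p.yaml"
    bad.write_text(
        "pathways:\n"
        "  HEDGEHOG:\n"
        "    genes: [PTCH1, SMO, STK36, SUFU]\n"
        "    targets:\n"
        "      SMO:\n"
        "        upstream: [PTCH1, SMO]\n"
        "        downstream: [SUFU, STK36]\n"
        "exceptions: []\n"
    )
    with pytest.raises(PathwayConfigError, match="PTEN"):
        load_pathways(bad)


def test_overlapping_upstream_downstream_rejected(tmp_path):
    bad = tmp_path / "p.yaml"
    bad.write_text(
        "pathways:\n"
        "  HEDGEHOG:\n"
        "    genes: [PTCH1, SMO, STK36, SUFU]\n"
        "    targets:\n"
        "      SMO:\n"
        "        upstream: [PTCH1, SMO, SUFU]\n"
        "        downstream: [SUFU, STK36]\n"
        "exceptions:\n"
        "  - {target: PIK3CA, gene: PTEN}\n"
    )
    with pytest.raises(PathwayConfigError, match="overlap"):
        load_pathways(bad)
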