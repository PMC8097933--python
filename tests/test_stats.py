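import numpy as np
import pytest

from oncoact import (
    Cohort,
    CopyNumberCall,
    Patient,
    VariantCall,
    alteration_frequency,
    chi_square,
    classify_alterations,
    is_vus,
    overlap_summary,
    tmb_split,
)
from oncoact.pathways import ActionabilityCall, default_pathways
from oncoact.stats import DegenerateTableError, oncoprint_matrix, pct_round
from oncoact.tmb import TmbResult


def pearson_brute_force(table):
    """Independent oracle: sum over cells of (O - E)^2 / E."""
    t = np.asarray(table, dtype=float)
    row, col, n = t.sum(axis=1), t.sum(axis=0), t.sum()
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = row[i] * col[j] / n
            stat += (t[i, j] - e) ** 2 / e
    return stat


def test_brca_table_significant():
    # BRCA1/2-altered vs not, by histological subtype
    res = chi_square([[11, 26], [0, 22], [0, 23]])
    assert res.dof == 2
    assert res.p_value < 0.001


def test_uniform_table_null():
    res = chi_square([[5, 5], [5, 5]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_statistic_matches_brute_force():
    table = [[6, 16], [1, 21], [1, 22]]
    res = chi_square(table)
    assert res.statistic == pytest.approx(pearson_brute_force(table), rel=1e-12)
    assert res.low_expected_counts  # several expected cells < 5


def test_random_tables_match_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(30):
        shape = rng.integers(2, 5, size=2)
        table = rng.integers(1, 40, size=shape)
        res = chi_square(table)
        assert res.statistic == pytest.approx(
            pearson_brute_force(table), rel=1e-9
        )
        assert res.dof == (shape[0] - 1) * (shape[1] - 1)


def test_degenerate_table_rejected():
    with pytest.raises(DegenerateTableError):
        chi_square([[0, 0], [5, 3]])
    with pytest.raises(DegenerateTableError):
        chi_square([[0, 5], [0, 3]])


def test_non_integer_rejected():
    with pytest.raises(ValueError):
        chi_square([[1.5, 2], [3, 4]])


@pytest.mark.parametrize(
    "count, denom, expected", [(11, 37, 30), (1, 37, 3), (0, 22, 0), (1, 2, 50),
                               (21, 37, 57), (0, 0, 0)]
)
def test_percent_rounding_half_up(count, denom, expected):
    assert pct_round(count, denom) == expected


@pytest.fixture()
def tiny_cohort():
    return Cohort(
        patients=[
            Patient("H1", "HGS", 80.0), Patient("H2", "HGS", 70.0),
            Patient("E1", "ENDOMETRIOID", 60.0),
            Patient("C1", "CLEAR_CELL", 50.0),
        ]
    )


def test_patient_counts_once_per_stratum(tiny_cohort):
    variants = [
        VariantCall("H1", "BRCA1", "frameshift", "Q1fs", 40.0,
                    acmg_class="pathogenic"),
        VariantCall("H1", "BRCA2", "nonsense", "R2*", 40.0,
                    acmg_class="pathogenic"),
    ]
    qualified = classify_alterations(variants, [])
    freq = alteration_frequency(tiny_cohort, qualified, {"BRCA1", "BRCA2"},
                                "BRCA1/2")
    assert freq.counts == {"HGS": 1, "ENDOMETRIOID": 0, "CLEAR_CELL": 0}
    assert freq.denominators == {"HGS": 2, "ENDOMETRIOID": 1, "CLEAR_CELL": 1}
    assert freq.percents["HGS"] == 50


def test_vus_excluded_from_frequencies(tiny_cohort):
    variants = [VariantCall("H1", "PIK3CA", "missense", "A1V", 40.0)]  # VUS
    qualified = classify_alterations(variants, [])
    assert all(is_vus(a) for a in qualified)
    with pytest.warns(UserWarning):
        freq = alteration_frequency(tiny_cohort, qualified, "PIK3CA")
    assert sum(freq.counts.values()) == 0


def test_tmb_split(tiny_cohort):
    results = [
        TmbResult("H1", 25, 20.0, True),
        TmbResult("H2", 10, 8.0, False),
        TmbResult("E1", 24, 19.2, True),
        TmbResult("C1", 4, 3.2, False),
    ]
    split = tmb_split(results, tiny_cohort, 18.0)
    assert split.counts == {"HGS": 1, "ENDOMETRIOID": 1, "CLEAR_CELL": 0}
    assert split.percents == {"HGS": 50, "ENDOMETRIOID": 100, "CLEAR_CELL": 0}


def test_overlap_summary_logic(tiny_cohort):
    specs = default_pathways()
    # H1: ERBB2-gain patient actionable for ERBB2 only -> denominator only;
    # H2: MTOR + MEK1_2 actionable -> numerator.
    qualified = classify_alterations(
        [VariantCall("H2", "KRAS", "missense", "G12D", 40.0,
                     oncokb_class="oncogenic"),
         VariantCall("H2", "PIK3CA", "missense", "H1047R", 40.0,
                     oncokb_class="oncogenic")],
        [CopyNumberCall("H1", "ERBB2", 5.0)],
    )
    calls = [
        ActionabilityCall("H1", "ERBB2", "actionable",
                          sensitizing=[qualified[-1]]),
        ActionabilityCall("H2", "MTOR", "actionable",
                          sensitizing=[qualified[1]]),
        ActionabilityCall("H2", "MEK1_2", "actionable",
                          sensitizing=[qualified[0]]),
    ]
    ov = overlap_summary(calls, qualified, tiny_cohort, specs)
    assert ov.denominators == {"HGS": 2, "ENDOMETRIOID": 0, "CLEAR_CELL": 0}
    assert ov.counts == {"HGS": 1, "ENDOMETRIOID": 0, "CLEAR_CELL": 0}


def test_oncoprint_matrix_codes(tiny_cohort):
    qualified = classify_alterations(
        [VariantCall("H1", "BRCA1", "frameshift", "Q1fs", 40.0,
                     acmg_class="pathogenic"),
         VariantCall("E1", "PTEN", "nonsense", "R130*", 40.0)],
        [CopyNumberCall("H1", "CCND1", 6.0), CopyNumberCall("H2", "PTEN", 1.0)],
    )
    m = oncoprint_matrix(tiny_cohort, qualified)
    assert m.loc["H1", "BRCA1"] == "mut"
    assert m.loc["H1", "CCND1"] == "gain"
    assert m.loc["H2", "PTEN"] == "loss"
    assert m.loc["E1", "PTEN"] == "mut"
    assert m.loc["C1", "BRCA1"] == ""


def test_count_cannot_exceed_denominator():
    from oncoact.stats import SubtypeFrequency

    with pytest.raises(ValueError):
        SubtypeFrequency("x", counts={"HGS": 5}, denominators={"HGS": 3})
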