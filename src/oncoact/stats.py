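"""Histology-stratified cohort summaries and contingency statistics.

Counting conventions: a patient counts once per stratum (gene, gene set, or
drug target) no matter how many qualifying alterations they carry;
denominators are the subtype sizes; VUS never enter any count.  Reported
percentages are rounded half-up to the nearest integer; full precision is
kept internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import QualifiedAlteration, is_vus
from .cohort import HISTOLOGIES, Cohort
from .pathways import ActionabilityCall, PathwaySpec, RTK_TARGETS
from .tmb import TmbResult

__all__ = [
    "SubtypeFrequency",
    "ChiSquareResult",
    "DegenerateTableError",
    "pct_round",
    "alteration_frequency",
    "actionability_frequency",
    "chi_square",
    "overlap_summary",
    "tmb_split",
    "oncoprint_matrix",
]


def pct_round(count: int, denominator: int) -> int:
    """Percent rounded half-up (reports print integer percents)."""
    if denominator == 0:
        return 0
    return int(math.floor(100.0 * count / denominator + 0.5))


@dataclass
class SubtypeFrequency:
    label: str
    counts: dict[str, int]
    denominators: dict[str, int]

    def __post_init__(self) -> None:
        for h, c in self.counts.items():
            if c > self.denominators.get(h, 0):
                raise ValueError(
                    f"{self.label}/{h}: count {c} exceeds denominator "
                    f"{self.denominators.get(h)}"
                )

    def fraction(self, histology: str) -> float:
        d = self.denominators[histology]
        return self.counts[histology] / d if d else 0.0

    @property
    def percents(self) -> dict[str, int]:
        return {
            h: pct_round(self.counts[h], self.denominators[h])
            for h in self.counts
        }


@dataclass
class ChiSquareResult:
    table: np.ndarray
    statistic: float
    dof: int
    p_value: float
    low_expected_counts: bool = False  # any expected cell < 5


class DegenerateTableError(ValueError):
    """A contingency table with an all-zero row or column."""


def _patients_by_histology(cohort: Cohort) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {h: set() for h in HISTOLOGIES}
    for p in cohort.patients:
        out[p.histology].add(p.patient_id)
    return out


def alteration_frequency(
    cohort: Cohort,
    qualified_alterations: list[QualifiedAlteration],
    gene_or_gene_set: str | set[str] | tuple[str, ...],
    label: str | None = None,
) -> SubtypeFrequency:
    """Per-subtype fraction of patients with >=1 qualified alteration in the
    gene or gene set."""
    genes = (
        {gene_or_gene_set.upper()}
        if isinstance(gene_or_gene_set, str)
        else {g.upper() for g in gene_or_gene_set}
    )
    label = label or "/".join(sorted(genes))
    hits = {
        a.patient_id
        for a in qualified_alterations
        if not is_vus(a) and a.gene in genes
    }
    known_genes = {a.gene for a in qualified_alterations if not is_vus(a)}
    if not genes & known_genes:
        warnings.warn(
            f"no alterations observed in stratum {label!r}", stacklevel=2
        )
    strata = _patients_by_histology(cohort)
    return SubtypeFrequency(
        label=label,
        counts={h: len(hits & ids) for h, ids in strata.items()},
        denominators={h: len(ids) for h, ids in strata.items()},
    )


def actionability_frequency(
    actionability_calls: list[ActionabilityCall],
    cohort: Cohort,
) -> dict[str, SubtypeFrequency]:
    """Per-target, per-subtype percent of patients with verdict=actionable."""
    strata = _patients_by_histology(cohort)
    targets = list(dict.fromkeys(c.drug_target for c in actionability_calls))
    out: dict[str, SubtypeFrequency] = {}
    for t in targets:
        hits = {
            c.patient_id
            for c in actionability_calls
            if c.drug_target == t and c.verdict == "actionable"
        }
        out[t] = SubtypeFrequency(
            label=t,
            counts={h: len(hits & ids) for h, ids in strata.items()},
            denominators={h: len(ids) for h, ids in strata.items()},
        )
    return out


def chi_square(table) -> ChiSquareResult:
    """Pearson chi-square on an r x c count table, no continuity correction.

    Expected counts below 5 are flagged, not corrected: the comparison of
    patient proportions is a plain chi-square test.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table must contain non-negative integers")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise DegenerateTableError("table has an all-zero row or column")
    stat, p, dof, expected = sps.chi2_contingency(arr, correction=False)
    return ChiSquareResult(
        table=arr.astype(int),
        statistic=float(stat),
        dof=int(dof),
        p_value=float(p),
        low_expected_counts=bool((expected < 5).any()),
    )


def _pathway_gene_sets(specs: list[PathwaySpec]) -> dict[str, set[str]]:
    return {s.name: set(s.genes) for s in specs}


def overlap_summary(
    actionability_calls: list[ActionabilityCall],
    qualified_alterations: list[QualifiedAlteration],
    cohort: Cohort,
    specs: list[PathwaySpec],
    label: str = "RTK_pathway_overlap",
) -> SubtypeFrequency:
    """Overlap of actionability across the RTK-related pathways.

    Denominator: patients carrying >=1 qualified alteration in any gene of
    the RTK, PI3K/AKT/MTOR, or RAS/MAPK pathways.  Numerator: those with
    actionable verdicts for at least two of {any RTK target, MTOR, MEK1_2} —
    candidates for combined inhibition of a receptor and a downstream node.
    """
    gene_sets = _pathway_gene_sets(specs)
    rtk_related = (
        gene_sets.get("RTK", set())
        | gene_sets.get("PI3K_AKT_MTOR", set())
        | gene_sets.get("RAS_MAPK", set())
    )
    denom_patients = {
        a.patient_id
        for a in qualified_alterations
        if not is_vus(a) and a.gene in rtk_related
    }
    actionable: dict[str, set[str]] = {}
    for c in actionability_calls:
        if c.verdict == "actionable":
            actionable.setdefault(c.patient_id, set()).add(c.drug_target)
    numer_patients = set()
    for pid in denom_patients:
        targets = actionable.get(pid, set())
        groups = 0
        if targets & set(RTK_TARGETS):
            groups += 1
        if "MTOR" in targets:
            groups += 1
        if "MEK1_2" in targets:
            groups += 1
        if groups >= 2:
            numer_patients.add(pid)
    strata = _patients_by_histology(cohort)
    return SubtypeFrequency(
        label=label,
        counts={h: len(numer_patients & ids) for h, ids in strata.items()},
        denominators={h: len(denom_patients & ids) for h, ids in strata.items()},
    )


def tmb_split(
    tmb_results: list[TmbResult],
    cohort: Cohort,
    threshold: float = 18.0,
) -> SubtypeFrequency:
    """Per-subtype percent of patients whose TMB strictly exceeds threshold."""
    high = {r.patient_id for r in tmb_results if r.tmb > threshold}
    strata = _patients_by_histology(cohort)
    return SubtypeFrequency(
        label=f"TMB>{threshold:g}",
        counts={h: len(high & ids) for h, ids in strata.items()},
        denominators={h: len(ids) for h, ids in strata.items()},
    )


_EVIDENCE_CODE = {
    "cn_gain": "gain",
    "cn_loss": "loss",
    "truncating_or_splice": "mut",
    "oncokb_oncogenic": "mut",
    "acmg_pathogenic": "mut",
}


def oncoprint_matrix(
    cohort: Cohort,
    qualified_alterations: list[QualifiedAlteration],
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Patients x genes matrix of alteration-type codes.

    Cells hold ``mut``, ``gain``, ``loss``, combinations joined by ``;``
    (deterministic order), or ``""``.  CNV evidence codes as gain/loss; all
    qualifying variant evidence codes as mut.  VUS are excluded.
    """
    if genes is None:
        genes = sorted({a.gene for a in qualified_alterations if not is_vus(a)})
    cells: dict[tuple[str, str], set[str]] = {}
    for a in qualified_alterations:
        if is_vus(a) or a.gene not in genes:
            continue
        code = _EVIDENCE_CODE[a.evidence]
        cells.setdefault((a.patient_id, a.gene), set()).add(code)
    order = ["mut", "gain", "loss"]
    data = {
        g: [
            ";".join(
                sorted(cells.get((pid, g), set()), key=order.index)
            )
            for pid in cohort.patient_ids()
        ]
        for g in genes
    }
    return pd.DataFrame(data, index=pd.Index(cohort.patient_ids(), name="patient_id"))
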