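"""Panel tumor mutational burden (TMB).

TMB is the number of detected mutations after filtering (VAF >= 10%,
non-polymorphic) divided by the number of analyzed base pairs of the panel,
1.247752 Mb by default.  The count is of detected small variants — VUS
included, copy-number calls never.  A patient is high-TMB when TMB strictly
exceeds the threshold (18 Mut/Mb by default).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import Cohort, VariantCall

__all__ = ["TmbConfig", "TmbResult", "compute_tmb", "compute_cohort_tmb"]


@dataclass
class TmbConfig:
    panel_size_mb: float = 1.247752
    high_tmb_threshold: float = 18.0  # Mut/Mb

    def __post_init__(self) -> None:
        if self.panel_size_mb <= 0:
            raise ValueError("panel_size_mb must be positive")
        if self.high_tmb_threshold <= 0:
            raise ValueError("high_tmb_threshold must be positive")


@dataclass
class TmbResult:
    patient_id: str
    n_mutations: int
    tmb: float  # Mut/Mb
    high_tmb: bool


def _dedupe(variants: list[VariantCall]) -> list[VariantCall]:
    # Variants assayed by both panels (BRCA1/2 overlap the comprehensive
    # panel) must count once; identity is (gene, protein_change).
    seen: set[tuple[str, str]] = set()
    out = []
    for v in variants:
        key = (v.gene, v.protein_change)
        if key in seen:
            continue
        seen.add(key)
        out.append(v)
    return out


def compute_tmb(
    variants: list[VariantCall],
    config: TmbConfig | None = None,
    patient_id: str | None = None,
) -> TmbResult:
    """TMB for one patient's post-filter variants."""
    config = config or TmbConfig()
    if patient_id is None:
        patient_id = variants[0].patient_id if variants else ""
    n = len(_dedupe(variants))
    tmb = n / config.panel_size_mb
    return TmbResult(
        patient_id=patient_id,
        n_mutations=n,
        tmb=tmb,
        high_tmb=tmb > config.high_tmb_threshold,
    )


def compute_cohort_tmb(
    cohort: Cohort,
    filtered_variants: list[VariantCall],
    config: TmbConfig | None = None,
) -> list[TmbResult]:
    """One TmbResult per patient, in manifest order (zero counts included)."""
    config = config or TmbConfig()
    by_patient: dict[str, list[VariantCall]] = {
        pid: [] for pid in cohort.patient_ids()
    }
    for v in filtered_variants:
        by_patient[v.patient_id].append(v)
    return [
        compute_tmb(vs, config, patient_id=pid) for pid, vs in by_patient.items()
    ]
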