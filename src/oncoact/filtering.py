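"""Pre-analysis variant filtering: VAF floor and polymorphism exclusion.

Only variants with a VAF of at least 10% in the tumor sample enter the
analysis.  A variant is treated as a polymorphism — and removed — if any
configured reference population (1000 Genomes, gnomAD, ExAC sub-populations)
reports an allele frequency of at least 0.5%, or if it was seen in the
panel of normals (healthy-donor PBMC samples), which catches recurrent
technical artifacts and unannotated local polymorphisms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .cohort import VariantCall

__all__ = [
    "DEFAULT_POPULATION_LABELS",
    "FilterConfig",
    "FilterReport",
    "filter_variants",
]

# Population columns checked against the polymorphism AF threshold.
DEFAULT_POPULATION_LABELS: tuple[str, ...] = (
    "1000g_global", "1000g_ASN", "1000g_AFR", "1000g_AMR", "1000g_EUR",
    "1000g_AA", "1000g_EA",
    "gnomad_total", "gnomad_EAS", "gnomad_AFR", "gnomad_AMR", "gnomad_ASJ",
    "gnomad_FIN", "gnomad_NFE", "gnomad_OTH",
    "exac_total", "exac_Adj", "exac_AFR", "exac_AMR", "exac_EAS",
    "exac_FIN", "exac_NFE", "exac_OTH", "exac_SAS",
)

# Removal reasons, in precedence order.
REASONS = ("low_vaf", "population_af", "panel_of_normals")


@dataclass
class FilterConfig:
    min_vaf_pct: float = 10.0
    polymorphism_af_threshold: float = 0.005
    population_labels: tuple[str, ...] = DEFAULT_POPULATION_LABELS
    use_panel_of_normals: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_vaf_pct <= 100:
            raise ValueError(f"min_vaf_pct {self.min_vaf_pct} out of (0, 100]")
        if not 0 < self.polymorphism_af_threshold < 1:
            raise ValueError(
                f"polymorphism_af_threshold {self.polymorphism_af_threshold} "
                "out of (0, 1)"
            )


@dataclass
class FilterReport:
    removed: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REASONS}
    )
    retained: int = 0

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def n_input(self) -> int:
        return self.n_removed + self.retained


def removal_reason(variant: VariantCall, config: FilterConfig) -> str | None:
    """Why this variant is excluded, or ``None`` if it passes.

    Reasons are assigned with precedence low_vaf > population_af >
    panel_of_normals, so counts are unambiguous when several apply.
    """
    if variant.vaf_pct < config.min_vaf_pct:
        return "low_vaf"
    labels = set(config.population_labels)
    for label, af in variant.population_afs.items():
        if label in labels and af >= config.polymorphism_af_threshold:
            return "population_af"
    if config.use_panel_of_normals and variant.in_panel_of_normals:
        return "panel_of_normals"
    return None


def filter_variants(
    variants: list[VariantCall],
    config: FilterConfig | None = None,
) -> tuple[list[VariantCall], FilterReport]:
    """Apply the inclusion rules; returns (retained, report), order preserved."""
    config = config or FilterConfig()
    known = set(config.population_labels)
    extra = {
        lab for v in variants for lab in v.population_afs if lab not in known
    }
    if extra:
        warnings.warn(
            f"ignoring population AF label(s) not in config: {sorted(extra)}",
            stacklevel=2,
        )
    report = FilterReport()
    retained: list[VariantCall] = []
    for v in variants:
        reason = removal_reason(v, config)
        if reason is None:
            retained.append(v)
            report.retained += 1
        else:
            report.removed[reason] += 1
    return retained, report
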