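"""Optional converter: single-sample VCF -> variant-table rows.

The core data of record are the tabular interchange files; this helper
ingests a standard VCF 4.x when calls arrive in that form.  Gene symbols and
variant classes come from a caller-supplied annotation callback (VCFs differ
too much in their annotation conventions to guess), VAF from FORMAT ``AF``
or allelic depths ``AD``, and population AFs from INFO keys matching the
configured population labels.

Requires ``cyvcf2`` (install extra ``oncoact[vcf]``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

from .cohort import VariantCall
from .filtering import DEFAULT_POPULATION_LABELS

__all__ = ["vcf_to_variants"]

Annotator = Callable[[str, int, str, str], tuple[str, str, str] | None]
"""(chrom, pos, ref, alt) -> (gene, variant_class, protein_change) or None to skip."""


def _variant_vaf_pct(variant, sample_idx: int = 0) -> float | None:
    try:
        af = variant.format("AF")
        if af is not None:
            return float(af[sample_idx][0]) * 100.0
    except (KeyError, TypeError):
        pass
    try:
        ad = variant.format("AD")
        if ad is not None:
            ref_d, alt_d = float(ad[sample_idx][0]), float(ad[sample_idx][1])
            total = ref_d + alt_d
            if total > 0:
                return alt_d / total * 100.0
    except (KeyError, TypeError, IndexError):
        pass
    return None


def vcf_to_variants(
    vcf_path: str | Path,
    patient_id: str,
    annotator: Annotator,
    population_labels: tuple[str, ...] = DEFAULT_POPULATION_LABELS,
    pon_sites: set[tuple[str, str]] | None = None,
) -> list[VariantCall]:
    """Read a single-sample VCF into :class:`VariantCall` rows.

    ``pon_sites`` is an optional set of (gene, protein_change) pairs from a
    panel-of-normals site list; matching variants get ``in_pon`` set.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    out: list[VariantCall] = []
    vcf = VCF(str(vcf_path))
    for rec in vcf:
        for alt in rec.ALT:
            ann = annotator(rec.CHROM, rec.POS, rec.REF, alt)
            if ann is None:
                continue
            gene, vclass, protein_change = ann
            vaf = _variant_vaf_pct(rec)
            if vaf is None:
                continue
            afs = {}
            for label in population_labels:
                val = rec.INFO.get(label)
                if val is not None:
                    afs[label] = float(val)
            gene = gene.upper()
            out.append(
                VariantCall(
                    patient_id=patient_id,
                    gene=gene,
                    variant_class=vclass,
                    protein_change=protein_change,
                    vaf_pct=vaf,
                    population_afs=afs,
                    in_panel_of_normals=bool(
                        pon_sites and (gene, protein_change) in pon_sites
                    ),
                )
            )
    return out
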