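"""Qualification of filtered calls into therapy-relevant alterations.

Four rules decide whether a filtered variant or a gene-level copy-number call
is therapy-relevant; everything else is a variant of unknown significance
(VUS) and is excluded from all downstream actionability and frequency
statistics (but not from TMB, which counts detected mutations):

1. oncogene copy-number gain (observed CN >= 4) -> activating
2. tumor-suppressor copy-number loss (observed CN <= 1, heterozygous loss
   counts: the included suppressors are haploinsufficient) or
   truncating/splice variant -> inactivating
3. variant classified oncogenic / likely oncogenic by OncoKB ->
   activating on an oncogene, inactivating on a tumor suppressor
4. BRCA1/2 variant classified pathogenic / likely pathogenic under the
   ACMG/AMP guidelines -> inactivating

Gene roles: an oncogene is a growth-signaling-pathway activating gene; a
tumor suppressor is a pathway-inactivating or DNA-repair gene.  The default
role table for the 54-gene actionability universe ships with the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .cohort import CopyNumberCall, VariantCall

__all__ = [
    "CnvConfig",
    "QualifiedAlteration",
    "load_roles",
    "default_roles",
    "classify_alterations",
    "is_vus",
]

ROLES = ("oncogene", "tumor_suppressor")
EFFECTS = ("activating", "inactivating", "VUS")
# Evidence precedence when several rules fire (bookkeeping only: the effect
# is identical whenever more than one rule applies to the same call).
EVIDENCE_PRECEDENCE = (
    "acmg_pathogenic",
    "oncokb_oncogenic",
    "truncating_or_splice",
    "cn_gain",
    "cn_loss",
)

ACMG_GENES = ("BRCA1", "BRCA2")


@dataclass
class CnvConfig:
    gain_min_cn: float = 4.0
    loss_max_cn: float = 1.0

    def __post_init__(self) -> None:
        if self.gain_min_cn <= self.loss_max_cn:
            raise ValueError("gain_min_cn must exceed loss_max_cn")


@dataclass
class QualifiedAlteration:
    patient_id: str
    gene: str
    effect: str  # activating | inactivating | VUS
    evidence: str | None  # one of EVIDENCE_PRECEDENCE, None for VUS
    source: VariantCall | CopyNumberCall

    @property
    def is_cnv(self) -> bool:
        return isinstance(self.source, CopyNumberCall)


def load_roles(path: str | Path) -> dict[str, str]:
    """Read a two-column (gene, role) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "role"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    roles: dict[str, str] = {}
    for _, row in df.iterrows():
        gene, role = row["gene"].upper(), row["role"]
        if role not in ROLES:
            raise ValueError(f"{path}: unknown role {role!r} for {gene}")
        if gene in roles and roles[gene] != role:
            raise ValueError(f"{path}: conflicting roles for {gene}")
        roles[gene] = role
    return roles


def default_roles() -> dict[str, str]:
    """Role table for the 54 genes of the six analyzed pathways."""
    with resources.as_file(
        resources.files("oncoact.data").joinpath("roles.tsv")
    ) as p:
        return load_roles(p)


def _classify_variant(
    v: VariantCall, roles: dict[str, str]
) -> tuple[str, str | None]:
    role = roles.get(v.gene)
    if role is None:
        return "VUS", None
    # Rule 4 outranks the others in evidence bookkeeping.
    if v.gene in ACMG_GENES and v.acmg_class in ("pathogenic", "likely_pathogenic"):
        return "inactivating", "acmg_pathogenic"
    if v.oncokb_class in ("oncogenic", "likely_oncogenic"):
        effect = "activating" if role == "oncogene" else "inactivating"
        return effect, "oncokb_oncogenic"
    if role == "tumor_suppressor" and v.is_truncating_or_splice:
        return "inactivating", "truncating_or_splice"
    return "VUS", None


def _classify_cnv(
    c: CopyNumberCall, roles: dict[str, str], config: CnvConfig
) -> tuple[str, str | None]:
    role = roles.get(c.gene)
    if role is None:
        if c.observed_copy_number >= config.gain_min_cn or (
            c.observed_copy_number <= config.loss_max_cn
        ):
            warnings.warn(
                f"CNV call on {c.gene} which has no configured role; "
                "treated as VUS",
                stacklevel=3,
            )
        return "VUS", None
    if role == "oncogene" and c.observed_copy_number >= config.gain_min_cn:
        return "activating", "cn_gain"
    if role == "tumor_suppressor" and c.observed_copy_number <= config.loss_max_cn:
        return "inactivating", "cn_loss"
    return "VUS", None


def classify_alterations(
    variants: list[VariantCall],
    cnvs: list[CopyNumberCall],
    roles: dict[str, str] | None = None,
    config: CnvConfig | None = None,
) -> list[QualifiedAlteration]:
    """Apply the qualification rules; exactly one output per input call."""
    roles = default_roles() if roles is None else roles
    config = config or CnvConfig()
    out: list[QualifiedAlteration] = []
    for v in variants:
        effect, evidence = _classify_variant(v, roles)
        out.append(
            QualifiedAlteration(
                patient_id=v.patient_id,
                gene=v.gene,
                effect=effect,
                evidence=evidence,
                source=v,
            )
        )
    for c in cnvs:
        effect, evidence = _classify_cnv(c, roles, config)
        out.append(
            QualifiedAlteration(
                patient_id=c.patient_id,
                gene=c.gene,
                effect=effect,
                evidence=evidence,
                source=c,
            )
        )
    return out


def is_vus(alteration: QualifiedAlteration) -> bool:
    """True for variants of unknown significance.

    Downstream actionability and alteration-frequency statistics must exclude
    these; only TMB counts them.
    """
    return alteration.effect == "VUS"
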