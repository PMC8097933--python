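"""Cohort data model and tabular interchange I/O.

The unit of analysis is a cohort of tumor samples, each annotated with a
histological subtype (high-grade serous, endometrioid, or clear cell ovarian
carcinoma) and a tumor-purity estimate.  Per-sample calls come in two kinds:
small variants (SNVs/indels, protein-coding or splice-site) carrying a variant
allele fraction (VAF) plus external population-frequency and clinical
annotations, and gene-level observed copy numbers.

Three tab-separated files form the interchange layer:

* ``patients.tsv`` — patient_id, histology, tumor_purity_pct (empty = unknown)
* ``variants.tsv`` — patient_id, gene, variant_class, protein_change, vaf_pct,
  ``af_<population>`` columns (zero or more), in_pon, oncokb_class, acmg_class
* ``cnv.tsv`` — patient_id, gene, observed_copy_number
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "HISTOLOGIES",
    "VARIANT_CLASSES",
    "ONCOKB_CLASSES",
    "ACMG_CLASSES",
    "Patient",
    "VariantCall",
    "CopyNumberCall",
    "Cohort",
    "PurityReport",
    "CohortFormatError",
    "ReferentialIntegrityError",
    "read_cohort",
    "write_cohort",
    "exclude_low_purity",
]

HISTOLOGIES = ("HGS", "ENDOMETRIOID", "CLEAR_CELL")
VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "splice_site",
    "other_coding",
)
TRUNCATING_CLASSES = ("nonsense", "frameshift", "splice_site")
ONCOKB_CLASSES = ("oncogenic", "likely_oncogenic", "other", "unannotated")
ACMG_CLASSES = ("pathogenic", "likely_pathogenic", "other", "unannotated")


class CohortFormatError(ValueError):
    """A required column is missing or a field value is outside its domain."""


class ReferentialIntegrityError(ValueError):
    """A call references a patient absent from the manifest."""


@dataclass
class Patient:
    patient_id: str
    histology: str
    tumor_purity_pct: float | None = None
    low_purity: bool = False  # set for purities in the flag band (20-30% by default)

    def __post_init__(self) -> None:
        if self.histology not in HISTOLOGIES:
            raise CohortFormatError(
                f"unknown histology {self.histology!r} for patient "
                f"{self.patient_id!r}; expected one of {HISTOLOGIES}"
            )
        if self.tumor_purity_pct is not None and not (
            0 <= self.tumor_purity_pct <= 100
        ):
            raise CohortFormatError(
                f"tumor_purity_pct {self.tumor_purity_pct} out of [0, 100] "
                f"for patient {self.patient_id!r}"
            )


@dataclass
class VariantCall:
    """One small variant: SNV or small indel, coding or splice-site.

    ``population_afs`` maps a population label (e.g. ``gnomad_EAS``) to the
    allele fraction reported for that population; absence of a label means the
    variant was not observed there.  ``oncokb_class`` and ``acmg_class`` are
    consumed as precomputed annotation columns, never queried at run time.
    """

    patient_id: str
    gene: str
    variant_class: str
    protein_change: str = ""
    vaf_pct: float = 0.0
    population_afs: dict[str, float] = field(default_factory=dict)
    in_panel_of_normals: bool = False
    oncokb_class: str = "unannotated"
    acmg_class: str = "unannotated"

    def __post_init__(self) -> None:
        if not self.gene:
            raise CohortFormatError("variant with empty gene symbol")
        self.gene = self.gene.upper()
        if self.variant_class not in VARIANT_CLASSES:
            raise CohortFormatError(
                f"unknown variant_class {self.variant_class!r} "
                f"({self.patient_id} {self.gene})"
            )
        if not 0 <= self.vaf_pct <= 100:
            raise CohortFormatError(
                f"vaf_pct {self.vaf_pct} out of [0, 100] "
                f"({self.patient_id} {self.gene})"
            )
        for label, af in self.population_afs.items():
            if not 0 <= af <= 1:
                raise CohortFormatError(
                    f"population AF {af} out of [0, 1] for {label} "
                    f"({self.patient_id} {self.gene})"
                )
        if self.oncokb_class not in ONCOKB_CLASSES:
            raise CohortFormatError(f"unknown oncokb_class {self.oncokb_class!r}")
        if self.acmg_class not in ACMG_CLASSES:
            raise CohortFormatError(f"unknown acmg_class {self.acmg_class!r}")

    @property
    def is_truncating_or_splice(self) -> bool:
        return self.variant_class in TRUNCATING_CLASSES


@dataclass
class CopyNumberCall:
    """Gene-level observed copy number for one patient (diploid baseline 2)."""

    patient_id: str
    gene: str
    observed_copy_number: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise CohortFormatError("CNV call with empty gene symbol")
        self.gene = self.gene.upper()
        if self.observed_copy_number < 0 or math.isnan(self.observed_copy_number):
            raise CohortFormatError(
                f"observed_copy_number {self.observed_copy_number} < 0 "
                f"({self.patient_id} {self.gene})"
            )


@dataclass
class Cohort:
    patients: list[Patient]
    variants: list[VariantCall] = field(default_factory=list)
    cnvs: list[CopyNumberCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortFormatError(f"duplicate patient_id(s): {dupes}")
        known = set(ids)
        bad_v = [v for v in self.variants if v.patient_id not in known]
        bad_c = [c for c in self.cnvs if c.patient_id not in known]
        if bad_v or bad_c:
            offending = sorted(
                {x.patient_id for x in bad_v} | {x.patient_id for x in bad_c}
            )
            raise ReferentialIntegrityError(
                f"{len(bad_v)} variant row(s) and {len(bad_c)} CNV row(s) "
                f"reference patient(s) absent from the manifest: {offending}"
            )
        seen: set[tuple[str, str]] = set()
        for c in self.cnvs:
            key = (c.patient_id, c.gene)
            if key in seen:
                raise CohortFormatError(f"duplicate CopyNumberCall for {key}")
            seen.add(key)

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def variants_of(self, patient_id: str) -> list[VariantCall]:
        return [v for v in self.variants if v.patient_id == patient_id]

    def cnvs_of(self, patient_id: str) -> list[CopyNumberCall]:
        return [c for c in self.cnvs if c.patient_id == patient_id]

    def histology_of(self, patient_id: str) -> str:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p.histology
        raise KeyError(patient_id)

    def subtype_sizes(self) -> dict[str, int]:
        sizes = {h: 0 for h in HISTOLOGIES}
        for p in self.patients:
            sizes[p.histology] += 1
        return sizes


# ---------------------------------------------------------------------------
# TSV interchange


_PATIENT_COLS = ["patient_id", "histology", "tumor_purity_pct"]
_VARIANT_FIXED_COLS = [
    "patient_id",
    "gene",
    "variant_class",
    "protein_change",
    "vaf_pct",
    "in_pon",
    "oncokb_class",
    "acmg_class",
]
_CNV_COLS = ["patient_id", "gene", "observed_copy_number"]


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    for col in required:
        if col not in df.columns:
            raise CohortFormatError(f"{path}: missing required column {col!r}")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_cohort(
    manifest_path: str | Path,
    variants_path: str | Path,
    cnv_path: str | Path,
) -> Cohort:
    """Read the three interchange TSVs into a validated :class:`Cohort`.

    Column order is irrelevant; population-AF columns are any column named
    ``af_<label>``.  Duplicate identical variant rows are collapsed with a
    warning (they would otherwise double-count in TMB).
    """
    manifest_path, variants_path, cnv_path = (
        Path(manifest_path),
        Path(variants_path),
        Path(cnv_path),
    )
    pdf = _read_tsv(manifest_path)
    _require_columns(pdf, _PATIENT_COLS, manifest_path)
    patients = [
        Patient(
            patient_id=row["patient_id"],
            histology=row["histology"],
            tumor_purity_pct=(
                float(row["tumor_purity_pct"]) if row["tumor_purity_pct"] != "" else None
            ),
        )
        for _, row in pdf.iterrows()
    ]

    vdf = _read_tsv(variants_path)
    _require_columns(vdf, _VARIANT_FIXED_COLS, variants_path)
    af_cols = [c for c in vdf.columns if c.startswith("af_")]
    seen_rows: set[tuple] = set()
    n_dupes = 0
    variants: list[VariantCall] = []
    for _, row in vdf.iterrows():
        key = tuple(row[c] for c in _VARIANT_FIXED_COLS + af_cols)
        if key in seen_rows:
            n_dupes += 1
            continue
        seen_rows.add(key)
        afs = {
            c[len("af_"):]: float(row[c]) for c in af_cols if row[c] != ""
        }
        variants.append(
            VariantCall(
                patient_id=row["patient_id"],
                gene=row["gene"],
                variant_class=row["variant_class"],
                protein_change=row["protein_change"],
                vaf_pct=float(row["vaf_pct"]),
                population_afs=afs,
                in_panel_of_normals=row["in_pon"] in ("1", "true", "True"),
                oncokb_class=row["oncokb_class"] or "unannotated",
                acmg_class=row["acmg_class"] or "unannotated",
            )
        )
    if n_dupes:
        warnings.warn(
            f"{variants_path}: collapsed {n_dupes} duplicate identical variant row(s)",
            stacklevel=2,
        )

    cdf = _read_tsv(cnv_path)
    _require_columns(cdf, _CNV_COLS, cnv_path)
    cnvs = [
        CopyNumberCall(
            patient_id=row["patient_id"],
            gene=row["gene"],
            observed_copy_number=float(row["observed_copy_number"]),
        )
        for _, row in cdf.iterrows()
    ]
    return Cohort(patients=patients, variants=variants, cnvs=cnvs)


def _fmt(x: float | None) -> str:
    if x is None:
        return ""
    return repr(float(x))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the three interchange TSVs; inverse of :func:`read_cohort`.

    Population-AF columns are emitted for every label observed anywhere in the
    cohort, in sorted order, so output is byte-stable for a given cohort.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out_dir / "patients.tsv",
        "variants": out_dir / "variants.tsv",
        "cnv": out_dir / "cnv.tsv",
    }

    with open(paths["patients"], "w") as fh:
        fh.write("\t".join(_PATIENT_COLS) + "\n")
        for p in cohort.patients:
            fh.write(
                f"{p.patient_id}\t{p.histology}\t{_fmt(p.tumor_purity_pct)}\n"
            )

    labels = sorted({lab for v in cohort.variants for lab in v.population_afs})
    af_cols = [f"af_{lab}" for lab in labels]
    with open(paths["variants"], "w") as fh:
        fh.write("\t".join(_VARIANT_FIXED_COLS + af_cols) + "\n")
        for v in cohort.variants:
            row = [
                v.patient_id,
                v.gene,
                v.variant_class,
                v.protein_change,
                _fmt(v.vaf_pct),
                "1" if v.in_panel_of_normals else "0",
                v.oncokb_class,
                v.acmg_class,
            ] + [
                _fmt(v.population_afs[lab]) if lab in v.population_afs else ""
                for lab in labels
            ]
            fh.write("\t".join(row) + "\n")

    with open(paths["cnv"], "w") as fh:
        fh.write("\t".join(_CNV_COLS) + "\n")
        for c in cohort.cnvs:
            fh.write(f"{c.patient_id}\t{c.gene}\t{_fmt(c.observed_copy_number)}\n")

    return paths


@dataclass
class PurityReport:
    excluded: list[str]
    flagged: list[str]


def exclude_low_purity(
    cohort: Cohort,
    min_purity_pct: float = 20.0,
    flag_below_pct: float = 30.0,
) -> tuple[Cohort, PurityReport]:
    """Drop samples whose tumor purity is too low for reliable calls.

    Patients with purity below ``min_purity_pct``, or with unknown purity
    (purity could not be determined), are removed together with all their
    calls.  Patients in ``[min_purity_pct, flag_below_pct)`` are retained but
    carry a low-purity flag — CNV detection, gene loss especially, is
    unreliable at such purities — which downstream reports propagate.
    """
    excluded: list[str] = []
    kept: list[Patient] = []
    flagged: list[str] = []
    for p in cohort.patients:
        if p.tumor_purity_pct is None or p.tumor_purity_pct < min_purity_pct:
            excluded.append(p.patient_id)
        elif p.tumor_purity_pct < flag_below_pct:
            flagged.append(p.patient_id)
            kept.append(replace(p, low_purity=True))
        else:
            kept.append(replace(p))
    kept_ids = {p.patient_id for p in kept}
    out = Cohort(
        patients=kept,
        variants=[v for v in cohort.variants if v.patient_id in kept_ids],
        cnvs=[c for c in cohort.cnvs if c.patient_id in kept_ids],
    )
    return out, PurityReport(excluded=excluded, flagged=flagged)
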