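"""End-to-end orchestration: purity exclusion -> filtering -> qualification
-> actionability -> TMB -> cohort statistics, with a provenance log.

Each stage's record counts are logged so that input = retained + removed is
checkable at every step; reruns on identical inputs produce identical
bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import CnvConfig, QualifiedAlteration, classify_alterations, default_roles, is_vus, load_roles
from .cohort import Cohort, exclude_low_purity, read_cohort
from .filtering import FilterConfig, filter_variants
from .pathways import DRUG_TARGETS, ActionabilityCall, assess_patient, default_pathways, load_pathways
from .stats import (
    actionability_frequency,
    alteration_frequency,
    chi_square,
    oncoprint_matrix,
    overlap_summary,
    tmb_split,
)
from .tmb import TmbConfig, compute_cohort_tmb

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

# Single-gene strata reported (and chi-squared) in frequencies.tsv; the
# subtype-characteristic genes of the study.
_FREQ_GENES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("BRCA1/2", ("BRCA1", "BRCA2")),
    ("ARID1A", ("ARID1A",)),
    ("PTEN", ("PTEN",)),
    ("ERBB2", ("ERBB2",)),
    ("PIK3CA", ("PIK3CA",)),
    ("KRAS", ("KRAS",)),
    ("NF1", ("NF1",)),
    ("CCND1", ("CCND1",)),
    ("RB1", ("RB1",)),
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    manifest_path: str | Path
    variants_path: str | Path
    cnv_path: str | Path
    out_dir: str | Path
    pathways_path: str | Path | None = None
    roles_path: str | Path | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    cnv_config: CnvConfig = field(default_factory=CnvConfig)
    tmb_config: TmbConfig = field(default_factory=TmbConfig)
    min_purity_pct: float = 20.0
    flag_below_pct: float = 30.0
    verbosity: int = 0


def _hash_config(cfg: RunConfig) -> str:
    payload = json.dumps(
        {
            "manifest": str(cfg.manifest_path),
            "variants": str(cfg.variants_path),
            "cnv": str(cfg.cnv_path),
            "pathways": str(cfg.pathways_path),
            "roles": str(cfg.roles_path),
            "min_vaf_pct": cfg.filter_config.min_vaf_pct,
            "poly_af": cfg.filter_config.polymorphism_af_threshold,
            "use_pon": cfg.filter_config.use_panel_of_normals,
            "gain_min_cn": cfg.cnv_config.gain_min_cn,
            "loss_max_cn": cfg.cnv_config.loss_max_cn,
            "panel_size_mb": cfg.tmb_config.panel_size_mb,
            "high_tmb_threshold": cfg.tmb_config.high_tmb_threshold,
            "min_purity_pct": cfg.min_purity_pct,
            "flag_below_pct": cfg.flag_below_pct,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _freq_to_rows(freq, flagged: set[str]) -> list[dict]:
    rows = []
    for h in freq.counts:
        rows.append(
            {
                "stratum": freq.label,
                "histology": h,
                "count": freq.counts[h],
                "denominator": freq.denominators[h],
                "percent": freq.percents[h],
            }
        )
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write the report bundle; returns the run summary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def _stage(name: str, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            raise PipelineError(name, str(exc)) from exc

    # 1. load + purity exclusion
    raw = _stage(
        "load", read_cohort, config.manifest_path, config.variants_path,
        config.cnv_path,
    )
    cohort, purity = _stage(
        "purity", exclude_low_purity, raw, config.min_purity_pct,
        config.flag_below_pct,
    )
    flagged = set(purity.flagged)
    log.append(
        {
            "stage": "purity",
            "input_patients": len(raw.patients),
            "retained_patients": len(cohort.patients),
            "excluded_patients": len(purity.excluded),
            "flagged_low_purity": len(purity.flagged),
        }
    )

    # 2. variant filtering
    filtered, freport = _stage("filter", filter_variants, cohort.variants,
                               config.filter_config)
    log.append(
        {
            "stage": "filter",
            "input_variants": freport.n_input,
            "retained": freport.retained,
            "removed": dict(freport.removed),
        }
    )

    # 3. qualification
    roles = (
        load_roles(config.roles_path) if config.roles_path else default_roles()
    )
    qualified = _stage(
        "classify", classify_alterations, filtered, cohort.cnvs, roles,
        config.cnv_config,
    )
    n_vus = sum(1 for a in qualified if is_vus(a))
    log.append(
        {
            "stage": "classify",
            "input_calls": len(filtered) + len(cohort.cnvs),
            "qualified": len(qualified) - n_vus,
            "vus": n_vus,
        }
    )
    therapy_relevant = [a for a in qualified if not is_vus(a)]

    # 4. actionability
    specs = (
        load_pathways(config.pathways_path)
        if config.pathways_path
        else default_pathways()
    )
    by_patient: dict[str, list[QualifiedAlteration]] = {
        pid: [] for pid in cohort.patient_ids()
    }
    for a in therapy_relevant:
        by_patient[a.patient_id].append(a)
    calls: list[ActionabilityCall] = []
    for pid in cohort.patient_ids():
        calls.extend(
            _stage("assess", assess_patient, by_patient[pid], specs, pid)
        )
    log.append(
        {
            "stage": "assess",
            "patients": len(cohort.patients),
            "calls": len(calls),
            "actionable": sum(1 for c in calls if c.verdict == "actionable"),
            "impaired": sum(1 for c in calls if c.verdict == "impaired"),
        }
    )

    # 5. TMB (on filtered variants, VUS included)
    tmb_results = _stage("tmb", compute_cohort_tmb, cohort, filtered,
                         config.tmb_config)
    log.append(
        {
            "stage": "tmb",
            "patients": len(tmb_results),
            "high_tmb": sum(1 for r in tmb_results if r.high_tmb),
        }
    )

    # 6. cohort statistics
    freq_rows: list[dict] = []
    chisq_rows: list[dict] = []
    for label, genes in _FREQ_GENES:
        freq = alteration_frequency(cohort, therapy_relevant, set(genes), label)
        freq_rows.extend(_freq_to_rows(freq, flagged))
        table = [
            [freq.counts[h], freq.denominators[h] - freq.counts[h]]
            for h in freq.counts
        ]
        try:
            res = chi_square(table)
            chisq_rows.append(
                {
                    "stratum": label,
                    "statistic": res.statistic,
                    "dof": res.dof,
                    "p_value": res.p_value,
                    "low_expected_counts": res.low_expected_counts,
                }
            )
        except ValueError:
            chisq_rows.append(
                {
                    "stratum": label,
                    "statistic": float("nan"),
                    "dof": 0,
                    "p_value": float("nan"),
                    "low_expected_counts": True,
                }
            )
    act_freqs = actionability_frequency(calls, cohort)
    split = tmb_split(tmb_results, cohort, config.tmb_config.high_tmb_threshold)
    overlap = overlap_summary(calls, therapy_relevant, cohort, specs)
    freq_rows.extend(_freq_to_rows(split, flagged))
    freq_rows.extend(_freq_to_rows(overlap, flagged))
    log.append({"stage": "stats", "strata": len(freq_rows)})

    # --- write bundle -----------------------------------------------------
    pd.DataFrame(freq_rows).to_csv(out_dir / "frequencies.tsv", sep="\t",
                                   index=False)
    pd.DataFrame(chisq_rows).to_csv(out_dir / "chisq.tsv", sep="\t",
                                    index=False)
    pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "drug_target": c.drug_target,
                "verdict": c.verdict,
                "sensitizing": ";".join(sorted({a.gene for a in c.sensitizing})),
                "negating": ";".join(sorted({a.gene for a in c.negating})),
                "low_purity": c.patient_id in flagged,
            }
            for c in calls
        ]
    ).to_csv(out_dir / "actionability.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "stratum": t,
                "histology": h,
                "count": f.counts[h],
                "denominator": f.denominators[h],
                "percent": f.percents[h],
            }
            for t, f in act_freqs.items()
            for h in f.counts
        ]
    ).to_csv(out_dir / "actionability_frequencies.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "n_mutations": r.n_mutations,
                "tmb": r.tmb,
                "high_tmb": r.high_tmb,
                "low_purity": r.patient_id in flagged,
            }
            for r in tmb_results
        ]
    ).to_csv(out_dir / "tmb.tsv", sep="\t", index=False)
    oncoprint_matrix(cohort, therapy_relevant).to_csv(
        out_dir / "oncoprint.tsv", sep="\t"
    )

    summary = {
        "version": __version__,
        "config_hash": _hash_config(config),
        "stages": log,
        "n_patients": len(cohort.patients),
        "excluded_low_purity": purity.excluded,
        "flagged_low_purity": purity.flagged,
    }
    (out_dir / "run_log.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
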