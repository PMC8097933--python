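"""Synthetic three-subtype ovarian-carcinoma cohorts.

The generator emulates the statistical structure the analysis assumes: a
cohort of high-grade serous (n=37), endometrioid (n=22) and clear cell
(n=23) carcinomas; per-gene, per-subtype alteration probabilities (mutation
vs copy-number gain vs loss) drawn independently per patient; a background
mutation load over a pool of non-actionability panel genes giving a median
TMB near 9.6 Mut/Mb; and rare high-TMB outliers (27% of endometrioid, 4% of
clear cell patients), a subset of which carry paired MLH1/MSH6 mismatch-
repair variants.

Default per-gene probabilities are taken from the reported per-subtype
alteration frequencies where printed (ERBB2 gain 3/23/22%, combined BRCA1/2
30/0/0%, ARID1A truncating 3/32/39%, NF1 14/0/0%, KRAS mutation confined to
endometrioid/clear cell, PTEN loss-only in serous and mutation-only in
endometrioid, CCND1 gain enriched in serous); the remaining entries were
solved, under the independence model, so the expected per-target
actionability percentages match the reported ones (PARP 59/50/48, AKT1
22/45/35, MTOR >=57 everywhere, KRAS 16/18/13, MEK1/2 30/27/13, CDK4/6
41/41/22, PIK3CA within 8-27).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, CopyNumberCall, Patient, VariantCall

__all__ = ["SimConfig", "generate", "default_frequency_table"]

_H = ("HGS", "ENDOMETRIOID", "CLEAR_CELL")
_PREFIX = {"HGS": "HGS", "ENDOMETRIOID": "E", "CLEAR_CELL": "CC"}

# (gene, p_mutation, p_gain, p_loss) per histology.  Genes absent from a
# subtype's list are never altered there.
_FREQ: dict[str, list[tuple[str, float, float, float]]] = {
    "HGS": [
        ("BRCA1", 0.22, 0.0, 0.0),
        ("BRCA2", 0.11, 0.0, 0.0),
        ("ARID1A", 0.03, 0.0, 0.0),
        ("PTEN", 0.0, 0.0, 0.22),
        ("ATM", 0.10, 0.0, 0.0),
        ("CHEK2", 0.06, 0.0, 0.0),
        ("RAD50", 0.05, 0.0, 0.0),
        ("BLM", 0.04, 0.0, 0.0),
        ("EGFR", 0.03, 0.0, 0.0),
        ("ERBB2", 0.0, 0.03, 0.0),
        ("MET", 0.0, 0.05, 0.0),
        ("IGF1R", 0.0, 0.03, 0.0),
        ("PIK3CA", 0.05, 0.24, 0.0),
        ("PIK3CB", 0.0, 0.02, 0.0),
        ("PIK3CG", 0.0, 0.02, 0.0),
        ("AKT1", 0.0, 0.14, 0.0),
        ("AKT2", 0.0, 0.02, 0.0),
        ("AKT3", 0.0, 0.02, 0.0),
        ("TSC1", 0.0, 0.0, 0.12),
        ("TSC2", 0.0, 0.0, 0.12),
        ("STK11", 0.0, 0.0, 0.12),
        ("NF2", 0.0, 0.0, 0.04),
        ("FLCN", 0.0, 0.0, 0.08),
        ("FBXW7", 0.0, 0.0, 0.14),
        ("MTOR", 0.0, 0.12, 0.0),
        ("KRAS", 0.0, 0.03, 0.0),
        ("NF1", 0.14, 0.0, 0.0),
        ("MAP2K1", 0.0, 0.08, 0.0),
        ("MAP2K2", 0.0, 0.08, 0.0),
        ("MAPK1", 0.0, 0.01, 0.0),
        ("CCND1", 0.0, 0.35, 0.0),
        ("CCNE1", 0.0, 0.10, 0.0),
        ("CDK4", 0.0, 0.08, 0.0),
        ("CDK6", 0.0, 0.05, 0.0),
        ("CDKN2A", 0.0, 0.0, 0.15),
        ("CDKN2B", 0.0, 0.0, 0.04),
        ("RB1", 0.0, 0.0, 0.12),
        ("SMO", 0.0, 0.05, 0.0),
        ("PTCH1", 0.0, 0.0, 0.04),
        ("SUFU", 0.0, 0.0, 0.01),
        ("STK36", 0.0, 0.01, 0.0),
    ],
    "ENDOMETRIOID": [
        ("ARID1A", 0.32, 0.0, 0.0),
        ("PTEN", 0.27, 0.0, 0.0),
        ("ERBB2", 0.0, 0.23, 0.0),
        ("RET", 0.0, 0.05, 0.0),
        ("PIK3CA", 0.32, 0.04, 0.0),
        ("AKT1", 0.09, 0.09, 0.0),
        ("TSC1", 0.05, 0.0, 0.0),
        ("TSC2", 0.05, 0.0, 0.0),
        ("STK11", 0.0, 0.0, 0.03),
        ("NF2", 0.04, 0.0, 0.0),
        ("FLCN", 0.0, 0.0, 0.02),
        ("FBXW7", 0.05, 0.0, 0.0),
        ("MTOR", 0.0, 0.05, 0.0),
        ("KRAS", 0.18, 0.0, 0.0),
        ("MAP2K1", 0.0, 0.04, 0.0),
        ("MAP2K2", 0.0, 0.04, 0.0),
        ("CCND1", 0.0, 0.15, 0.0),
        ("CCNE1", 0.0, 0.02, 0.0),
        ("CDK4", 0.0, 0.05, 0.0),
        ("CDK6", 0.0, 0.05, 0.0),
        ("CDKN2A", 0.0, 0.0, 0.25),
        ("RB1", 0.0, 0.0, 0.02),
        ("SMO", 0.0, 0.03, 0.0),
        ("PTCH1", 0.0, 0.0, 0.03),
    ],
    "CLEAR_CELL": [
        ("ARID1A", 0.39, 0.0, 0.0),
        ("ATM", 0.05, 0.0, 0.0),
        ("CHEK2", 0.05, 0.0, 0.0),
        ("BAP1", 0.05, 0.0, 0.0),
        ("ERBB2", 0.0, 0.22, 0.0),
        ("IGF1R", 0.0, 0.04, 0.0),
        ("PIK3CA", 0.35, 0.04, 0.0),
        ("AKT1", 0.0, 0.10, 0.0),
        ("AKT2", 0.0, 0.02, 0.0),
        ("TSC1", 0.04, 0.0, 0.0),
        ("TSC2", 0.04, 0.0, 0.0),
        ("STK11", 0.0, 0.0, 0.04),
        ("NF2", 0.04, 0.0, 0.0),
        ("FBXW7", 0.04, 0.0, 0.0),
        ("MTOR", 0.0, 0.05, 0.0),
        ("KRAS", 0.10, 0.0, 0.0),
        ("CCND1", 0.0, 0.08, 0.0),
        ("CCNE1", 0.0, 0.02, 0.0),
        ("CDKN2A", 0.0, 0.0, 0.16),
        ("SMO", 0.0, 0.03, 0.0),
        ("PTCH1", 0.0, 0.0, 0.02),
    ],
}

# How a qualifying mutation in each gene presents.  Unlisted tumor
# suppressors default to "truncating", unlisted oncogenes to
# "missense_oncogenic".
_MUT_STYLE: dict[str, str] = {
    "BRCA1": "acmg",
    "BRCA2": "acmg",
    "PTEN": "pten",
    "PIK3CA": "hotspot",
    "KRAS": "hotspot",
    "AKT1": "hotspot",
    "EGFR": "egfr",
}

_HOTSPOTS = {
    "PIK3CA": ("H1047R", "H1047L", "E545K", "E542K"),
    "KRAS": ("G12D", "G12V", "G13D", "Q61H"),
    "AKT1": ("E17K",),
}

_TSG = {
    "ARID1A", "ATM", "ATR", "BAP1", "BLM", "BRCA1", "BRCA2", "CHEK1",
    "CHEK2", "ERCC1", "MLH1", "MRE11A", "PALB2", "RAD50", "PTEN", "TSC1",
    "TSC2", "STK11", "NF1", "NF2", "FLCN", "FBXW7", "CDKN2A", "CDKN2B",
    "RB1", "PTCH1", "SUFU",
}

# Panel genes outside the 54-gene actionability universe, over which the
# background mutation load (and hence TMB) is drawn.
_BACKGROUND_POOL = (
    "TP53", "CTNNB1", "PPP2R1A", "SMARCA4", "ARID1B", "ARID2", "KMT2A",
    "KMT2C", "KMT2D", "NOTCH1", "NOTCH2", "NOTCH3", "FAT1", "FAT4", "SPOP",
    "ATRX", "CREBBP", "EP300", "SETD2", "KDM6A", "KDM5C", "NFE2L2", "RNF43",
    "POLE", "POLD1", "APC", "SMAD4", "GATA3", "FOXA1", "CDH1", "VHL", "BCOR",
    "STAG2", "ASXL1", "DNMT3A", "TET2", "IDH1", "IDH2", "EZH2", "PBRM1",
    "MED12", "ZFHX3", "ROS1", "ALK", "NTRK1", "NTRK3", "FGFR1", "FGFR2",
    "FGFR3", "FGFR4", "JAK1", "JAK2", "ERBB3", "ERBB4", "CIC", "DAXX",
    "MEN1", "CARD11", "TSHR", "GNAS",
)

_AMINO = "ACDEFGHIKLMNPQRSTVWY"


def default_frequency_table() -> pd.DataFrame:
    """Per-(histology, gene) qualifying-alteration probabilities.

    Columns: histology, gene, p_mutation, p_gain, p_loss.  Genes of the
    actionability universe absent from a subtype's rows have probability 0
    there (e.g. PTEN in clear cell carcinomas).
    """
    rows = [
        {
            "histology": h,
            "gene": g,
            "p_mutation": pm,
            "p_gain": pg,
            "p_loss": pl,
        }
        for h, entries in _FREQ.items()
        for (g, pm, pg, pl) in entries
    ]
    return pd.DataFrame(rows)


@dataclass
class SimConfig:
    n_per_subtype: dict[str, int] = field(
        default_factory=lambda: {"HGS": 37, "ENDOMETRIOID": 22, "CLEAR_CELL": 23}
    )
    freq_table: pd.DataFrame | None = None  # None -> default_frequency_table()
    # High-TMB outlier rate per subtype; among endometrioid outliers,
    # mmr_coupling receive paired MLH1 + MSH6 variants (biallelic pattern).
    high_tmb_rate: dict[str, float] = field(
        default_factory=lambda: {"HGS": 0.0, "ENDOMETRIOID": 0.27, "CLEAR_CELL": 0.04}
    )
    mmr_coupling: float = 1.0 / 3.0
    # Total filtered-mutation count targets (Poisson, clamped): ordinary
    # patients land in the 3.2-16 Mut/Mb band, outliers in 19.2-28 Mut/Mb.
    background_mean: float = 11.5
    background_clamp: tuple[int, int] = (3, 18)
    high_tmb_mean: float = 30.0
    high_tmb_clamp: tuple[int, int] = (24, 34)
    panel_vus_rate: float = 0.4  # extra non-qualifying missense in the 54 genes
    # Pre-filter junk, removed by the polymorphism/VAF filter.
    low_vaf_rate: float = 1.2
    polymorphic_rate: float = 0.8
    pon_rate: float = 0.3
    # Tumor purity: a small fraction of samples sit in the 20-30% flag band.
    low_purity_rate: float = 3.0 / 82.0
    # Optional co-occurrence multiplier for PTEN mutation given an ARID1A
    # mutation in endometrioid carcinomas (1.0 = independent).
    arid1a_pten_odds: float = 1.0
    vaf_mean: float = 35.0
    vaf_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        for h, r in self.high_tmb_rate.items():
            if not 0 <= r <= 1:
                raise ValueError(f"high_tmb_rate[{h}]={r} out of [0, 1]")
        if not 0 <= self.mmr_coupling <= 1:
            raise ValueError("mmr_coupling out of [0, 1]")
        for h, n in self.n_per_subtype.items():
            if n < 0:
                raise ValueError(f"n_per_subtype[{h}]={n} negative")
        tab = self.freq_table if self.freq_table is not None else default_frequency_table()
        bad = tab[
            (tab[["p_mutation", "p_gain", "p_loss"]].lt(0).any(axis=1))
            | (tab[["p_mutation", "p_gain", "p_loss"]].gt(1).any(axis=1))
            | ((tab["p_gain"] + tab["p_loss"]).gt(1))
        ]
        if len(bad):
            raise ValueError(
                f"invalid probabilities in frequency table:\n{bad}"
            )


def _draw_vaf(rng: np.random.Generator, cfg: SimConfig) -> float:
    return float(np.clip(rng.normal(cfg.vaf_mean, cfg.vaf_sd), 10.0, 90.0))


def _protein_change(rng: np.random.Generator, kind: str) -> str:
    pos = int(rng.integers(20, 1200))
    aa = _AMINO[rng.integers(0, len(_AMINO))]
    if kind == "missense":
        alt = _AMINO[rng.integers(0, len(_AMINO))]
        return f"{aa}{pos}{alt}"
    if kind == "nonsense":
        return f"{aa}{pos}*"
    if kind == "frameshift":
        return f"{aa}{pos}fs"
    return ""  # splice_site


def _make_mutation(
    rng: np.random.Generator, cfg: SimConfig, pid: str, gene: str
) -> VariantCall:
    style = _MUT_STYLE.get(gene, "truncating" if gene in _TSG else "missense_oncogenic")
    vaf = _draw_vaf(rng, cfg)
    if style == "pten":
        style = "truncating" if rng.random() < 0.7 else "missense_oncogenic"
    if style == "acmg":
        vclass = "frameshift" if rng.random() < 0.6 else "nonsense"
        return VariantCall(
            patient_id=pid, gene=gene, variant_class=vclass,
            protein_change=_protein_change(rng, vclass), vaf_pct=vaf,
            acmg_class="pathogenic" if rng.random() < 0.7 else "likely_pathogenic",
        )
    if style == "truncating":
        u = rng.random()
        vclass = "nonsense" if u < 0.40 else ("frameshift" if u < 0.85 else "splice_site")
        return VariantCall(
            patient_id=pid, gene=gene, variant_class=vclass,
            protein_change=_protein_change(rng, vclass), vaf_pct=vaf,
        )
    if style == "hotspot":
        hs = _HOTSPOTS[gene]
        return VariantCall(
            patient_id=pid, gene=gene, variant_class="missense",
            protein_change=hs[rng.integers(0, len(hs))], vaf_pct=vaf,
            oncokb_class="oncogenic",
        )
    if style == "egfr":
        return VariantCall(
            patient_id=pid, gene=gene, variant_class="missense",
            protein_change="G588S", vaf_pct=vaf,
            oncokb_class="likely_oncogenic",
        )
    # missense_oncogenic
    return VariantCall(
        patient_id=pid, gene=gene, variant_class="missense",
        protein_change=_protein_change(rng, "missense"), vaf_pct=vaf,
        oncokb_class="oncogenic" if rng.random() < 0.8 else "likely_oncogenic",
    )


def _vus_missense(
    rng: np.random.Generator, cfg: SimConfig, pid: str, gene: str, **kw
) -> VariantCall:
    return VariantCall(
        patient_id=pid, gene=gene, variant_class="missense",
        protein_change=_protein_change(rng, "missense"),
        vaf_pct=kw.pop("vaf_pct", _draw_vaf(rng, cfg)),
        oncokb_class="unannotated", **kw,
    )


def generate(config: SimConfig | None = None) -> Cohort:
    """Draw one cohort; identical config (incl. seed) gives identical output."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    tab = cfg.freq_table if cfg.freq_table is not None else default_frequency_table()
    by_hist: dict[str, list[tuple[str, float, float, float]]] = {h: [] for h in _H}
    for _, row in tab.iterrows():
        by_hist[row["histology"]].append(
            (row["gene"], row["p_mutation"], row["p_gain"], row["p_loss"])
        )

    patients: list[Patient] = []
    variants: list[VariantCall] = []
    cnvs: list[CopyNumberCall] = []

    for hist in _H:
        n = cfg.n_per_subtype.get(hist, 0)
        for i in range(1, n + 1):
            pid = f"{_PREFIX[hist]}{i:04d}"
            purity = (
                float(rng.uniform(20, 30))
                if rng.random() < cfg.low_purity_rate
                else float(rng.uniform(35, 95))
            )
            patients.append(
                Patient(patient_id=pid, histology=hist,
                        tumor_purity_pct=round(purity, 1))
            )

            mutated: set[str] = set()
            entries = by_hist[hist]
            # ARID1A drawn first so the optional co-occurrence multiplier
            # can condition PTEN on it (endometrioid only).
            for gene, p_mut, p_gain, p_loss in entries:
                if gene == "PTEN" and hist == "ENDOMETRIOID":
                    if "ARID1A" in mutated:
                        p_mut = min(1.0, p_mut * cfg.arid1a_pten_odds)
                if rng.random() < p_mut:
                    variants.append(_make_mutation(rng, cfg, pid, gene))
                    mutated.add(gene)
                u = rng.random()
                if u < p_gain:
                    cnvs.append(
                        CopyNumberCall(pid, gene, round(float(rng.uniform(4, 8)), 1))
                    )
                elif u < p_gain + p_loss:
                    cn = 1.0 if rng.random() < 0.8 else 0.0
                    cnvs.append(CopyNumberCall(pid, gene, cn))

            n_panel = len(mutated)
            # extra non-qualifying missense within the actionability genes
            n_vus = int(rng.poisson(cfg.panel_vus_rate))
            vus_genes = rng.choice(
                [g for g, *_ in entries], size=min(n_vus, len(entries)),
                replace=False,
            )
            for g in vus_genes:
                variants.append(_vus_missense(rng, cfg, pid, str(g)))
            n_panel += len(vus_genes)

            high = rng.random() < cfg.high_tmb_rate.get(hist, 0.0)
            n_mmr = 0
            if high and hist == "ENDOMETRIOID" and rng.random() < cfg.mmr_coupling:
                for g in ("MLH1", "MLH1", "MSH6", "MSH6"):
                    variants.append(_vus_missense(rng, cfg, pid, g))
                n_mmr = 4
            lo, hi = cfg.high_tmb_clamp if high else cfg.background_clamp
            mean = cfg.high_tmb_mean if high else cfg.background_mean
            target = int(np.clip(rng.poisson(mean), lo, hi))
            n_bg = max(target - n_panel - n_mmr, 0)
            bg_genes = rng.choice(
                _BACKGROUND_POOL, size=min(n_bg, len(_BACKGROUND_POOL)),
                replace=False,
            )
            for g in bg_genes:
                variants.append(_vus_missense(rng, cfg, pid, str(g)))

            # Pre-filter junk: removed by the VAF / polymorphism / panel-of-
            # normals rules, so none of it reaches TMB or classification.
            for _ in range(rng.poisson(cfg.low_vaf_rate)):
                g = _BACKGROUND_POOL[rng.integers(0, len(_BACKGROUND_POOL))]
                variants.append(
                    _vus_missense(rng, cfg, pid, g,
                                  vaf_pct=round(float(rng.uniform(2, 9.9)), 2))
                )
            for _ in range(rng.poisson(cfg.polymorphic_rate)):
                g = _BACKGROUND_POOL[rng.integers(0, len(_BACKGROUND_POOL))]
                v = _vus_missense(rng, cfg, pid, g)
                v.population_afs = {
                    "gnomad_total": round(float(rng.uniform(0.005, 0.2)), 5)
                }
                variants.append(v)
            for _ in range(rng.poisson(cfg.pon_rate)):
                g = _BACKGROUND_POOL[rng.integers(0, len(_BACKGROUND_POOL))]
                v = _vus_missense(rng, cfg, pid, g)
                v.in_panel_of_normals = True
                variants.append(v)

    return Cohort(patients=patients, variants=variants, cnvs=cnvs)
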