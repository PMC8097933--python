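# oncoact

Pathway-based drug-target actionability analysis for tumor genetic profiles
of epithelial ovarian carcinomas.

Panel sequencing of an ovarian tumor yields small-variant calls (SNVs and
indels with variant allele fractions and OncoKB / ACMG-AMP annotation
columns) and gene-level observed copy numbers. The question a molecular
tumor board asks of such a profile is not "which genes are mutated" but
"which drug targets are plausibly inhibitable, given where the alterations
sit in the signaling cascade". `oncoact` answers that question for cohorts
of high-grade serous (HGS), endometrioid (E) and clear cell (CC) ovarian
carcinomas, over six pathways (DNA repair, RTK, PI3K/AKT/MTOR, RAS/MAPK,
cell cycle, hedgehog), 14 drug targets and 54 genes.

## The method

1. **Sample exclusion.** Samples with tumor purity < 20% (or undetermined)
   are dropped; purities in [20%, 30%) are flagged, since CNV detection —
   gene loss especially — is unreliable there.
2. **Variant filtering.** Only variants with VAF ≥ 10% are kept. A variant
   is a polymorphism, and removed, if any of 24 reference populations
   (1000 Genomes, gnomAD, ExAC subpopulations) reports allele frequency
   ≥ 0.5%, or if it was seen in a healthy-donor panel of normals.
3. **Qualification.** A filtered call is therapy-relevant iff (i) oncogene
   gain (observed CN ≥ 4), (ii) tumor-suppressor loss (observed CN ≤ 1 —
   heterozygous loss counts; the included suppressors are haploinsufficient)
   or truncating/splice variant, (iii) OncoKB (likely) oncogenic variant, or
   (iv) BRCA1/2 variant (likely) pathogenic under ACMG/AMP. Everything else
   is a VUS and excluded from all actionability and frequency statistics.
4. **Actionability.** For drug target *t* with upstream set *U(t)* and
   downstream set *D(t)* in its pathway topology, and a patient's set *A* of
   pathway-activating alterations (oncogene activation or tumor-suppressor
   inactivation):

       S = A ∩ U(t),  D = A ∩ D(t)
       verdict(t) = actionable   if S ≠ ∅ and D = ∅
                    impaired     if D ≠ ∅
                    no_evidence  otherwise

   PARP has no downstream set (synthetic lethality with defective DNA
   repair), and PTEN alterations are invisible to the PIK3CA target.
5. **TMB.** Tumor mutational burden = filtered mutation count (VUS
   included) / 1.247752 Mb; high-TMB means TMB > 18 Mut/Mb.
6. **Cohort statistics.** Histology-stratified alteration and actionability
   percentages, Pearson chi-square comparisons (no continuity correction),
   the high-TMB split, actionability-overlap summaries, and an
   oncoprint-style matrix export.

A synthetic-cohort generator (`oncoact.simulate`) draws cohorts with the
subtype structure the analysis assumes — per-gene, per-subtype alteration
probabilities, a realistic TMB distribution with mismatch-repair-coupled
hypermutator outliers, and pre-filter junk variants — so every stage is
testable without any data download.

## Worked example

```
$ oncoact simulate --seed 7 --out demo/cohort
wrote 82 patients, 1330 variants, 144 CNV calls to demo/cohort
$ oncoact run --cohort demo/cohort --out demo/report
analyzed 82 patients; bundle in demo/report (config 0e1330b0c3358852)
$ grep -E "PARP|MTOR" demo/report/actionability_frequencies.tsv
PARP    HGS             20      37      54
PARP    ENDOMETRIOID    10      22      45
PARP    CLEAR_CELL      5       23      22
MTOR    HGS             30      37      81
MTOR    ENDOMETRIOID    13      22      59
MTOR    CLEAR_CELL      12      23      52
```

Reading: in this simulated cohort 20 of 37 HGS patients (54%) carry at
least one inactivating DNA-repair-gene alteration and are therefore
postulated PARP-inhibitor candidates; MTOR is the most broadly actionable
target because any pathway-activating PI3K/AKT/MTOR alteration sensitizes
it and nothing negates it. The bundle also contains per-patient
actionability calls with their sensitizing and negating genes
(`actionability.tsv`), TMB per patient (`tmb.tsv`), gene-level frequencies
with chi-square comparisons (`frequencies.tsv`, `chisq.tsv`) and an
oncoprint matrix (`oncoprint.tsv`). Per-stage subcommands (`filter`,
`classify`, `assess`, `tmb`, `stats`) expose each step separately, and
`run_log.json` records per-stage record counts for provenance.

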