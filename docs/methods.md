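# Methods

## Data model and filtering

A cohort is a patient manifest (id, histological subtype, tumor purity) plus
two call tables: small variants and gene-level copy numbers. The interchange
format is three TSVs mirroring how such cohorts are published as
supplementary tables; a VCF converter is provided but is not the data model.
Gene symbols are taken verbatim after uppercasing; no alias resolution is
attempted. Duplicate identical variant rows are collapsed on read (they
would double-count in TMB). An empty purity cell means "could not be
determined" and leads to exclusion, the same as purity < 20%; purities in
[20, 30)% are retained but flagged, and the flag is propagated into every
per-patient output row.

Variant inclusion uses three rules with fixed reason precedence
(`low_vaf` > `population_af` > `panel_of_normals`):

* VAF ≥ 10% (inclusive);
* not a polymorphism: no configured reference population — 1000 Genomes
  (global, ASN, AFR, AMR, EUR, AA, EA), gnomAD (total, EAS, AFR, AMR, ASJ,
  FIN, NFE, OTH), ExAC (total, Adj, AFR, AMR, EAS, FIN, NFE, OTH, SAS) —
  reports allele frequency ≥ 0.005 (compared exactly, no rounding of source
  AFs; the disjunction is over populations);
* not present in the panel of normals. The panel is consumed as a
  precomputed boolean column (or a gene/protein-change site list at
  ingestion); it is a fixed donor resource, not something recomputed.

The same VAF rule is applied uniformly to all variants, including BRCA1/2
panel calls and indels.

## Qualification rules

Roles: 27 oncogenes (growth-pathway activating) and 27 tumor suppressors
(pathway-inactivating or DNA-repair genes), shipped as `data/roles.tsv` and
overridable. Rules, in evidence-precedence order
(`acmg_pathogenic` > `oncokb_oncogenic` > `truncating_or_splice` > CN
rules — precedence is bookkeeping only; the effect is identical whenever
several rules fire):

* BRCA1/2 variant, ACMG/AMP (likely) pathogenic → inactivating;
* OncoKB (likely) oncogenic → activating on an oncogene, inactivating on a
  tumor suppressor (the latter reading folds suppressor-inactivating
  annotations into the same therapy-relevant set);
* tumor-suppressor truncating (nonsense, frameshift) or splice variant →
  inactivating;
* oncogene observed CN ≥ 4 → activating; tumor-suppressor observed CN ≤ 1 →
  inactivating. Heterozygous loss counts: the included suppressors are
  haploinsufficient, and observed losses in such cohorts are mostly
  single-copy. The observed copy number is retained on the call so a
  stricter homozygous-only re-threshold is a config change
  (`CnvConfig(loss_max_cn=0)`).

Oncogene missense variants without an OncoKB (likely)-oncogenic annotation
are VUS even at hotspot positions — qualification is strictly
annotation-driven. Calls in genes without a role pass through as VUS.

## Pathway topology

`data/pathways.yaml` encodes, per drug target, the upstream set (genes whose
pathway-activating alteration sensitizes the target, including the target
itself) and the downstream set (genes whose pathway-activating alteration
negates it). Structural invariants validated on load: upstream and
downstream are disjoint per target, every pathway gene appears in at least
one map of some target, and the (PIK3CA, PTEN) exception is present.

Choices where the cascade diagrams leave freedom:

* RTK targets (EGFR, ERBB2, KDR, IGF1R, MET, RET): upstream = the receptor
  itself; downstream = every pathway-activating gene of the PI3K/AKT/MTOR
  and RAS/MAPK branches. Receptor gains do not sensitize downstream-node
  targets by default (`rtk_sensitizes_downstream=False`): receptor-level
  evidence is not credited to inhibitors of nodes below it.
* An alteration *on* a downstream drug target (e.g. MAP2K1 gain) negates
  upstream targets (KRAS) and sensitizes its own target (MEK1/2).
* HRAS and NRAS are context genes of the RAS/MAPK cascade: they negate RTK
  targets but carry no KRAS/MEK map entry of their own.
* PARP and MTOR have empty downstream sets (synthetic lethality; most
  downstream node).

`impaired` is reported distinctly from `no_evidence` so that cohort
percentages can be computed over `actionable` only.

## TMB

TMB = deduplicated filtered mutation count / 1.247752 Mb (the analyzed
panel footprint). VUS count toward TMB — the statistic is defined on
detected mutations, not on therapy-relevant ones — and CNVs never do.
Cross-panel duplicates are collapsed by (gene, protein_change). High-TMB is
strict: TMB > 18 Mut/Mb. All variant rows are counted; whether synonymous
variants should be excluded does not arise because the variant classes
carried by the format are protein-coding and splice classes.

## Cohort statistics

A patient counts once per stratum regardless of alteration multiplicity;
denominators are subtype sizes. Percentages are rounded half-up to integers
for reporting (full precision internally). Chi-square is Pearson's without
Yates correction and without an exact-test fallback; tables with an expected
cell < 5 are flagged, and degenerate tables (all-zero row or column) are
rejected. The actionability-overlap summary uses as denominator the
patients with ≥ 1 qualified alteration in any RTK, PI3K/AKT/MTOR or
RAS/MAPK gene, and as numerator those actionable for at least two of
{any RTK target, MTOR, MEK1/2}.

## Synthetic cohorts

The generator draws, per patient, independent Bernoulli indicators from a
per-(subtype, gene) table of qualifying-alteration probabilities (mutation /
gain / loss), then adds: occasional non-qualifying missense VUS inside the
54-gene universe (Poisson, mean 0.4/patient); a background mutation load
over a 60-gene pool outside the universe that sets the TMB level (Poisson
mean 11.5, clamped to 3–18 so ordinary patients land in the 3.2–16 Mut/Mb
band); hypermutator outliers (27% of endometrioid, 4% of clear cell
patients; counts clamped to 24–34, i.e. 19.2–27.2 Mut/Mb), a third of the
endometrioid ones carrying two MLH1 and two MSH6 variants (a biallelic
mismatch-repair pattern; generated as unannotated missense so they drive
TMB without perturbing the DNA-repair actionability calibration); and
pre-filter junk (low-VAF, population-polymorphic and panel-of-normals
variants) that the filter must remove. Purity is drawn uniform on [35, 95]%
except for a 3/82 fraction in the [20, 30)% flag band. VAFs are normal
(mean 35%, sd 12%) clipped to [10, 90]%.

Where the per-gene frequency was published it is used directly (ERBB2 gain
0.03/0.23/0.22 across HGS/E/CC, combined BRCA1/2 0.30/0/0, ARID1A
0.03/0.32/0.39, NF1 0.14/0/0, PTEN loss-only in HGS and mutation-only in E,
AKT1 0.14–0.18 in HGS/E, KRAS mutation only in E/CC). The remaining entries
were solved once, in closed form under the independence model, so that the
expected per-target actionability percentages match the published ones
(PARP 59/50/48, AKT1 22/45/35, MTOR ≥ 57 everywhere, KRAS 16/18/13, MEK1/2
30/27/13, CDK4/6 41/41/22, PIK3CA within 8–27). Gene co-occurrence is
independent by default; an optional odds multiplier couples PTEN to ARID1A
mutation in endometrioid tumors (`arid1a_pten_odds`, default 1.0), since
the true joint structure is not recoverable from published marginals.

What passing tests on synthetic cohorts do show: the filter, qualification
rules, rule engine, TMB and statistics recover planted structure at scale.
What they do not show: performance on real panels with annotation
conflicts, multi-transcript effects, subclonal VAF structure, or correlated
alteration landscapes (e.g. copy-number-unstable genomes alter many genes
jointly; the independence assumption understates patient-level
co-occurrence).

## Numerical and size choices

* Percent rounding is half-up (`floor(x + 0.5)`), matching printed integer
  percents; banker's rounding would shift exact .5 cases.
* Thresholds are inclusive exactly as stated: VAF ≥ 10, population AF
  ≥ 0.005, gain CN ≥ 4, loss CN ≤ 1; high-TMB is strict (> 18).
* Recovery tests use 2,000 patients per subtype with exact binomial 99%
  confidence intervals; the rule-engine oracle check enumerates all
  alteration subsets of size ≤ 4 over a 10-gene toy topology, and
  monotonicity is checked over 1,000 randomized insertions. All
  randomness is seeded; outputs are byte-stable per seed.

## Known limitations

* The overlap definition above, combined with strict RTK downstream
  negation, makes an actionable receptor target incompatible with an
  actionable MTOR or MEK1/2 (an actionable RTK requires zero
  pathway-activating alterations below the receptor). Overlap as computed
  here therefore consists of MTOR+MEK1/2 pairs only and is substantially
  lower — e.g. for clear cell cohorts — than overlap statistics that count
  receptor sensitization regardless of downstream negation. The
  corresponding reproduction test documents this and fails by design.
* One variant class per row: multi-transcript annotation conflicts (splice
  vs missense on different transcripts) must be resolved upstream.
* Germline vs somatic origin, MSI testing, and survival analysis are out of
  scope; OncoKB/ClinVar are consumed as columns, never queried.
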