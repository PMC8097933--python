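# Declarative topology for the six analyzed signaling pathways, the 14 drug
# targets, and the 54-gene actionability universe.
#
# Semantics per drug target:
#   upstream:   genes whose pathway-activating alteration (oncogene
#               activation or tumor-suppressor inactivation) on or upstream
#               of the target sensitizes it to inhibition;
#   downstream: genes whose pathway-activating alteration downstream of the
#               target impairs (negates) its actionability.
# A target with an empty downstream list cannot be negated (PARP acts via
# synthetic lethality; MTOR is the most downstream node of its pathway).
#
# Receptor tyrosine kinase (RTK) targets are negated by any pathway-
# activating alteration in the PI3K/AKT/MTOR or RAS/MAPK branches they feed.
# HRAS and NRAS carry no KRAS/MEK map entry of their own (context genes of
# the RAS/MAPK cascade); they still negate RTK targets.

pathways:
  DNA_REPAIR:
    genes: [ARID1A, ATM, ATR, BAP1, BLM, BRCA1, BRCA2, CHEK1, CHEK2,
            ERCC1, MLH1, MRE11A, PALB2, PTEN, RAD50]
    targets:
      PARP:
        upstream: [ARID1A, ATM, ATR, BAP1, BLM, BRCA1, BRCA2, CHEK1, CHEK2,
                   ERCC1, MLH1, MRE11A, PALB2, PTEN, RAD50]
        downstream: []

  RTK:
    genes: [EGFR, ERBB2, KDR, IGF1R, MET, RET]
    targets:
      EGFR:
        upstream: [EGFR]
        downstream: &rtk_downstream
          [PIK3CA, PIK3CB, PIK3CG, PIK3CD, PTEN, AKT1, AKT2, AKT3,
           TSC1, TSC2, STK11, NF2, FLCN, FBXW7, MTOR,
           KRAS, NF1, BRAF, HRAS, NRAS, MAP2K1, MAP2K2, MAPK1]
      ERBB2:
        upstream: [ERBB2]
        downstream: *rtk_downstream
      KDR:
        upstream: [KDR]
        downstream: *rtk_downstream
      IGF1R:
        upstream: [IGF1R]
        downstream: *rtk_downstream
      MET:
        upstream: [MET]
        downstream: *rtk_downstream
      RET:
        upstream: [RET]
        downstream: *rtk_downstream

  PI3K_AKT_MTOR:
    genes: [AKT1, AKT2, AKT3, FLCN, FBXW7, NF2, PIK3CA, PIK3CB, PIK3CD,
            PIK3CG, PTEN, STK11, TSC1, TSC2, MTOR]
    targets:
      PIK3CA:
        upstream: [PIK3CA, PIK3CB, PIK3CG, PIK3CD]
        downstream: [AKT1, AKT2, AKT3, TSC1, TSC2, STK11, NF2, FLCN,
                     FBXW7, MTOR]
      AKT1:
        upstream: [PIK3CA, PIK3CB, PIK3CG, PIK3CD, PTEN, AKT1, AKT2, AKT3]
        downstream: [TSC1, TSC2, STK11, NF2, FLCN, FBXW7, MTOR]
      MTOR:
        upstream: [PIK3CA, PIK3CB, PIK3CG, PIK3CD, PTEN, AKT1, AKT2, AKT3,
                   TSC1, TSC2, STK11, NF2, FLCN, FBXW7, MTOR]
        downstream: []

  RAS_MAPK:
    genes: [KRAS, NF1, NF2, MAPK1, MAP2K1, MAP2K2, BRAF, HRAS, NRAS]
    targets:
      KRAS:
        upstream: [KRAS, NF1, NF2]
        downstream: [BRAF, MAP2K1, MAP2K2, MAPK1]
      MEK1_2:
        upstream: [KRAS, NF1, NF2, BRAF, MAP2K1, MAP2K2]
        downstream: [MAPK1]

  CELL_CYCLE:
    genes: [CCND1, CCNE1, CDKN2A, CDKN2B, CDK4, CDK6, RB1]
    targets:
      CDK4_6:
        upstream: [CCND1, CDK4, CDK6, CDKN2A, CDKN2B]
        downstream: [CCNE1, RB1]

  HEDGEHOG:
    genes: [PTCH1, SMO, STK36, SUFU]
    targets:
      SMO:
        upstream: [PTCH1, SMO]
        downstream: [SUFU, STK36]

# PTEN alterations are invisible to the PIK3CA target: PTEN sits beside, not
# upstream of, PI3K in the signaling cascade, and its loss is not considered
# for PI3K-inhibitor sensitization.
exceptions:
  - target: PIK3CA
    gene: PTEN
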