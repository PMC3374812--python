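# Default group/gene weights for the relative recurrence score.
# Reference-derived from the published 21-gene recurrence-score algorithm
# (Paik et al. 2004, NEJM); NOT fitted to any cohort shipped here.
# Positive weights worsen the prognosis orientation of the score.
groups:
  her2:
    genes: [HER2, GRB7]
    weight: 0.47
  hormonal:
    genes: [ER, PGR, BCL2, SCUBE2]
    weight: -0.34
  proliferation:
    genes: [KI67, STK15, SURVIVIN, CCNB1, MYBL2]
    weight: 1.04
  invasion:
    genes: [MMP11, CTSL2]
    weight: 0.10
genes:
  CD68: 0.05
  GSTM1: -0.08
  BAG1: -0.07
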