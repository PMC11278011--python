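# Ordered backbone classification rules.
#
# A gene matches a class when every clause is satisfied by its PFAM
# accession set: a clause {domains: [...], min: k} requires at least k
# *distinct* accessions from the list.  `other_than` additionally
# requires at least one accession outside the listed set.  The first
# matching class in `order` wins, so compositions carrying both PKS and
# NRPS core domains resolve to HYBRID before the pure classes are tried.
#
# Domain shorthand: KS = beta-ketoacyl synthase (PF00109 N-terminal,
# PF02801 C-terminal), AT = acyltransferase (PF00698), PP = carrier /
# phosphopantetheine attachment (PF00550), C = condensation (PF00668),
# A = adenylation / AMP-binding (PF00501), TE = thioesterase (PF00975),
# R = NAD-binding reductase (PF07993), DMATS = tryptophan
# dimethylallyltransferase (PF11991).
#
# NRPS-like ships in two variants: `legend` requires condensation +
# adenylation + a C-terminal thioesterase or reductase; `loose` drops
# the condensation requirement (adenylation + TE/R without the full
# NRPS set).  PredictorConfig.nrps_like_variant selects one.

order: [HYBRID, PKS, NRPS, PKS-like, NRPS-like, DMATS, TC]

pks_specific: [PF00109, PF02801, PF00698, PF00550, PF08659, PF14765]

classes:
  - name: HYBRID
    clauses:
      - {domains: [PF00109, PF02801, PF00698], min: 1}
      - {domains: [PF00668, PF00501], min: 1}
  - name: PKS
    clauses:
      - {domains: [PF00109, PF02801], min: 1}
      - {domains: [PF00698], min: 1}
  - name: NRPS
    clauses:
      - {domains: [PF00668], min: 1}
      - {domains: [PF00501], min: 1}
      - {domains: [PF00550], min: 1}
  - name: PKS-like
    clauses:
      - {domains: [PF00109, PF02801, PF00698, PF00550, PF08659, PF14765], min: 2}
    other_than: [PF00109, PF02801, PF00698, PF00550, PF08659, PF14765]
  - name: NRPS-like
    variant: legend
    clauses:
      - {domains: [PF00668], min: 1}
      - {domains: [PF00501], min: 1}
      - {domains: [PF00975, PF07993], min: 1}
  - name: NRPS-like
    variant: loose
    clauses:
      - {domains: [PF00501], min: 1}
      - {domains: [PF00975, PF07993], min: 1}
  - name: DMATS
    clauses:
      - {domains: [PF11991], min: 1}
  - name: TC
    clauses:
      - {domains: [PF06330, PF01397, PF03936, PF00494, PF13243], min: 1}
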