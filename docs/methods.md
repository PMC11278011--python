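# Methods

## Cluster prediction

The predictor works from gene coordinates (1-based, inclusive, GFF3
convention) and per-gene PFAM domain sets; strand is recorded but never
used.  The intergenic distance between consecutive genes is
`start(next) − end(prev) − 1`.

**Backbone classification.**  An ordered rule table
(`src/smgc/data/backbone_rules.yaml`) maps PFAM compositions to the
seven backbone classes; the first match wins, in the order
HYBRID → PKS → NRPS → PKS-like → NRPS-like → DMATS → TC, so that a gene
carrying both PKS and NRPS core domains is a hybrid rather than either
pure class.  Rules count *distinct* accessions.  The table is data, not
code: the exact accession lists (KS = PF00109/PF02801, AT = PF00698,
carrier = PF00550, C = PF00668, A = PF00501, TE = PF00975,
R = PF07993, DMATS = PF11991, and a terpene-cyclase set) follow the
SMURF lineage and can be edited without touching the package.
NRPS-like ships in two variants: the default requires condensation +
adenylation + a C-terminal thioesterase or reductase; a looser variant
(`nrps_like_variant="loose"`) drops the condensation requirement.
Because the full NRPS rule (C + A + carrier) is evaluated first, the
default variant never shadows it.

**Cluster extension.**  Genes with SM evidence (a backbone composition
or ≥ 1 SM-specific PFAM from `sm_pfams.txt`) are chained: two
consecutive SM genes link when every intergenic gap between them is
≤ `max_intergenic_bp` (default 3000) and at most `max_non_sm_genes`
(default 6) genes without SM evidence lie between them.  Each chain
containing at least one backbone becomes one cluster spanning its
outermost SM genes.  This formulation is equivalent to growing each
backbone seed outward and merging touching extensions, but it also
guarantees the emitted invariants directly: borders always carry SM
evidence, no internal gap exceeds the limit, no internal SM-free run
exceeds six, and raising the gap limit can only grow clusters.

## Pairwise protein comparison

The aligner is the exact affine-gap local dynamic programme (Gotoh)
under BLOSUM62 with gap open 11 / extend 1, where the opening penalty
is charged to the first gap column (a length-L gap costs 11 + (L−1)).
Percent identity is identical columns over aligned columns, gaps
included, as BLAST reports it.  Significance uses the Karlin–Altschul
estimate `E = K·m·n·exp(−λ·S)` with the published gapped BLOSUM62(11,1)
parameters λ = 0.267, K = 0.041 and the raw sequence lengths; no
edge-effect or composition correction is applied, which is
conservative at the protein lengths used here.  Stage-specific e-value
cutoffs: 1e-10 for cluster scoring and dereplication, 1e-5 for
orthology.  Each unordered pair is aligned once (the DP score is
symmetric) and both directions are recorded with their own query
coverage; only the best hit per ordered pair is kept, and self-hits
are excluded (a protein is defined to be 100% identical to itself
where a diagonal is needed).

## Cluster similarity score and families

For a cluster pair the tailoring term uses only tailoring↔tailoring
identities and the backbone term only backbone↔backbone identities;
roles partition the gene set (a backbone gene never also counts as
tailoring).  Within each role the hit identities form a bipartite
matrix that is reduced to a maximum-weight one-to-one pairing
(Hungarian algorithm; `pairing_policy="best_hit_per_query"` gives the
literal many-to-one sum for comparison).  The summed identities are
divided by nmax — the larger of the two clusters' enzyme counts for
that role — and weighted 0.3 (tailoring) and 0.7 (backbone).  The
one-to-one reduction bounds the score at 100 and makes self-similarity
exactly 100.  Degenerate tailoring counts: if both clusters lack
tailoring enzymes the backbone weight is renormalised to 1.0; if only
one lacks them the tailoring term is 0 with nmax from the other
cluster.  Scores above the edge threshold (default 0, i.e. any
positive score) become weighted edges; isolated clusters stay as
nodes.

Families are walktrap communities (random-walk length 4, agglomerative
merge cut at maximal modularity) on the weighted network.  Any
community with more members than the number of species in the analysis
(`max_members`, derived from the data by default) is re-clustered by
one identical round on its induced subgraph — refinement can only
split, never merge — and a community still oversized after that is
accepted with a warning.  Determinism comes from building the graph
with nodes and edges in sorted order; igraph's walktrap is
deterministic given that ordering.  The directional shared-cluster
matrix reports, for species A against B, the percentage of A's
clusters whose family contains at least one cluster from B (diagonal
100); sharing is defined by family co-membership, not by a direct
score threshold.

## Dereplication

Reference clusters are parsed from GenBank with Biopython, keeping CDS
`translation` qualifiers only (no conceptual translation) and records
whose organism matches the taxon filter (default *Aspergillus*,
*Penicillium*).  A family is labelled when any reference protein hits
any member cluster protein at strictly more than `min_pident`
(default 95) with query coverage ≥ `min_query_cov` (default 0.5; the
coverage floor exists because identity over a tiny local alignment is
meaningless).  A single protein hit suffices by default;
`require_multi_gene=True` demands two distinct cluster proteins.
Labels propagate to the whole family and multiple labels concatenate
sorted by accession, so two clusters of one family always agree on
their label set, and lowering `min_pident` can only add labels.

## Orthology and the monocore supermatrix

For each species pair, best hits are by raw alignment score with ties
kept as co-best; two proteins are BBH when each is among the other's
best hits.  Groups form by single-linkage over BBH edges (proteins
without hits become singleton groups); a species represented more than
once in a group — e.g. through an exact duplicate — is dropped from
that group.  Monocore groups have exactly one member in every species.
Selection ranks monocore groups by mean pairwise identity among
members (most conserved first, ties by group id), which is a
deterministic, order-invariant criterion chosen because no published
rule exists for picking among more-than-enough monocore groups.
Concatenation joins each species' members in sorted group-id order;
the exported FASTA is the input for external MAFFT → Gblocks → RAxML
runs, which are out of scope here.

## Synthetic pangenome generator

The generator emulates multi-scaffold annotated genomes with planted,
cross-genome homologous cluster families so that every downstream
stage has exact ground truth.  Defaults, chosen once as the study
conditions: 6 species, 2 scaffolds per genome, 30 background genes per
scaffold, 12 planted families, proteins of 120–240 residues, 2–4
tailoring genes per cluster, intra-cluster gaps 50–1500 bp, background
gaps 150–2800 bp, and cluster-flank gaps 3100–6000 bp.  The flank gaps
deliberately exceed the 3 kb predictor limit so planted extents are
unambiguous; background genes carry only neutral accessions (valid
PFAM format, outside both the SM set and the rule table), so any
predictor false positive is attributable to the predictor.  The
default presence design makes each family a singleton with
probability 0.25 and otherwise spans a uniform 2–n subset of species;
explicit per-family subsets or a Bernoulli presence probability can be
configured.

Proteins mutate by substitutions only (no indels), drawn uniformly
from the 19 alternative residues, with an exact-count policy
(`floor((100 − identity)/100 × len)` positions), so identity is
controlled exactly.  `target_identity` refers to the *pairwise*
identity between cross-genome homologs: each species copy diverges
from the family prototype by the per-copy fraction `d` solving
`(1 − d)² + d²/19 = t`, which keeps the measured copy-to-copy identity
on target (independent divergence from a common ancestor compounds;
naively mutating every copy to `t` would give pairwise ≈ t²).

What the simulator does *not* emulate — and therefore what passing
tests do not show about real data: nucleotide sequences and introns,
realistic PFAM e-value or domain-architecture distributions, gene
gains/losses and rearrangements within clusters, shared tailoring
domains between unrelated families, fragmented assemblies, and
annotation noise.  On real genomes, cluster boundaries are genuinely
ambiguous and family recovery will be imperfect; the synthetic results
demonstrate correctness of the machinery, not field accuracy.

## Numerical and engineering choices

- All randomness flows from one `numpy` Generator seeded by the
  configuration; identical (config, seed) produce byte-identical
  output files (writers emit sorted rows; domain e-values are written
  and re-read exactly, with `float_precision="round_trip"` on input).
- Score ties in best-hit selection resolve to the first-seen hit over
  sorted protein ids; walktrap ties follow sorted graph construction.
- Problem sizes in the drivers and acceptance script (6 species, 12
  families, ~190 cluster proteins) are the package's desk-scale study
  conditions; the pipeline itself has no size assumptions and the
  aligner cost grows with the square of proteome size, so full-genome
  comparisons of real data are better served by pointing the same
  `HitTable` interface at external BLAST output (outfmt-6-compatible
  reader in `smgc.align`).
- Empty inputs degrade explicitly: no backbone → no clusters; empty
  family list → zero statistics; a cluster without a backbone anywhere
  downstream is a hard error, as it violates the cluster invariant.

## Known limitations

- The SM-specific PFAM list and backbone accession lists are curated
  defaults, not a published enrichment analysis; both are editable
  data files and results depend on them.
- The Karlin–Altschul parameters are those of BLAST's gapped
  BLOSUM62(11,1) mode; e-values for very short sequences (< ~30
  residues) are optimistic.
- Walktrap is run with a fixed walk length (4); no parameter sweep is
  performed, and a community still oversized after one refinement
  round is accepted as-is.
- Dereplication is only as good as the reference snapshot provided;
  the package bundles none and tests use synthetic records.
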