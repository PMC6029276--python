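# Methods

This note documents the models, algorithms and numerical choices
behind `divcover`, the assumptions they make, and what the synthetic
studies do and do not demonstrate.

## Problem setting

The quantity of interest is, for each named cluster `C` of a clade's
rRNA tree, the *sequenced genome fraction*
`f(C) = n_genome_backed(C) / n_otus(C)`, where an OTU is genome-backed
iff its dereplication cluster contains at least one genome-derived
sequence.  `f` is kept as an exact rational throughout and only
rendered to three decimals in reports.  The classification boundary is
strict: `f < 1/100` means *unsequenced*; `f = 1/100` is sequenced.
Cohort summaries (min, median, IQR) are computed over sequenced
clusters only — including the zero-fraction clusters would make the
minimum trivially zero and hide the information the summary is meant
to carry.  Quantiles use linear interpolation (the numpy default);
the report header records this.

## Sequence handling

All sequences are normalised on ingest: upper-case, `U → T`, and every
IUPAC ambiguity code collapsed to `N`.  Identity and entropy
computations thus see a single degenerate symbol, and `N` never counts
as a match or as an observed base.  Gap characters are forbidden in
unaligned input.

## Dereplication

Clustering reproduces the incremental greedy scheme of cd-hit-est
without the k-mer prescreen: records sorted by (length descending, id
ascending); each record joins the first-founded cluster whose
*representative* passes all three gates, else founds a new cluster.
Gates: identity ≥ 0.975, shorter-sequence coverage ≥ 0.9,
longer-sequence coverage ≥ 0 (unconstrained).  Identity is the number
of identical aligned positions divided by the length of the shorter
sequence — the denominator under which the asymmetric 0.9/0.0
coverage pair is meaningful.  The pairwise alignment is global with
free terminal gaps, scored match +1, mismatch −1, gap open −2, gap
extension −1 (the opening position costs −2, each further position
−1).  These scores are pinned package-wide; they are a deliberate,
documented stand-in for CD-HIT's internal defaults.  Skipping the
prescreen makes the result exactly the greedy definition and is
affordable at desk scale (the all-candidates scan is O(n·k)
alignments).

After clustering, any cluster containing a genome-derived member but
represented by a non-genome record has its representative replaced by
a genome member (longest first, then id ascending).  The partition is
untouched; only the representative label changes.  This is what makes
a phylogenomic constraint expressible on the rRNA tree: backbone taxa
must appear as tree leaves, and tree leaves are cluster
representatives.

## Seed-alignment extension

New sequences are threaded into a curated seed alignment by global
alignment against the seed's majority-rule consensus (gap counted as a
fifth state; a column over 50% gaps yields a consensus gap, ties among
bases break alphabetically).  Aligned residues drop into the
corresponding seed columns; residues that fall inside consensus-gap
runs — insertions relative to the seed — are discarded rather than
given new columns, since a column present in only one added sequence
would exceed the 20% gap cut-off and be trimmed anyway.  Seed rows and
the column count are never modified (checked byte-for-byte in tests).
A sequence with fewer than half its residues placeable is rejected
into a skip report instead of being force-fitted.

This consensus-threading is a deterministic, dependency-free profile
aligner.  It is exact when added sequences have no insertions relative
to the seed (the synthetic default) and degrades gracefully — dropped
insertions, never disturbed seed columns — when they do.

## Column trimming

Per column: `entropy = −Σ p_i ln p_i / ln 4` over the observed A/C/G/T
frequencies (columns with no bases score 1.0, maximally
uninformative), and `gap_fraction = gaps / rows`.  A column is kept
iff entropy ≤ 0.5 **and** gap_fraction ≤ 0.2.  This is plain
normalised Shannon entropy, not a similarity-matrix-smoothed variant:
for nucleotides the smoothed form reduces nearly to this, the same
cut-offs transfer, and the plain form has closed-form test values
(e.g. frequencies 0.7/0.1/0.1/0.1 give 0.6784).  No sliding-window
smoothing and no minimum block size are applied, keeping the operation
per-column and order-independent; both are natural future options.
The trimmed alignment's missing-character fraction (gaps + N over
cells) is reported as a quality metric.

Note the deliberate consequence of a two-state ceiling: a 50/50
two-base column has exactly 1 bit = 0.5 normalised entropy and is
kept; any column with three well-represented bases is removed.

## Distances and tree inference

Distances are Jukes–Cantor with pairwise deletion: sites where both
rows carry a plain base; `d = −(3/4) ln(1 − 4p/3)`; saturated pairs
(`p ≥ 0.75`) are capped at 5.0 substitutions/site to keep the matrix
finite.  JC replaces a full GTR+Γ likelihood machinery on purpose: the
tested contribution here is the *constraint-plus-coverage* procedure,
not the substitution model, and JC has closed forms the tests can pin.
The distance module is the designated swap point for a likelihood
engine.

The constrained search is minimum evolution under OLS:

1. Start from the backbone topology; branch lengths are refit by OLS.
   The normal equations are assembled combinatorially — two edges of a
   tree are either nested or disjoint, giving closed forms for every
   entry of `AᵀA`, and `Aᵀd` per edge is the distance mass crossing
   it — so a refit is O(n²) rather than a naive least squares over
   all pairs.
2. Insert every non-backbone taxon, in ascending id order, on the edge
   minimising total fitted tree length (negative OLS estimates clamped
   to zero before summing); ties break to the lowest edge index in a
   fixed postorder.  Leaf insertion can never remove an induced
   backbone split, so the constraint is maintained by construction.
3. NNI hill-climbing on the same criterion, scanning edges in a fixed
   postorder with first-improvement and a strict-decrease threshold of
   1e-10; any rearrangement whose induced backbone topology would lose
   a backbone split is rejected outright.

The output therefore always satisfies the containment
`splits(backbone) ⊆ splits(tree | backbone taxa)` — the invariant the
whole design rests on — and is byte-deterministic for identical
inputs.  On additive distances the procedure recovers the generating
topology exactly (verified up to 12 taxa against exhaustive-placement
oracles).  OLS (unweighted) rather than balanced ME was chosen as the
simplest criterion with an exhaustive oracle; branch lengths reported
are the final OLS fit with negatives clamped to zero.

## Rooting and collapsing

The tree is rooted at the midpoint of the edge subtending the outgroup
clan; a non-monophyletic outgroup is a hard error that names the
intruding taxa.  Cluster collapsing takes an OTU → label map: each
label is reported whole with a monophyly flag (true iff the MRCA of
its OTUs contains no differently-labelled leaf).  Paraphyletic labels
are *not* split into monophyletic pieces — the label, not the subtree,
is the unit a sequencing decision is made about.

## Synthetic studies

The generator emulates the structure of a genome-representation survey
with every truth value known:

* **Species tree** — pure-birth (Yule) topology, rescaled to an
  ingroup depth of 0.25 substitutions/site, plus a floor of 0.1 on the
  pairwise divergence between any two species (half the floor added to
  every terminal branch).  The floor guarantees that between-species
  identity stays safely below the 97.5% threshold at the simulated
  sequence length, so dereplication recovers the species partition
  exactly — the regime the identity threshold is designed for.
* **Sequences** — HKY (kappa = 2, equal base frequencies, rate matrix
  normalised to one substitution per site per unit branch length) via
  per-branch transition matrices; no indels by default, so the true
  alignment is the sequence matrix itself and seed extension is exact.
  Sequences default to 450 nt — the length of a V3–V4-style amplicon,
  and a size at which a full study (about 120 records, 68 OTUs) runs
  in tens of seconds.
* **Database records** — 1–3 records per species; replicates mutated
  at 0.3% per-site divergence (an order of magnitude inside the
  threshold); a genome-flagged species contributes its exact sequence
  as the genome record; remaining records are tagged
  reference : collection at 9:1.  A couple of records receive a
  deliberately incongruent lineage, and a few genome accessions appear
  in the metadata with no sequence — exercising both merge filters.
* **Genome availability** — flags drawn per species (the organism,
  not the record, is the unit of "sequenced") with its clade's
  probability.  The default twelve clades use probabilities
  (0, 0, 0, 0, .5, .5, .7, .7, .9, .9, 1, 1): the four zero-probability
  clades are the planted unsequenced diversity.  Clades with positive
  probability are conditioned on at least one flagged species, and
  flags are topped up (within positive-probability clades only) when
  fewer than `backbone_size` species were drawn — a sequenced clade is
  sequenced by construction, and a backbone always exists.
* **Backbone and seed** — the true tree restricted to 20 flagged
  species, with leaves renamed to their genome record ids (emulating a
  *correct* phylogenomic constraint), and a stratified seed alignment
  holding about half the species per clade.
* **Outgroup** — a separate clan of 8 species on a 0.4
  substitutions/site stem, guaranteeing outgroup monophyly so rooting
  is testable in both directions.

What passing tests on these studies show: the pipeline's bookkeeping
is exact, the constraint is genuinely enforced, and the coverage
statistic recovers planted truth whenever dereplication resolves
species correctly.  What they do not show: behaviour under indels,
chimeras, rRNA secondary-structure alignment effects, intragenomic
rRNA copy variation, GC heterogeneity, or taxon sampling biases of
real databases — the generator's clean separation of within- and
between-species divergence is an idealisation of exactly the property
the 97.5% threshold presupposes.

## Problem sizes and determinism

Default study conditions are 60 ingroup species in 12 clades,
backbone 20, outgroup 8, 450 nt sequences; test sweeps run 20 such
studies, and smaller fixtures (12 species) back the unit tests.  All
randomness flows from a single integer seed through
`numpy.random.default_rng`; studies, trees and reports are
byte-identical across reruns with the same seed.

## Known limitations

* The entropy trimmer conditions on column conservation, which biases
  JC distances downward on deep trees; topology is generally
  preserved but absolute branch lengths are not interpretable after
  trimming.
* ME insertion is greedy; NNI repairs most but provably not all
  insertion-order artefacts on non-additive distances.  The backbone
  constraint bounds the damage where it matters.
* The congruence filter is an allow-list on lineage strings, not a
  taxonomy graph; records with an empty lineage are trusted.
* No bootstrap support values are computed; downstream coverage
  statistics do not consume them.
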