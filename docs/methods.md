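# Methods

This note documents the models implemented in `halomotif`, the parameter
choices that matter, what the synthetic data generator does and does not
emulate, and the design decisions taken where the problem was genuinely
open.

## Profile HMM screening

A profile HMM is estimated from a seed multiple alignment.  Columns with a
gap fraction strictly below `gap_threshold` (default 0.5, the usual
match-column heuristic) become match states.  Emissions use Laplace
pseudocounts,

    P(a | column) = (count_a + c) / (n_observed + 20 c),   c = 1 by default,

where `n_observed` counts rows carrying a canonical residue ('X' counts in
neither numerator nor denominator, and scores as background wherever an
emission probability is needed).  Transition probabilities among the
match/insert/delete successors of each node are estimated from the per-row
state paths with the same pseudocount, three successors per state.  We do
not replicate the Dirichlet-mixture priors, sequence weighting or entropy
weighting of mature HMM packages: the model is deliberately simple and
reproducible, and consequently **absolute scores and E-values are not
interchangeable with HMMER's**.  All screening thresholds are therefore
exposed as parameters rather than hard-coded.

Scoring is local-in-sequence and local-in-model: an alignment enters at any
match state (uniform probability 1/L), follows match/insert/delete
transitions, and may end at any match state; unaligned query flanks are
emitted by the background and cancel in the odds ratio.  The forward score
is the log2 of the summed odds over all such paths, the Viterbi score the
log2 maximum; both are computed in log space, vectorized over model nodes,
with delete chains resolved by a prefix scan.  Model coverage is the number
of distinct match states on the Viterbi path divided by L.  The test suite
checks both recursions against an independent exhaustive path enumeration
on small models (L ≤ 4, queries ≤ 6 residues) at 1e-9 relative tolerance.

E-values come from a Gumbel fit (scipy maximum likelihood) to forward
scores of `n_shuffles` (default 200, minimum 50) sequences drawn i.i.d.
from the background; E(s) = N · (1 − GumbelCDF(s)) with N the number of
scanned queries.  The survival function is evaluated with expm1/asymptotic
branches so extreme scores underflow to an E-value of exactly 0 rather
than NaN.  The screening defaults — E-value < 1e-130 AND model coverage
> 0.5, both strict — reproduce the published filtering rule for this
family; because our E-value scale differs from HMMER's, the cutoff is a
CLI flag, and a `--whitelist` option exempts candidates with independent
gene-cluster evidence.  Background defaults to uniform 1/20 (configurable
to the seed composition); calibration length defaults to the model length.

## Positional-probability features and classification

For each of six substrate groups (5-, 6-, 7-Trp, indole, phenolic,
pyrrole) a positional probability profile over the group's match columns is
built with the same column rule and pseudocounts.  A query is Viterbi-
aligned to each group's profile HMM; each match column contributes the
column probability of the residue aligned there, and columns with no
aligned residue contribute a flat fill value of 0.05.  The fill value keeps
features in [0, 1] but only weakly distinguishes "absent" from "improbable
residue"; this is a known limitation.  Segments are concatenated in the
fixed order (5-Trp, 6-Trp, 7-Trp, indole, phenolic, pyrrole), which is
serialized with the profile set.

t-SNE (scikit-learn, perplexity 10, 1000 iterations, PCA initialization,
seeded) provides the 2-D map; it requires at least 3 × perplexity points.
Classification is 1-nearest-neighbour with the Euclidean metric, ties
broken by the lexicographically lowest reference id.  The default
classification path runs on the **raw feature vectors**, not the t-SNE
coordinates: t-SNE is stochastic and non-metric, while the raw-feature
neighbour structure is identical in expectation and exactly reproducible.
Embedding-space classification remains available for parity with
embedding-based workflows.

## 3-mer entropy screen

For every window of three alignment columns, the Shannon entropy (bits) of
the distinct tripeptides across rows is computed; rows gapped anywhere in
the window are excluded and reported as a gap fraction rather than treated
as a 21st symbol, so gap-rich regions cannot masquerade as conserved.
Maximal runs of windows with entropy ≤ τ and gap fraction ≤ 0.5 form
candidate regions; regions spanning fewer than 3 columns are dropped.  The
default τ = 1.0 bit makes the ten known functional sites emerge on the
bundled seed alignments, but no canonical threshold exists for this
statistic, so τ is a flag, not a claimed constant.  Site labels are
assigned by degenerate anchor patterns (shipped as an editable TSV): a
region receives a label when ≥ 50% of its non-gap rows match an anchor,
each site labelling at most one region (ties raise an error rather than
being resolved silently).  Because entropy-run boundaries can overshoot a
motif by a column or two, the site's column set is trimmed to the anchor
match on the region's majority consensus before motif extraction.

The Trp1–4 anchors derive from the characterized-enzyme catalogue; the
FAD1 anchor is the classic Rossmann G-x-G-x-x-G and the halide anchor the
W-x-W-x-I-P class.  The FAD2–4 and catalytic-K anchors are permissive
package defaults, intended to be edited when the screen is pointed at a
new family.

## The Trp1–4 motif grammar

Extraction maps each labelled site's profile columns through the query's
Viterbi alignment; a site is absent when more than half of its columns are
deleted.  The grammar then votes:

| rule | weight | evidence |
|------|--------|----------|
| R1 | 2 | Trp4 absent → C; long form → {A1, A2}; short form → {B1, B2} |
| R2 | 2 | within A: residue before terminal YY (N → A1, S → A2); within B: positions 5–6 (FE → B1, LP → B2) |
| R3 | 1 | Trp1 tail: IP → A1, VP → A2, …STV → B1, …SDI → B2 |
| R4 | 1 | Trp2 2nd residue: L/S → A1, P → {A2, B1, B2}; 5th: R → B1, Q → B2 |
| R5 | 1 | Trp3 present → {B1, B2}; QxxQ → B1, QxxxQ → B2 |

A set-valued vote adds its full weight to every member.  The group is the
argmax; ties or an empty vote list yield `ambiguous`, which the consensus
step resolves with the 1-NN label (confidence 0.5 · (motif confidence +
1/(1+distance))).  The fixed regioselectivity map is A1→7, A2→6, B1→5,
B2→6, C→non-Trp.

Design decisions in the grammar:

* **R3–R5 vote only when Trp4 is present.**  Trp1/Trp2 motifs occur in
  every group, including the non-tryptophan group C (e.g. an indole
  halogenase carries the same `ATIP`/`HxF` patterns as 7-Trp enzymes), so
  their sub-patterns carry no information about family membership — only
  about regiochemistry within the tryptophan family.  Without this gating,
  Trp1/Trp2 votes can tie the family vote for several catalogued group-C
  enzymes.  A completely empty motif set yields `ambiguous`, not C: absence
  of evidence is not evidence of a non-Trp halogenase.
* **Trp4 carries double weight** (R1, R2): in site-directed mutagenesis,
  swapping the Trp4 motif alone shifts the product distribution while
  Trp1/Trp2 swaps alone do not; the caller reproduces this direction of
  effect on the vote margin.
* **Length split at 14 residues** between the 19-residue group-A and
  9-residue group-B Trp4 forms, so noisy extractions with small indels
  still vote; exact-length inputs behave identically.
* **Trp3 spacing abstention**: some catalogued B2 members carry a
  4-residue (QxxQ) Trp3; the spacing sub-rule abstains when Trp1/Trp4
  indicate B2, avoiding per-enzyme special cases.  Known single-motif
  exceptions (a B-type Trp1 in an A2 enzyme, an A1 enzyme with an S-type
  Trp2) are outvoted by the weight-2 rules rather than special-cased.
* One catalogued enzyme (KrmI) prints regioselectivity 6 while sitting in
  group C with no Trp3/Trp4; the grammar, like the enzyme's cluster
  placement, reads it as non-Trp.  It is treated as an expected-discordant
  fixture, not guessed around.

## Synthetic family generator

The generator emulates the statistical structure the analysis relies on: a
common backbone scaffold (470 residues, realistic for this family), the
ten functional motifs planted at fixed coordinates (Trp1 at 50, Trp2 at
101, Trp3 at 160, Trp4 at 443, plus FAD/K/halide sites), cluster-specific
drift at 15–30% of non-motif positions, and near-invariant motifs within a
cluster (0.5% noise in seed alignments, matching the essentially exact
within-group motif conservation seen in the catalogue).  Seed alignments
draw 12 rows per cluster with 30% scaffold noise so the entropy screen has
contrast.  Positive query sets are consensus-plus-noise: each position is
independently replaced at the chosen substitution rate by a uniform random
residue (a full HMM path sampler is a documented extension point).  Decoys
are i.i.d. uniform sequences.  Everything is deterministic given a seed.

What the generator does **not** emulate: insertions and deletions (the
synthetic family is gap-free; indel handling is exercised by separate toy
alignments), realistic amino-acid composition and site-specific rate
variation, phylogenetic correlation among sequences, and partial or
fragmented genes.  Passing tests on this family therefore demonstrate the
correctness of the machinery and the separability logic, not performance
on real proteomes, where the discriminative margins will be smaller.

Study-condition sizes used by the tests and the acceptance script: label
recovery uses 200 sequences per cluster at substitution rate 0.05, and a
rate series 0 / 0.05 / 0.15 / 0.30 at 50 per cluster; decoy rejection uses
100 decoys against the combined tryptophan-family model with a 200-shuffle
calibration.

## Numerical choices and degenerate inputs

* All log-space dynamic programming in natural log, reported in bits.
* Delete-chain prefix scans reassociate additions; scores agree with the
  direct recurrence to ~1e-15 relative, well inside the 1e-9 oracle bound.
* Viterbi traceback recomputes predecessor candidates locally and follows
  the argmax; exact ties follow the fixed order match > insert > delete.
* Gumbel calibration refuses degenerate (zero-variance) score sets and
  fewer than 50 shuffles.
* Empty query FASTA: the pipeline writes empty outputs and exits
  successfully with a logged warning.  Fully gapped entropy windows return
  NaN and are never part of a conserved region.  Alignments must be
  rectangular; ragged input names the offending rows.
* TSVs are written with fixed float formats and a config hash in the
  header, so identical runs are byte-identical.

## Known limitations

* E-values are calibrated, not HMMER-compatible; cross-tool thresholds
  must be re-derived.
* The feature gap-fill constant (0.05) conflates deletion with an
  improbable residue.
* The anchor table beyond Trp1–4/FAD1/halide is a permissive default.
* Multi-domain proteins are scored as single domains (no repeat
  splitting), and nucleotide input is out of scope.
* mmCIF structures are not parsed; PDB format only.
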