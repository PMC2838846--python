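# Methods

## Overview

`kinomeprofiler` re-implements, as a self-contained pipeline, the comparative
kinome analysis used for fungal proteomes: identify putative protein kinases
in a predicted proteome by profile-HMM bit score, classify each one into one
of the 12 kinase groups (AGC, Alpha, CAMK, CK1, CMGC, PDHK, PIKK, RGC, RIO,
STE, TK, TKL), annotate the flanking domain architecture of the predicted
kinases, and compare species by kinome composition, kinome density and
domain-frequency ordination.

## Profile HMM scoring

A model is the standard match/insert/delete profile architecture: L match
states with position-specific emission distributions over the 20 amino
acids, L+1 insert states (insert 0 precedes the model), delete states, and a
null model of background residue frequencies. Transition probabilities are
stored per node as the seven quantities M→M, M→I, M→D, I→M, I→I, D→M, D→D;
node 0's match state is the begin state, and at node L the "next match" is
the end state (so M→D and D→D are structurally zero there).

Scores are log-odds in bits: log2 of the probability of the sequence (and a
state path) under the model divided by its probability under the null. The
**Viterbi** score maximises over paths and is the classification score
throughout; the **forward** score (log-sum-exp over paths) is provided for
completeness but is off by default, matching the behaviour of the
Viterbi-based search scores the original analysis consumed.

Two alignment modes exist:

* **glocal** — the whole model against the whole sequence; used for unit
  checks and model diagnostics.
* **local** (default for searching) — the model matches a subsequence.  The
  path enters any match state with uniform probability 1/L (a fixed
  −log2 L entry cost), exits from any match state at no cost, and the
  flanking residues outside the hit are emitted by the null model, so they
  contribute exactly zero bits.  This convention is simple enough to verify
  by brute-force path enumeration, which the test suite does for every model
  length ≤ 3 and sequence length ≤ 5 (agreement within 1e-6 bits; observed
  agreement is at machine precision).

Numerical choices: all dynamic programming is in log2 space; log of a zero
probability is floored at −1e6 bits rather than −inf, which keeps every
score finite (an invariant of the API) and keeps the delete-chain
prefix-sum recurrence free of NaN from −inf arithmetic.  An astronomically
penalised path can never win, so the floor does not affect any score of
practical magnitude.  Residues outside the 20-letter alphabet (ambiguity
codes, normalised to `X` on input) emit with null probability and therefore
contribute zero bits wherever they are aligned.

Proteome-scale scanning batches the DP: one sequence against a stack of
models of equal length, and blocks of ~64 length-sorted sequences padded to
a common length, with per-sequence score updates masked so padding cannot
leak into results.  The batched path is asserted equal to the per-sequence
path in the tests.

Model construction from alignments uses the common maximum-likelihood recipe:
columns with gap fraction < 0.5 become match states, counts receive add-one
(Laplace) pseudocounts (constant configurable), and the null model defaults
to the alignment's overall residue frequencies.  Models serialise to a
versioned JSON schema (`khmm-1`); a best-effort importer for HMMER3 ASCII
files maps their emission/transition tables onto this representation (it is
not bit-exact with HMMER's own scoring, and ignored fields are reported in a
warnings list).

## Kinase classification

Each protein is scored in local mode against every model of the group
library; a group's score is the maximum over its models (libraries may carry
more than one model per group).  A protein is called a kinase when its best
score is **strictly greater than the cutoff**, default 20 bits; the
best-scoring group wins, and exact ties break to the lexicographically
smallest group name for determinism.  There is deliberately no "Others"
category: sub-threshold proteins are simply absent from the kinome while
still counting toward proteome size, a choice that favours precision over
recall.  The 20-bit default follows the rule of thumb that a score above
log2 of the number of sequences in the searched database indicates a true
homologue; proteomes of 10^4–10^6 proteins put that at roughly 13–20 bits,
and `recommend_cutoff(n)` computes the rule for any n.  E-values are
intentionally not computed: a fixed bit cutoff gives the same criterion in
every species, which is what makes cross-species counts comparable.

## Domain annotation

Only proteins already called as kinases are scanned against the domain
library (pipeline order: classify first, then annotate).  Hits above a
significance threshold — default 20 bits, the same spirit as the kinase
cutoff, since per-family curated gathering thresholds do not exist for toy
libraries — are reported with 1-based inclusive envelope coordinates from a
Viterbi traceback.  Multiple non-overlapping copies of one domain on one
protein are found by re-scanning the flanks around each accepted hit and
each copy counts separately.  Envelopes of different domain types that
overlap by more than 50% of the shorter envelope are resolved in favour of
the higher score, to avoid counting one region under two related models.

Seven domain types are *catalytic* (kinase enzymatic activity): Pkinase,
Pkinase_C, PI3_PI4_kinase, BCDHK_Adom3, RIO1, Pkinase_Tyr, Alpha_kinase.
Everything else is *accessory* — including HATPase_c, whose ATPase activity
is not kinase activity.  Corpus summaries report totals, the
catalytic/accessory split, per-kinase means (unrounded, plus a 1-decimal
display rounding), type counts and singleton types.

## Comparative statistics

Per species: group counts over all 12 groups (structural zeros such as RGC
are reported — their absence is itself informative), normalized frequencies
(percent of the species' kinome, summing to 100), and **kinome density**,
expressed as a percentage: 100 × kinases / proteome size.  Cohort tables
keep species-table order, and mean kinome size is reported per clade.

Densities of two clades are compared with the two-sided unpaired Wilcoxon
rank-sum (Mann–Whitney U) test.  The p-value is exact (full null
distribution of U) when there are no ties and both samples have ≤ 25
observations, otherwise a tie-corrected, continuity-corrected normal
approximation — the same switching rule as R's `wilcox.test`.  The
implementation delegates to `scipy.stats.mannwhitneyu`; the test suite
checks it against an independent enumeration over all rank assignments for
every sample-size pair up to 8, and checks the exact test's null rejection
rate at α = 0.05 (discreteness makes it conservative, ~4–5%).  A fully tied
input returns p = 1 explicitly.

## Domain-frequency PCA

Each species' row is the percentage of each domain type among **all domain
occurrences in that species' kinome**.  The denominator is an interpretive
choice: per-species domain totals make rows comparable across kinome sizes,
which is the property an ordination of compositions needs.  Domain types
present in fewer than half of the species are dropped (threshold
configurable; "at least half" is inclusive, ceil(n/2) species).  PCA is the
eigendecomposition of the covariance of the centered rows (variance scaling
off by default, matching the common R default); each component's sign is
fixed by making its largest-magnitude loading positive so results do not
depend on the linear-algebra backend.  Tests verify agreement with an
independent SVD oracle at 1e-8.  Species are projected onto PC1–PC3 with
clade labels attached; fewer than three components are zero-padded and
flagged.

Clusters are not formally assigned — ordination plots are judged by eye — so
a numeric surrogate is provided for testing only: a silhouette-style
separation score in [−1, 1] (nearest-other-clade mean distance minus
own-clade mean distance, over the larger of the two, averaged; singleton
clades contribute 0).

## Synthetic benchmark data

Real cohort reconstruction needs dozens of proteomes plus curated HMM
libraries, so testing uses generated miniatures with full ground truth.

* **Toy libraries** — one model per group (or domain type), each built on a
  random consensus with peak emission weight chosen so the total-variation
  distance between differing consensus columns equals the requested
  `divergence` (default 0.9 → peak 0.905); consensi are re-drawn until all
  pairwise identities are < 30%.  Transitions are match-dominated
  (M→M 0.99).
* **Planted kinases** — a consensus walk with emission noise (each residue
  drawn from its match-state distribution) embedded in null-model flanks;
  full stochastic traversal of insert/delete states is available by flag but
  off by default so score margins stay controllable (planted hits score
  ~120–140 bits against their own model, background sequences < 20).
* **Cohorts** — the default design has two clades of 8 species with planted
  kinome-density means 0.5% and 1.2% (SD 0.1), mirroring the magnitude of
  the density contrast seen between filamentous and yeast-like fungi, and a
  kinase-group profile echoing the observed distribution (AGC/CAMK/CMGC/STE
  ≈ 88% of the kinome, RGC empty).  Each kinase carries one catalytic
  domain plus Poisson(2.0) accessory domains drawn from clade-specific
  profiles whose total-variation separation is ~0.6.  Desk-scale choices:
  1500 background sequences of 150–350 residues per species (real proteomes
  are 5–20× larger), and an accessory rate well above the ~0.3 per kinase
  seen in real fungal kinomes — with only a handful of kinases per toy
  species, compositions would otherwise be pure noise.  These sizes keep a
  full cohort analysis under ~2 minutes on one core.

What passing these tests shows — and does not show: the machinery correctly
recovers group labels, densities and clade-level domain structure that are
actually present at the planted margins.  Synthetic sequences are
i.i.d.-background with clean planted segments; they do not emulate real
amino-acid composition, homology between groups, gene-model errors,
alternative isoforms or shared domain architecture between clades, so
performance on real proteomes depends on the quality of the supplied HMM
libraries in ways these tests cannot measure.

All generators are deterministic under their seed (per-species generators
are seeded by sequence, so streams are independent of each other and of the
library streams), and a cohort regenerated with the same design is
byte-identical — as are all pipeline reports under a fixed config, which the
tests verify by double-run comparison.

## Known limitations

* HMMER3 import is best-effort, not score-compatible with HMMER.
* No E-value statistics, no model calibration, no sub-group (family-level)
  classification, no clan-aware domain grouping.
* Homology-based functional annotation and phylogenetic tree building are
  out of scope; `classify --export-group-fastas` emits per-group FASTA files
  so external aligners/tree builders can take over.
* The Wilcoxon normal approximation is used whenever ties occur, even for
  tiny samples, where its accuracy is limited (as with any rank test).
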