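# Methods

`epinet` has two halves that meet in a shared classifier: a discrete
simulator that exhaustively explores small gene-regulatory network
models and asks which topologies can produce particular
genetic-interaction patterns, and an expression-data pipeline that
calls those same patterns in double-mutant expression profiles.  This
note records the models, the parameter choices and their rationale, the
places where the design was genuinely open, and what the synthetic data
do and do not establish.

## The model space

A model couples two upstream regulators (R1, R2) to two downstream
genes (G1, G2) through signed, weighted edges drawn from
{0, ±1, ±W}: weak or strong activation or inhibition, with W = 5 by
default and W = 9 as a sensitivity setting.  A topology is a 4×4
integer matrix (rows = edge source, columns = edge target).  Three
structural conditions prune the 5¹⁶ raw space to 9,287,616 matrices:
no self-edges; at most two incoming edges per node; and at least two
regulator-to-gene edges that share a source regulator or a target gene.
The third condition excludes the degenerate case in which the only
regulator-gene edges form a "crossing" pair (R1→Ga, R2→Gb with a ≠ b),
i.e. two fully independent one-regulator/one-gene systems; the counting
identity (61 admissible incoming-edge states per node; 2,496 admissible
joint gene-column states) pins this reading down, and
`model_space.count_matrices` verifies it in closed form against the
streamed enumeration.

Matrices come in mirror families under relabeling R1↔R2 and/or G1↔G2.
One representative per orbit is kept: the lexicographic minimum in a
fixed row-major base-5 digit order.  The orbit count of the constrained
space is 2,324,136.  (A historical count of this model family reports
2,323,936, a 200-orbit difference whose origin is a deduplication
detail not recoverable from the available description; the package
reports its own exactly reproducible orbit count.)

Each canonical matrix expands into Petri-net model variants by input
logic.  A node with two incoming edges of equal magnitude ("same
weight") yields an AND and an OR variant; two incoming edges of
different magnitude combine with OR only; nodes with at most one input
are tagged SINGLE.  For a mixed activator/inhibitor input pair the
simulator applies inhibition-dominant semantics regardless of the tag,
so the AND/OR duplication is formal there; variants are still counted
as distinct models, matching the magnitude-based doubling rule that the
expanded-space total anchors.  The expansion yields 9,172,826 models
over the 2,324,136 canonical matrices (average factor 3.95).

## Petri-net semantics

Each model compiles, per deletion condition, into a Petri net with one
place per node.  An activating edge X→Y becomes a transition with an
input arc from X (weight fixed to 1) and an output arc to Y carrying
the edge magnitude.  Inhibition edges carry no output arc; they act
through inhibitor arcs (below).  Simulation runs 50 synchronous steps;
in each step every transition enabled on the pre-step marking fires
once (maximal parallel execution).  Firing consumes one token per input
arc; when simultaneous demands exceed a place's supply, the enabled
transitions are applied in randomly shuffled order and transitions that
can no longer be funded are skipped.  This conflict policy is the only
source of stochasticity, and it is what makes a small fraction of
models "unstable" (different pattern calls across repeat runs).

Token provisioning is regulator-centric: a regulator starts with 200
tokens — its transcript resource for the run, matched to the 50 steps so
that a regulator serving up to a few targets never exhausts it — unless
the *other regulator activates it*, in which case it starts empty and
is filled through that transition.  Genes always start empty.

The firing rules for inhibition admit several Petri-net readings, and
the choice matters; the defaults were fixed by requiring that the
minimal-model analysis come out exactly (see below) and that the
full-space aggregate statistics sit near their expected values:

* **Regulator–regulator inhibition silences.**  If R_a ⊣ R_b, node R_b
  keeps its token stock but its outgoing transitions are disabled while
  R_a holds tokens.  Deleting R_a therefore *releases* R_b.  This rule
  is weight-inert, which is consistent with the two minimal inversion
  models — identical except for the inhibition weight — behaving
  identically.
* **All other inhibition gates and drains.**  An inhibiting edge into a
  gene (or from a gene into a regulator) disables the transitions that
  produce into the target while the inhibitor is *active*, and
  additionally removes tokens from the target at the edge magnitude per
  step.  "Inhibition dominates" for mixed input pairs.  The
  gate-versus-silence rule for these edges is pluggable
  (`InhibitionMode`), as are the removal scope and the gene-arc
  consumption rule (`SimConfig`).
* **Activity, not mere token presence, inhibits.**  A silenced
  regulator neither activates nor represses its targets even though it
  holds tokens; double inhibition therefore de-represses.
* **Basal expression for repressed genes.**  A gene whose only inputs
  are inhibitory receives a constitutive source of 4 tokens/step
  (= 200/50, the same scale as a provisioned regulator spread over the
  run) gated by its inhibitors.  Without it, repression could never be
  observed as an expression change, and de-repression buffering in the
  double mutant would be impossible.

Deletion surgery empties the deleted place and removes every output arc
into it; input arcs survive, so a transition whose target was deleted
still consumes from its sources.

Expression readout: the token counts of G1 and G2 after 50 steps, per
condition (wild type, R1Δ, R2Δ, R1ΔR2Δ).  M values are
log2((tokens_mut + 1)/(tokens_WT + 1)); the pseudo-count of 1 on both
sides avoids division by zero and caps the dynamic range of
fully-silenced genes.

The minimal-model anchor: among all models with at most three edges,
no two-edge model shows inversion and exactly two three-edge models do
— R1 ⊣ R2 (weak or strong) with weak activation of a gene by R1 and
strong activation of the same gene by R2.  Mechanistically: deleting R1
releases R2 (strong up-regulation), deleting R2 changes nothing (R2 was
silenced), deleting both removes the weak input (down-regulation).
This is asserted exactly in the test suite, and both models persist at
W = 9.

## Pattern classification

For a gene *i* and mutants x, y the interaction effect is
ε_i = |M_i,xy − (M_i,x + M_i,y)|.  Genes with ε above a threshold get
exactly one of six classes from the direction calls (up/down/unchanged)
of the three M values: buffering (singles unchanged, double changed),
quantitative buffering (double in the shared direction, stronger than
additive), suppression (single change restored in the double),
quantitative suppression (shared direction, weaker than additive),
masking (opposite singles, double within ε-threshold of the
larger-magnitude single), and inversion (double opposite to the
singles' shared direction).  The rule table is total and invariant
under a global sign flip.

Thresholds: simulated profiles use ε > log2(1.7) and direction
|M| > log2(1.7).  Expression data use ε > log2(1.5) — the threshold is
on the log2 (M) scale — with directions from adjusted p ≤ 0.01 together
with |M| > log2(1.5), mirroring the changed-gene definition used for
profile summaries; the direction caller is pluggable.  Masking's
boundary (how closely the double must track the dominant single) is the
least certain part of the reconstruction and is isolated in a single
predicate.

## The survey

Every expanded model is simulated five times across the four deletion
conditions.  A model is stable when the (G1, G2) pattern tuple is
identical across the five runs; unstable models are excluded from
aggregates.  Aggregates: pattern frequency by complexity (edge count)
split by the quantitative-edge-difference flag (a model mixing weak and
strong magnitudes); the companion-gene pattern distribution for
inversion models (models oriented so the inversion gene plays the G1
role; a double-inversion model contributes "inversion" as its own
companion); the 2×2 association of the quantitative-difference flag
with a buffering-or-quantitative-buffering companion (chi-square, with
Fisher's exact test when any cell is small; for the all-models
reference the flag is buffering in either downstream gene); and the
persistence of inversion when strong edges are relabeled from 5 to 9.

Reproducibility contract: each (model, run, condition) simulation draws
its shuffle stream from a counter-based seed mixed from the global seed
and a content-based model identity, so chunked, reordered, or
subsampled surveys agree exactly with single-pass runs; the suite
asserts this.  Sample-based estimates in `scripts/acceptance.py` use a
500,000-model sample (200,000 in the test suite), sizes at which the
binomial standard errors of the reported percentages are well below
their tolerance bands.

## Expression pipeline

Growth side: fitness W is on the mutant/WT ratio scale, so slow growers
have W < 1 and a redundant pair — double mutant slower than expected —
gets a negative score ε_growth = W_xy − W_x·W_y (the reciprocal
convention would make negative interactions impossible for slow
doubles).  Z-scores against a caller-supplied null mean and standard
deviation give one-sided (lower-tail) p-values, BH-corrected;
significance is adjusted p < 0.05.  Pair selection requires a
significant negative growth score and at least one single mutant whose
profile is wild-type-like (fewer than eight genes with adjusted
p < 0.05 and |M| > log2(1.7)).

Slow-growth correction removes, per profile, the orthogonal projection
onto a supplied unit signature vector (the common expression program of
slow-growing strains, e.g. the first principal component of a large
deletion compendium — recomputing that component is out of scope; the
vector is an input).  The operation is idempotent and norm-non-
increasing, and leaves the profile uncorrelated with the signature.

Pairs are summarized by pattern-count vectors (six patterns, gene
identity disregarded) and clustered with average linkage on cosine
distance of the raw counts; input rows are sorted by pair label so that
equal-distance merges resolve deterministically, and the dendrogram is
exported as Newick.  Group contrasts of per-pair inversion percentages
use exact two-sided Mann-Whitney tests with BH correction.  Gene-set
enrichment uses the upper-tail hypergeometric test against a background
of 6,359 annotated genes with Bonferroni correction across the sets
tested.

## Synthetic data

The generator plants, for each pattern, (M_x, M_y, M_xy) triples that
satisfy the rule table with a margin of at least twice the calling
threshold before noise (default effect 1.5 log2 units); the masking
template separates the dominant single (2e vs −e) so noise cannot flip
dominance.  Remaining genes are null.  Independent Gaussian noise
(default sd 0.2, a typical replicate-averaged microarray residual
scale) is added to all M values; adjusted p-values are synthesized from
z = M/sd with BH — deliberately *before* signature correction, as
upstream differential-expression statistics would be.  A smooth random
unit signature, scaled per mutant (default loadings 0.2/0.1/0.5,
largest for the slow-growing double), is added to all three profiles.
Cohorts mix three pair archetypes (buffering-dominated,
inversion-dominated, mixed epistasis) with 20% jitter on the planted
counts.

What passing tests show: the pipeline recovers planted classes (mean ≥
95% at the default noise and loadings after correction), removes the
signature to near-zero residual correlation, recovers planted cohort
structure exactly at low noise, and its statistics match hand-computed
oracles.  What they do not show: robustness to limma-style moderated
statistics, replicate-level variance structure, gene-gene correlation
beyond one shared component, or intensity-dependent microarray bias —
real profiles carry all of these.

## Numerical and degenerate-input choices

Tokens are integers and floor at zero after each step's net change.
Enablement is always judged on the pre-step marking (synchronous
semantics).  Genes with no producers stay at zero and classify as "no
pattern".  The conflict shuffle uses a per-simulation 64-bit counter
RNG (splitmix-seeded LCG) inside the batch kernel and a NumPy generator
in the reference implementation; the two paths agree exactly on
conflict-free nets and are tested against each other.  All-zero count
vectors are rejected by the clustering step; degenerate contingency
margins fall back to Fisher's exact test; empty hit sets give
enrichment p = 1.

## Known limitations

* The firing rules for inhibition and regulator provisioning are a
  behavioral reconstruction; they reproduce the minimal-model analysis
  exactly and most aggregate statistics closely, but the share of
  inversion models with a quantitatively different edge *and* a
  buffering companion is under-estimated by the defaults (the
  non-consuming gene-arc variant over-shoots instability instead; see
  `SimConfig` to explore the alternatives).
* The mirror-orbit count is the exact group-orbit count; it differs by
  200 (0.009%) from the historical count of this model family, and the
  logic-expanded total inherits that gap.
* Four nodes, two weight magnitudes, and single-profile (not
  replicate-level) expression inputs are fixed scope.
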