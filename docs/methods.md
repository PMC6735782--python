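# Methods

## Coordinate system and event classes

All computation happens on a 60 nt target context. Offsets are 0-based;
the blunt double-strand break sits on the boundary before offset 30; the
20 bp protospacer occupies [13, 33) so the cut falls between its 17th and
18th bases; the NGG PAM occupies [33, 36). Deletions are half-open
intervals `[start, start + length)`.

The deletion-class universe is every `(start, length)` with
1 ≤ length ≤ 29 whose interval lies inside the context and overlaps the
assignment window — the 5 positions {27, 28, 29, 30, 31}, i.e. 3 nt
upstream and 2 nt downstream of the cut. Under this reading the
enumeration has exactly 550 members (a 29 bp deletion loses one candidate
start to the left context edge), which the test suite checks against an
exhaustive double-loop oracle. Insertions are identified by their inserted
sequence: 4 single-base classes, 16 dinucleotide classes and one sentinel
class for ≥ 3 bp (21 total). Event ids are written
`D:<start_rel_cut>:<length>`, `I:<seq>`, `I:LONG` in every TSV.

Deletions are stored right-aligned. On a specific target, distinct classes
can produce byte-identical alleles (repeated sequence); such groups are
*redundant* and their probability mass is summed onto the right-aligned
member (largest start) whenever a distribution is reported. A class with a
right-aligned microhomology tract of m bases has exactly m allele-preserving
left shifts, so its group has m + 1 members when all shifts stay inside the
window — a cross-module identity the suite verifies.

## Microhomology

For a right-aligned deletion, the MH length is the largest n (scanned
from 1 to 10) such that the n bases immediately upstream of the deletion
equal the last n bases of the deleted tract. A deletion is MH-mediated iff
n ≥ 1. Deletions touching the left context edge cap n at the available
flank (the definition is otherwise silent there). The feature encoder
truncates MH at 4 bp; the annotation itself keeps the 1–10 scan.

## Feature encoding

* sequence block: one-hot mono- (4 × 20 = 80) and dinucleotide
  (16 × 19 = 304) content of the protospacer, 384 bits, exactly 39 set;
* hexamer block: the same encoding of positions 27–32 (cut ± 3),
  24 + 80 = 104 bits, 11 set;
* MH block: per deletion class a one-hot over truncated MH length, levels
  0..min(4, length) — 5 bits for classes of length ≥ 4 down to 2 bits for
  1 bp classes. One-hot (including an explicit level 0) is the encoding
  under which the block-size arithmetic works out exactly: 2716 bits for
  the full 550-class catalog, and 2649 for a 536-class observed list
  grouped 519/7/6/4 by length (3100/3033 bits with the sequence block).

Which 14 of the 550 potential classes go unobserved in a real screen is a
property of the data; `synthetic_observed_deletion_classes()` is a
synthetic stand-in reproducing the canonical group sizes (drops the 13
largest classes and one 1 bp class) so the 2649/3033/557 counts are
executable.

## The three-component model

The ratio component is a two-class softmax (equivalently sigmoid) on the
384 sequence features; MH features are deliberately excluded (they do not
improve this component). The deletion component is a softmax over the
550-class catalog on sequence + MH features. The insertion component is a
softmax over the 21 insertion classes on the 104 hexamer features only —
the cut-proximal context carries the templating signal, and the full 20 bp
encoding hurts.

Training uses soft labels: each target's label vector is its observed
class-frequency distribution (conditioned per component: insertion vs
deletion mass for the ratio; frequencies within deletions / within
insertions for the other two, dropping targets with zero mass for that
component). Zero-frequency classes get soft label 0 — no pseudocount;
smoothing is left to the penalty. The loss is categorical cross-entropy
plus an L1 or L2 penalty (bias row unpenalised), optimised with mini-batch
Adam: learning rate 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e−7, batch size 32,
seeded shuffle, zero initialisation (deterministic; softmax of zeros is
uniform). Full batch (batch_size=None) is supported but leaves the
patience-1 early stop only ~6 effective updates, so mini-batches are the
default. Training runs at most 100 epochs and stops once validation
cross-entropy has not improved for patience + 1 = 2 consecutive epochs;
best-epoch weights are restored.

Hyperparameter search scans penalty strengths over 10⁻¹⁰..10⁻¹ separately
for L1 and L2 and selects the lowest validation MSE of predicted
probabilities; ties resolve to the larger penalty (the simpler model).
The full search log is retained on the results object.

Prediction intersects the components — `P(del c) = (1 − p_ins)·softmax_del(c)`,
`P(ins j) = p_ins·softmax_ins(j)` — and collapses redundant deletion
classes for the specific target. The result is normalised by construction.
Models serialise to JSON with an explicit feature-schema version;
prediction refuses a version mismatch.

Evaluation uses per-target MSE over the target's canonical class set
(collapsed deletion classes plus the 21 insertion classes, ~450–570
classes). The reference baseline predicts every class at its pooled
aggregate frequency across the training targets (support-weighted).

A separate linear least-squares regression predicts the insertion
*proportion* from the 104 hexamer features; a small ridge term (α = 1e−6,
intercept unpenalised) resolves the exact collinearity of the one-hot
blocks so a constant signal is carried by the intercept. Predictions are
clipped to [0, 1].

## Indel calling

Reads are grouped by exact 15 nt UMI; the representative is the most
common sequence (ties: lexicographically smallest); reads under 90%
identity to it (edlib edit distance over the longer length) are removed;
groups with fewer than 10 retained reads are dropped, all removals
tallied. Exact-match UMI grouping is a simplification of edit-distance
clustering — acceptable here because the simulator controls UMI
collisions (15 nt tags, modest depths).

Each consensus allele is compared to its target. Pure string scanning
identifies all single-indel readings (via longest common prefix/suffix);
a deletion is assigned to the largest start that is still a catalog member
— exactly the collapse canonical, making
`classify(apply(class)) == canonical(class)` an identity the suite checks
over the full catalog. An insertion is read at the cut boundary whenever
consistent with it; this makes the round trip exact for insertions too,
which a rightmost-only reading would not (inside repeats, `I:GT` and
`I:TG` can yield identical alleles; the cut-anchored reading is
injective). Alleles equal to the target are wild-type; same-length
mismatched alleles are aligned and, if gapless, counted wild-type with a
substitution flag (tallied separately, excluded from distributions);
everything not explainable by one indel is complex; single indels whose
every reading misses the window (including deletions > 29 bp) are
out-of-window.

Alignment uses Biopython's global affine-gap aligner with match 5,
mismatch −4, gap-open −13, gap-extend −0.5 (a length-g gap costs
|open| + (g−1)·|extend|), plus a preset with gap-open −20 and N-scored-0
for users aligning raw amplicons against N-masked backbones. Gaps are then
shifted as far 3′ as sequence identity allows (score-preserving,
idempotent) for a deterministic rightmost tie-break. Observed
distributions are frequencies over deletion/insertion calls only;
summaries report category fractions, Shannon entropy in bits (log₂,
0·log 0 = 0) and the frameshift ratio. The ≥ 3 bp insertion class counts
as frameshifting by default (2 of every 3 lengths shift frame); the flag
is configurable.

## Simulator

The generator emulates the mechanistic structure of real editing screens
with a deliberately simple log-linear form. Per target:

* insertion fraction: logistic(logit(0.315) ± δ/2), +δ/2 when the base 5′
  of the cut is A or T, −δ/2 for G/C, with δ = 0.6. The symmetric shift
  keeps the pooled fraction near the 31.5% baseline while giving the ratio
  component a learnable sequence signal of realistic size;
* insertion mix 75.3 / 21 / 3.7 % for 1 bp / 2 bp / ≥3 bp; 84% of 1 bp
  insertions are templated by the base 5′ of the cut and 41% of 2 bp
  insertions by the upstream dinucleotide (the remainder spread uniformly);
* deletion-class weight ∝ exp(−length/λ) · γ^mh · u^[start or end at cut],
  normalised over the catalog and collapsed. λ = 4 bp reproduces the
  small-deletion dominance (a few percent of deletions above 25 bp);
  γ = 3 yields roughly three quarters of deletions MH-mediated; u = 2
  expresses the observed preference for unidirectional deletions abutting
  the cut. These three numbers are declared modelling choices, set once.

UMI counts per target are 10 + Poisson(mean − 10) (every target clears the
caller's UMI filter); class counts are one multinomial draw; reads can be
materialised (n copies per UMI, per-base substitution errors, random 3–10 nt
sequences for the ≥3 bp class) for end-to-end pipeline tests.

What the simulator does *not* emulate: substitution and complex alleles,
deletions beyond 29 bp, chromatin or cell-type effects, UMI collisions and
PCR/sequencing artefacts beyond uniform substitution errors, and any
nonlinear sequence dependence beyond the declared factors. Passing
recovery tests therefore show that the estimator learns this mechanism's
signal from sampled data — not that real screens obey it.

## Problem sizes and numerics

The recovery study in the tests and the acceptance script uses 300
training + 50 held-out targets at ~500 UMIs with a 3-point L2 grid —
sizes chosen so the whole suite runs in well under a minute per study
while leaving a wide model-vs-baseline margin (aggregate/model MSE ratio
≈ 1.5). Distribution normalisation is enforced at 1e−9; training aborts
on non-finite weights; probabilities are clipped at 1e−12 inside logs.

On programmed microhomology: copying the m bases upstream of the cut to
just after the PAM (6 bp spacer) makes the 6 + m bp deletion the designed
outcome, and its probability rises steeply with m in the median across
backbones. On individual backbones the trend can invert (accidental extra
MH at shorter tracts; new repeats introduced by the copied tract), so the
monotonicity checks are population-level — medians and means across ≥30
backbones plus a majority of individually monotone ones — matching how
such designs behave in real screens.

## Known limitations

* The model predicts the *spectrum* of edited outcomes, not editing
  efficiency (the fraction of unedited molecules is assay-confounded).
* PAM is not validated against NGG (warn-only by design): prediction on
  arbitrary input is allowed, but the training data conventions assume a
  cut 3 bp upstream of an NGG.
* N bases are rejected in the protospacer/window region (features are
  undefined there) and tolerated only in distal context.
* Exact-match UMI grouping and direct allele-vs-target comparison replace
  the original read-merging and reference-discovery steps of a raw
  sequencing pipeline; the −20/N-neutral scoring preset is provided for
  users who need the latter.
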