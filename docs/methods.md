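# Methods

## The model of RNA decomposition

An RNA secondary structure is a sequence over {A, C, G, U} plus a set
of base pairs (i, j), i < j, 0-based. Nothing restricts the pair set to
nested canonical pairs: crossing pairs (pseudoknots) and bases with
more than one partner (triples) are first-class, because the
decomposition argument below does not need nestedness.

A base k is **exterior** iff it is an endpoint of no pair and no pair
(i, j) satisfies i < k < j. Operationally this is interval-union
coverage: k is exterior iff it lies outside the union of closed
intervals [i, j] over all pairs. The three cases of the definition —
paired base (an endpoint), base between two paired bases (strict
interior of some interval), unpaired dangling/linker base (outside
every interval) — map onto coverage exactly, and a brute-force
all-pairs enclosure check is kept in the test suite as an independent
oracle.

**i-fragments** are the maximal runs of non-exterior bases. Because the
closed interval of any pair is entirely non-exterior, each pair lies
inside exactly one fragment; hence extracting per-fragment
substructures and re-assembling them is the identity on pair sets (a
property test over random structures, including pseudoknots and
triples). A fully unpaired RNA has zero fragments — there is nothing to
fold — rather than one degenerate fragment.

Cross-fragment pairs cannot exist *under true labels* by construction.
Under predicted labels a false-positive exterior base can split a true
fragment and sever real pairs; the pipeline reports these as pair-level
false negatives and makes no attempt to repair them (a post-assembly
refinement stage is explicitly out of scope).

## Structure I/O

Dot-bracket (bracket layers `()[]{}<>Aa Bb` in that precedence, layers
assigned by greedy crossing-conflict coloring on output), CT and BPSEQ
(1-based, partner 0 = unpaired, symmetric-partner validation) are
supported. A base triple is representable in memory but in none of the
three formats, so writers raise an unrepresentable-structure error
instead of silently dropping pairs. `T` is mapped to `U` and lowercase
uppercased on input, since sequences often arrive from DNA-alphabet
FASTA.

## Windowing and encoding

Sequences are cut into windows of length L (default 200) at a
configurable step; the final window is right-padded with `-`.
Dataset construction uses non-overlapping windows (step = L);
inference defaults to step = L/2, averaging predictions on bases
covered by two windows — overlap at inference is free accuracy, and
averaging is the natural combination rule. Both strides are
configurable, and L ∈ {60, 120, 200, 280} are the supported window
regimes (prediction quality peaks at intermediate L: too-short windows
lack context, too-long windows strain the recurrent layer).

One-hot channels are ordered `-`, U, G, C, A, so a column reads
`10000` for padding and `00001` for A. Labels are 1 for exterior
bases; padding carries label 0 under mask 0 and is excluded from loss,
batch-norm statistics, and stitching.

## The labeler

Architecture (per window, features per position):

    4 × Conv1D(kernel K, C channels, relu, dropout)
    → BiLSTM(U units per direction, dropout)
    → BatchNorm
    → 2 × ResNet layer(width N, dropout)
    → BatchNorm
    → Dense(2) + softmax

A ResNet layer is two position-wise FC layers with a shortcut joining
their outputs: `a = relu(W₁x + b₁)`, `out = relu(a + W₂a + b₂)`; the
first FC also adapts the incoming width (2U from the BiLSTM) to N.
Batch normalization sits after the recurrent block and after the
ResNet block; within blocks, dropout follows activation. Padding
positions are zeroed before every block, which makes the output
provably invariant to whatever symbol sits under the mask (asserted by
a mutation test) and keeps the recurrence from carrying padding
content.

The network and its training loop are implemented directly in NumPy —
layers expose exact forward/backward passes (verified against central
finite differences; note that zero-initialized biases can park
pre-activations exactly on the ReLU kink where two-sided differences
legitimately disagree with the subgradient, so the check nudges
parameters first). Optimization is Adam (default learning rate 1e-3,
configurable); the loss is cross-entropy over unmasked positions.

**Early stopping** monitors validation base-level MCC with patience 10
(default) and restores best-epoch weights. While predictions are
degenerate (one class ⇒ MCC undefined), the monitor falls back to
validation loss so training can leave the degenerate regime; any
defined MCC outranks the fallback. Binarization threshold is 0.5 with
ties going to the positive class.

**Transfer training** runs the same scheme twice: stage 1 on the large
coarse (noisy-label) corpus, stage 2 from the stage-1 weights on the
smaller accurate corpus with identical hyper-parameters — no layer
freezing, no learning-rate drop. The Adam moment state restarts at
stage 2; the knowledge transfer is in the weights, not the optimizer.
An empty accurate set degenerates to pre-training only.

**Hyper-parameter search** over K (odd, 3–11), C (16–128), U (16–128),
N (32–256) uses a sequential model-based optimizer: the first five
trials sample uniformly, later trials fit a Gaussian-process surrogate
(Matérn 5/2) to observed validation MCCs and maximize expected
improvement over random candidates. Default budget is 20 trials
(configurable; large-scale searches simply raise it). The top models
by validation MCC form a mean-probability ensemble (default top 3).

## Metrics

Base-level confusion counts unmasked positions with exterior as the
positive class. Segment-level confusion scores each maximal run of
constant truth label as one unit: an exterior segment with ≥1 hit is a
TP else FN; a non-exterior segment with ≥1 predicted positive is an FP
else TN. This answers "was the partition found at all", which base
accuracy obscures when segments are long. Pair-level confusion is set
algebra on pair sets, with TN = C(n,2) − TP − FP − FN.

SEN = TP/(TP+FN), PRE = TP/(TP+FP), ACC = (TP+TN)/total,
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
F1 = 2·PRE·SEN/(PRE+SEN). Zero denominators yield *undefined* (None),
reported distinctly from 0 and excluded from macro averages with a
logged count. Corpus metrics pool counts (micro) by default;
per-sequence macro averages are available, and bootstrap standard
errors (default B = 100 resamples, seeded) operate on per-sequence
values.

The with/without-partition comparison reports paired per-RNA pair
metrics, a permutation sign test on the F1 differences, and
length-binned means.

## The built-in folder

`nussinov_fold` maximizes the number of nested pairs from
{AU, UA, GC, CG, GU, UG} with hairpin loops ≥ 3 by the classical O(n³)
dynamic programme, vectorizing the split-point maximum per cell.
Tie-breaks are deterministic: leave j unpaired when equal, else pair
with the smallest admissible k. It exists so the pipeline is testable
and deterministic without external engines — it is a maximum-pairing
folder, not a thermodynamic one, and its absolute accuracy is
accordingly modest. Real engines plug in through the
fragment-predictor contract (sequence → equal-length structure); a
subprocess adapter for RNAfold-style tools is included as an example
and required by nothing.

## Synthetic corpora

The generator emulates the anatomy the labeler must recognize:
alternating unpaired exterior linkers and fragments whose outermost
helix closes the whole fragment (so intended fragment boundaries and
derived labels agree exactly — the generator returns
`label_exterior(structure)` and a self-consistency test holds by
construction). Fragment interiors recurse through a stem–loop grammar:
helix extension (p = 0.7 per bp beyond the 2-bp minimum), two-way
multiloops (p = 0.35 when room allows), internal loops/bulges (≤ 6 nt
per side), hairpin loops ≥ 3 nt; minimum feasible fragment is 7 nt
(requests below that raise). With probability `pseudoknot_prob`
(default 0.1) one crossing pair connects two loop regions inside a
fragment. A grammar rather than thermodynamic sampling is deliberate:
exact ground-truth labels are the requirement, and a grammar
guarantees them.

Defaults mirror the corpus statistics the package is meant to emulate:
lognormal fragment lengths with mean 129 nt, geometric linker lengths
(mean 10 nt, internal linkers ≥ 1), a fragment-count distribution with
~17 % of RNAs holding more than two fragments (up to 10), pair
composition GC/AU/GU = 0.5/0.4/0.1, and unpaired-region G+C of 0.2 in
exterior linkers versus 0.6 inside fragments — the compositional
contrast (exterior loops GC-depleted) that makes sequence-only
labeling learnable, and that `context_composition` verifies with
two-proportion z-tests on 31-nt windows.

The label-noise knob flips real-base labels at a given rate to produce
"coarse" variants next to clean "accurate" variants of the same
windows; test-split labels stay clean so both regimes are scored
against truth.

What the generator does *not* emulate: thermodynamic plausibility,
family-specific motifs, non-canonical pair geometries, sequencing
noise, or long-range cross-fragment interactions. Tests passing on
these corpora show the algebra is exact and the learning machinery
works on the stated signal; they do not certify accuracy on biological
RNAs, which depends on training corpora this package does not ship.

## Problem sizes and numerical choices

The bundled checks run on deliberately modest corpora chosen as
desk-scale study conditions: oracle and round-trip properties on 1000
random structures (n ≤ 300); the pipeline premise on 200 synthetic
RNAs; Nussinov optimality against exhaustive enumeration on 500
sequences of length ≤ 12; learnability with K=5, C=32, U=32, N=64 on
~2000 windows of 120 nt (held-out base MCC ≥ 0.7); the transfer
direction with a 20 %-noise coarse corpus (~1000 windows of 60 nt) and
a clean accurate corpus one-third its size; the partition benefit on
40 multi-fragment RNAs with the Nussinov folder. Training uses
learning rate 2e-3, batch 128, patience 3–4 at these scales —
early-stopped runs of a couple of dozen epochs.

Reproducibility is bitwise under fixed seeds on one machine: all
randomness (generator, shuffling, dropout, initialization, bootstrap,
search) flows through seeded NumPy generators.

## Known limitations

- The labeler's accuracy on real RNAs is untested here and bounded by
  the realism of its training corpus; the synthetic contrast is
  stronger than what distinguishes biological exterior loops.
- The Nussinov folder ignores thermodynamics and pseudoknots; it is a
  reference predictor, not a recommendation.
- Predicted false-positive exterior bases sever true long-range pairs;
  no post-assembly repair is attempted.
- The NumPy implementation targets CPU-scale experiments; it is exact
  but not fast enough for corpus-scale searches with large budgets.
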