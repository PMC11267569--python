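# Methods

## Sequence encoding

A DNA sequence is mapped into the square [−1, 1]² by the chaos-game midpoint
iteration started at the origin, with corners A (−1, +1), C (−1, −1),
G (+1, −1), T (+1, +1). The corner convention is the one consistent with the
recursive sub-square reading in which the T quadrant splits clockwise into
TT, GT, CT, AT; other published CGR implementations may differ from it by a
rotation or reflection. Class separability is invariant to such a flip, but
stored images from different tools may not be pixel-identical.

Rasterization uses half-open cells: col = ⌊(x+1)/2·N⌋ and row = ⌊(1−y)/2·N⌋,
clamped into [0, N−1]; row 0 is the top of the image (y = +1 edge) so arrays
render in conventional CGR orientation. Interior points can touch a cell
boundary only within the first few iterations (e.g. (0.5, 0.5) lies on a
grid line at N = 64); floor semantics send such points to the higher-index
cell.

The load-bearing property is the k-mer equivalence: at N = 2ᵏ, the cell of
trajectory point i (for i ≥ k) is a closed-form function of the length-k
suffix ending at i — x-bits A,C→0 / G,T→1 and y-bits C,G→0 / A,T→1, with the
last character as the most significant bit. Counts over points i ≥ k
therefore equal sliding-window k-mer counts exactly, and the full image
differs from the k-mer table by at most the k−1 leading points. We include
all points in the stored image (the bound is asserted in tests and in the
acceptance script); whether those leading points should be dropped is a
representational choice with a provably bounded effect.

Non-ACGT handling: input is case-folded and U is mapped to T; the default
policy is strict (error naming the character, its position and the record),
with an optional skip policy that silently drops bad characters. Strictness
is the default because ambiguity codes in enhancer FASTA files usually
indicate a data problem worth surfacing. Stored FCGR images are integer raw
counts; any scaling (per-total, per-max) is applied at an output or network
boundary so the stored representation stays lossless.

Default resolution N = 64 (6-mer resolution): fine enough to separate
hexamer composition, coarse enough that 200 bp sequences still populate the
grid.

## Network

Architecture: one Conv2D + ReLU frontend; a second Conv2D whose output
channels are reshaped into L primary capsules of dimension m and squashed;
learned matrices W_{i,j} (L×J×n×m) produce prediction vectors; r rounds of
dynamic routing yield J = 2 type capsules of dimension n; class scores are
capsule lengths. Defaults: m = 8, n = 32, r = 3. The routing softmax is
taken across type capsules j for each primary capsule i, logits reset to
zero for every example, and the agreement update runs on all but the last
iteration — the canonical dynamic-routing formulation; where the source
architecture left these details open we fix and document them here.

Two geometries are provided:

- `small_config` (default): frontend 16 filters, 9×9, stride 2; primary conv
  9×9, stride 2, 4 capsule channels → L = 400 capsules at N = 64. Sized for
  single-CPU training in minutes.
- `full_scale_config`: 32 filters at stride 1 and 8 capsule channels
  (L = 4608), the classical heavier geometry, for full-scale runs.

The loss is the standard capsule margin loss with m⁺ = 0.9, m⁻ = 0.1,
λ = 0.5 (no reconstruction decoder). Training uses minibatch Adam
(batch 32). The canonical epoch budget is 100 with the learning rate exposed
in the tuning grid; the documented stable default is 1e-3 — Adam at 0.1
frequently diverges on this loss, and divergence aborts with a clear
diagnostic naming the epoch and learning rate rather than returning junk.

Input scaling: FCGR counts are divided by the per-image maximum before the
frontend (configurable: per_max, per_total, none). Counts are sparse small
integers; per-max keeps inputs in [0, 1] independent of sequence length.

Numerical choices. squash is computed as s·‖s‖/(1+‖s‖²), so a zero vector
maps to exactly zero with no epsilon; its backward pass zeroes the gradient
at the origin (the Jacobian's limit). The whole backward pass — including
unrolling the routing iterations, through which coupling coefficients are
themselves functions of the prediction vectors — is hand-written NumPy,
validated against central finite differences at tolerance 1e-4 and against
a straight-line loop implementation of the forward equations. Everything is
float64; forward passes are deterministic bit-for-bit, and checkpoints
(versioned .npz, written atomically) reproduce outputs bit-exactly.

Decision rule: predict the positive class iff its capsule is strictly longer
than the negative one; an exact tie goes to the negative class. Capsule
lengths are independent presence probabilities and do not sum to 1;
`predict_proba` renormalizes them only for scikit-learn interface
compatibility, and AUC uses the raw positive-capsule length as the score.
Positive-class convention: "enhancer" beats "nonenhancer" and "strong" beats
"weak"; for other label sets the lexicographically larger label is positive
unless `positive_label` says otherwise.

## Evaluation

Accuracy, sensitivity, specificity (percentages), MCC, and AUC as the
Mann–Whitney pair-ordering probability with ties counted ½ (computed via
scikit-learn, cross-checked against brute-force pair enumeration in tests).
Any metric with a zero denominator is reported as null — silently reporting
0 would deflate or inflate comparisons. Cross-validation is stratified
k-fold (default 5) with a fixed seed; whether the original protocol
stratified is unknown, so we stratify and say so. Grid search scores each
Cartesian-product cell by mean CV accuracy, breaks ties toward the earlier
combination in product order, and records failing cells (e.g. divergent
learning rates) instead of aborting.

Two-stage prediction has two modes. *Independent* scores every record with
both stages — the benchmark semantics under which published two-stage test
metrics are computed. *Chained* runs stage 2 only on stage-1 positives —
the deployment semantics, where stage-1 false positives are the records a
user would wrongly grade for strength. Stage-1 outputs are identical in
both modes.

## Synthetic data

The generator emulates the documented statistical structure of the enhancer
benchmark: fixed-length (200 bp) sequences in classes that differ in GC
content, drawn i.i.d. per position with P(G) = P(C) = gc/2,
P(A) = P(T) = (1−gc)/2. Default GC fractions — nonenhancer 0.40, enhancer
0.60, strong 0.65, weak 0.55 — are qualitative stand-ins ordered the way the
real classes order (the benchmark's actual GC distributions are not
numerically published); stage-1 enhancers are drawn half from the strong and
half from the weak profile, since real enhancers are the pooled strength
classes. Optional motif planting substitutes an exact k-mer at a uniform
random offset with a per-sequence probability, giving classes a signal that
FCGR at N = 2ᵏ can resolve independently of GC content. Every dataset
carries a manifest (seed, sizes, profiles, generator version) that
regenerates it exactly.

What this does not emulate: dinucleotide/Markov composition, repeats,
positional motif grammar, real transcription-factor binding sites, or
sequence redundancy. Passing the end-to-end tests therefore demonstrates
that the encoding preserves compositional signal and that the network can
learn it — not that real-benchmark accuracy is reproduced. The negative
control (identical GC, no motifs) checks the complementary failure mode:
with no signal present, held-out accuracy must stay inside the 95% binomial
band around chance.

## Problem sizes used in the checked runs

The test suite and acceptance script run the two-stage workflow at a
reduced, fixed scale chosen as a realistic single-CPU experiment: 300
sequences per class for stage-1 training (150 per class for stage 2), an
independent 100 + 100 + 200 test split mirroring the benchmark's test
composition, N = 64, the small geometry, 30 epochs at learning rate 1e-3.
Under these conditions the GC-contrast task is learned to ≥ 90% held-out
accuracy and ≥ 0.95 AUC. Full-benchmark training (1484/1484 and 742/742
training sequences, 100 epochs, grid-tuned hyperparameters,
`full_scale_config`) is supported by the same code paths but is a long
run left to the user with the real data.

## Known limitations

- The published tuning grid for the original experiment is unavailable; the
  default grid ({m: 4, 8} × {n: 16, 32} × {r: 2, 3} × {lr: 0.1, 1e-3}) is a
  reasonable reconstruction, with lr 0.1 retained for fidelity despite its
  instability.
- The exact routing variant of the original implementation (iteration
  count, softmax axis, logit reset) is not published; we use the canonical
  formulation and flag it as an assumption.
- CGR corner convention may be a reflection of other tools' (see above).
- Training is CPU NumPy: adequate for the scales above, slow for
  full-benchmark grid searches.
- Sequences shorter than ~N points leave FCGR images sparse; the encoder
  accepts variable lengths, but very short inputs carry little signal.
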