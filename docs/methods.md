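# Methods

This note documents the model, its numerical choices, the synthetic
data the package is validated on, and what those validations do and do
not show.

## Affinity scale and labels

IC50 values in nM are mapped to [0, 1] by the log50k transform
`1 − log(a)/log(50000)` (natural log; the base cancels in the ratio).
The transform is clamped to [0, 1] for affinities outside (1, 50000)
nM so the scale invariant holds for arbitrary inputs.  A pair is a
*binder* when its normalized score is strictly greater than 0.426
(the image of 500 nM to three decimals); ties at the cutoff are
nonbinders.  The inverse map `50000^(1−s)` inverts the unclamped
transform.

Internally all coordinates are 0-based half-open; files written for
users carry 1-based inclusive positions.

## Embedding backend contract

A backend maps one (allele pseudo-sequence, peptide) pair to position
embeddings `H_mhc (M×D_mhc)`, residue embeddings `H_p (N×D_p)`, a
symmetric contact map `A (N×N)` with entries in [0, 1] and unit
diagonal (a residue trivially contacts itself; the self-contact also
guarantees positive hypergraph degrees), and an optional row-
normalized attention profile.  In a full-scale deployment this role
belongs to fine-tuned protein language models trained with a mean
squared error on binding reactivity (`finetune_loss` implements that
objective); such a backend is an optional plugin behind the same
contract and is never loaded here.

The shipped synthetic backend is deterministic: residue embeddings
come from per-residue-identity lookup tables seeded by (seed, role).
An earlier sketch seeded each sequence's embeddings independently;
that was dropped because it makes residue identity statistically
invisible downstream — no model could then learn any sequence rule,
which would defeat the backend's purpose as a test stand-in for a
language model (whose embeddings are, above all, consistent functions
of residue identity and context).  Contact maps are a banded kernel
`exp(−|i−j|/band_width)` (defaults: band_width 2.0) plus
`n_longrange = 2` planted symmetric long-range contacts at value
≥ 0.9, placed by a hash of the sequence at separation > 3×band_width;
attention is the contact map with rows normalized to sum 1.

## Hypergraph construction

The contact map holds *scores* (higher = closer), so binarization
retains the top `ceil(ratio · N(N−1)/2)` off-diagonal pairs (default
ratio 0.5, applied per map).  Ties at the cut are resolved toward the
smallest (i, j) so the retained count is exact and deterministic.  A
distance-threshold reading (`C_ij = 1` iff the pairwise value is
below a cutoff) exists in the field; retaining the largest scores is
the semantics consistent with "most significant contacts" and is the
implemented default.

Rows of the binary map are candidate hyperedges; duplicates are
removed by set equality keeping the first occurrence (row order).
Surviving singleton edges are kept (they act as self-loops); validity
only requires at least one edge with ≥ 2 members, and a pair without
one is rejected and excluded from training/evaluation with its count
reported.  Note that with top-ratio binarization a rejection can only
arise for directly supplied binary maps, since the ratio rule always
retains some pair.

## Hypergraph convolution

One layer computes `X′ = σ(D_v^{−1/2} I D_e^{−1} Iᵀ D_v^{−1/2} X Φ)`.
The unnormalized two-step form `I (Iᵀ X Φ)` (edge aggregation, then
node aggregation) is kept as a transparent oracle path; the tests
assert the fused operator equals the degree-normalized composition to
1e−8 and that the propagation matrix is symmetric, non-negative and
fixes `D_v^{1/2} 1` (eigenvalue 1).  Hyperedge weights are identity;
the default stack is L = 2 layers with ReLU (configurable:
identity/relu/elu).

## Encoders, fusion, and the fixed-width frame

The MHC side runs a bidirectional LSTM (hidden 32 per direction) over
`H_mhc` followed by a linear projection to the common width D = 64;
the peptide side projects each HyperConv layer output (including
layer 0, the raw embeddings) to width D.  Fusion contracts the
feature axis — `H^{(l)} = X_mhc X_p^{(l)ᵀ}` — and max-pools
elementwise across the layer stack, yielding `H_binding (M×N)`.  The
pooling axis is genuinely ambiguous in the field's descriptions;
pooling across the *stack* is the only reading that preserves the
M×N binding-surface shape, and is the implemented choice.

For the fixed-width head input, `H_binding` is zero-padded on the
peptide axis to `max_peptide_len = 21` with the peptide *centered* in
the frame.  MHC-II grooves are open at both ends and peptides
protrude roughly symmetrically, so center alignment keeps
core-proximal residues in comparable feature columns across peptide
lengths; with left alignment the binding register drifts with length
and desk-scale training cannot compensate (observed ~0.1 held-out AUC
difference on the benchmark).

## Heads and training

Both task heads are three-layer MLPs (hidden 32 and 16, ReLU) with a
terminal sigmoid — the regression target lives in [0, 1], so the
squashed output honors the score range; with all-zero parameters both
heads output 0.5.

Training is joint and end-to-end through the fusion stage: the MHC
projection, the peptide projections and the HyperConv filters receive
gradients (through the max-pool routing and the linear propagation),
while the LSTM recurrence, the embedding tables and the hypergraph
structure stay fixed.  The loss is binary cross-entropy on reactivity
plus squared error on affinity, weighted 1:1 (records missing one
target simply drop out of that term).  Optimization uses Adam
(lr 1e−3, batch 64, weight decay 1e−3) for up to 200 epochs with
early stopping (patience 30) on a 10% validation split, restoring the
best snapshot; with fewer than 20 records no split is made and the
running training loss is monitored.  Features are standardized by an
affine layer frozen at the initial trunk state (identity for a single
record).

Two regularizers matter at desk-scale sample sizes and are defaults:
dropout 0.7 on the flattened interaction map during training, and a
deep ensemble of `n_ensemble = 3` independently seeded replicas whose
predictions are averaged.  Without them the ~700-dimensional dense
input lets the heads memorize a 2000-record panel outright (training
loss < 1e−3 while validation loss rises from the first epoch).

Everything is deterministic given `random_state`: embeddings, trunk
initialization, batch order, dropout masks and the validation split
all derive from it, and repeated fits are bit-identical.

## Interpretation

*Contextual contribution* of residue i sums its attention weights
with all other residues in both directions (diagonal excluded) and
normalizes the profile to sum 1 (uniform if the off-diagonal mass is
zero).  *Spatial importance* is occlusion-based: zero residue i's
embedding row and record `|p_base − p_masked(i)|` in the ensemble
binding probability.  A mask-optimizing graph-explainer variant would
fit the same interface; occlusion is the default because it is exactly
reproducible and parameter-free.  The residue importance map is the
elementwise product of the two views; the binding core is the 9-mer
window (step 1) with the highest cumulative importance, ties resolved
to the leftmost window.  Core predictions against an annotation are
categorized exact / shifted_1 / shifted_2 / miss by start offset.

Contact profiles are the interaction map min-max normalized to
[0, 1]; constant maps normalize to all zeros so the range invariant
stays well-defined.

## Synthetic benchmark

The generator emulates the structure of MHC-II binding-affinity
panels: peptide lengths 9–21 with a triangular distribution peaking
at 15, 34-position pseudo-sequences, normalized affinities, and
motif-grouped folds (records sharing a planted core 9-mer are never
split across folds, mirroring redundancy-reduced benchmark splits;
groups go greedily to the smallest fold).

Each of the 5 synthetic alleles prefers one residue at each of the
four classic anchors (P1, P4, P6, P9; distinct letters per allele).
The binding core sits at the central register `(L−9)//2` —
consistent with the symmetric overhangs of the open groove — and the
latent affinity is `0.1 + 0.2 × (#anchor matches)` at that register,
spanning 0.1–0.9 so that ≥ 2 matches crosses the 0.426 cutoff.  The
per-anchor match probability is solved by binomial inversion from the
binder-fraction target (default 0.5).  Observed affinity adds
Gaussian noise (sd 0.05), clamps to [0, 1], and the label is derived
from the noisy value, as in real panels where labels are thresholded
measurements.  Defaults: n = 2000 records.

What passing the recovery benchmark shows: the full pipeline —
synthetic embeddings, hypergraph construction, convolution, fusion
and heads — can learn a position-anchored, allele-conditioned residue
preference rule from ~1600 training pairs (five-fold CV AUC ≈ 0.87,
PCC ≈ 0.76).  What it does not show: recovery under register
variation (real peptides bind in shifted registers, which requires
orders of magnitude more data or register-scanning architectures),
realistic amino-acid composition, inter-allele similarity structure,
or the behavior of language-model embeddings.  Core-detection
fixtures (planted 9-mer signal plus noise) similarly validate the
window localizer, not biological core calling.

## Evaluation

AUC is the pairwise concordance fraction (ties half-weight), AUPR the
step-interpolated precision-recall area (average precision — the
conservative estimator; no linear interpolation), PCC the standard
product-moment correlation; degenerate inputs (single-class labels,
no positives, constant vectors) raise typed errors rather than
returning conventions.  Cross-validation honors provided fold ids and
never re-splits; metrics are computed per fold and averaged
(mean ± sd), with pooled-prediction metrics reported alongside since
the field's aggregation convention varies.  Leave-one-molecule-out
cycles over alleles with strictly more than 40 observations and at
least 3 binders, training on all remaining records and testing on the
held-out molecule, reported per allele in sorted order.

## Known limitations

* The synthetic backend carries no evolutionary or structural signal;
  conclusions transfer to real embeddings only at the interface level.
* Fixed central-register training data means the model does not learn
  register invariance (see above).
* The regression head's sigmoid compresses extreme affinities near
  the scale ends.
* Problem sizes (n = 2000, 5 alleles, 3-member ensemble, ≤ 200
  epochs) are the package's benchmark conditions, chosen to make the
  full validation a single-CPU, few-minute run.
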