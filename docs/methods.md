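# Methods

## Problem setting

A candidate site is a serine or threonine residue of a protein with a
known 3D structure. The classifier sees the site as a sequence window of
2N+1 residues (N = 10 by default) and predicts the probability that the
site is O-GlcNAcylated. Each window position carries m features: a
20-column one-hot encoding of the amino acid plus the residue's
local-environment block.

## Local-environment features

For a centre residue and each radial cutoff r ∈ {5, 10, 15, 20, 25} Å the
feature vector holds, per physicochemical class c, the neighbour count
`count(c, r)` and the summed per-residue SASA `total_sasa(c, r)` of the
residues within r. Radius 0 contributes the centre's own class
memberships (one-hot) and its own SASA. With the default 10-class table
this yields 11 + 10×2×5 = 111 columns; the class table is fully
configurable, so a larger published inventory (e.g. one spanning 498
columns) can be reproduced by supplying its class definitions.

Decisions where the design was genuinely open:

* **Residue–residue distance** is the minimum heavy-atom pair distance
  (captures side-chain reach); a Cα metric is available
  (`metric="ca"`). The neighbourhood at cutoff 0 is the centre alone.
* **Hydrogens** are excluded from SASA and distances by default because
  published vdW radii for H are inconsistent; `include_hydrogens=True`
  restores the fully protonated setting for structures that have them.
* **Partial charges** are accepted as optional input (they come from
  external force-field pipelines) and exposed as class-wise sums per
  radius via `include_charges=True`; they are never computed internally.
* **Per-position features**: the local-environment block is attached to
  every window position, not only the centre, so subsite-resolved
  statistics (see the ratio profiles) are meaningful.

## SASA

Shrake–Rupley with probe radius 1.4 Å (water) and 960 quadrature points
per atom. The point layout is a deterministic golden-spiral (Fibonacci)
sphere, so results are bit-reproducible without a seed. vdW radii come
from a bundled Bondi-style element table. For an isolated atom the
quadrature is exact (all points accessible ⇒ 4π(r+p)²); for overlapping
pairs the error at 960 points is below 1% against the closed two-sphere
form, and per-residue sums agree with an independent implementation
(biotite) within 2% on toy structures. Per-residue SASA is the plain sum
over the residue's atoms, which conserves the per-atom total exactly.

## Windows, encoding and scaling

Windows crossing the sequence termini are padded with `-`; pad rows (and
the unknown residue `X`) one-hot encode to all-zero rows and keep
all-zero feature rows after scaling. Continuous features are min–max
scaled to [0, 1] with bounds learned on the training split only
(leak-free); values outside the training range clip to [0, 1], and
constant features map to 0. The one-hot block is already in {0, 1} and
passes through unscaled. Column order is fixed — one-hot block then
local-environment block — so penalty group indices are stable.

## Class imbalance and splits

O-GlcNAcylation data is heavily imbalanced (~1:26 positives to
negatives). Splits are stratified 80/20 (an unstratified 20% test set
could lose most positives at this imbalance); k-folding is stratified
with near-equal folds. Training positives are replicated to match the
negative count: whole copies first, then a remainder drawn without
replacement under the split seed. Validation and test sets are never
oversampled.

## The sparse recurrent classifier

Architecture: a single LSTM layer reads the window position by position;
the final hidden state (context vector) passes through ReLU dense layers
to a two-way softmax. Defaults: hidden size 16, one dense layer of 8,
batch 256 — deliberately small; they are configuration, not claims about
any published architecture.

Objective: mean binary cross-entropy (probabilities clipped at 1e-7)
plus λ·R(W). R applies independently to the input layer and/or the
hidden layer. For SGL the group term is `α Σ_g √|g|·‖w_g‖₂` — the
√group-size factor is the standard weighting and can be switched off —
and the L1 term covers the same layer's weights with weight 1−α
(α = 0.5 by default; α = 0 reduces exactly to L1). Biases are not
penalized.

Optimisation is Adam (learning rate 1e-3) on the loss gradient plus the
penalty subgradient (sign for L1; `w_g/‖w_g‖₂` per group, zero at a zero
group). The penalty is non-smooth at zero, so weights oscillate around
zero with amplitude of the order of the effective step size rather than
landing exactly on it; "zero" groups are therefore read at a 1e-3 norm
threshold, and proximal updates were deliberately left out for
simplicity. Early stopping monitors validation cross-entropy with
patience 10 and a minimum improvement of 1e-4; the best-validation
parameters are restored (the parameters at the last step are also kept,
since under a dominating penalty the collapsed end state is exactly what
sparsity inspection needs). Before batching, training samples are put
into a canonical content order (MD5 of features+label), which makes
results invariant to the order samples arrive in; all remaining
randomness derives from the spec seed, so identical runs are
bit-identical on a single thread.

λ can be chosen by stratified 5-fold cross-validation over the grid
{1e-5 … 1e-1} maximizing mean validation F1 (`select_lambda_cv`; ties go
to the smaller penalty). The synthetic-benchmark runs in the acceptance
script use the package default λ = 1e-3 directly: on a generator whose
signal strength is known and large, the grid search adds cost but no
information.

## Evaluation

Accuracy, precision, recall and F1 from the standard 2×2 tally;
0/0 ratios resolve to 0 (conservative). Thresholding defaults to 0.5.
Monte-Carlo cross-validation repeats the stratified 80/20 resplit
(5 repeats by default), oversamples and trains afresh per repeat, and
reports per-metric mean and standard deviation. Within each repeat a
further stratified 80/20 carve-out of the training split provides the
early-stopping validation set.

Feature importance is the L2 norm of each input group, ties broken
alphabetically. Top-fraction selection keeps ⌈fraction × total⌉ features.
F1-versus-fraction curves retrain from scratch per fraction on the
one-hot block plus the selected local-environment features (the one-hot
block is always retained; selection operates on the structural feature
inventory). A masking mode that reuses the ranking model with dropped
features zeroed is available as a cheaper alternative.

The mean-ratio statistic is computed on *unscaled* feature values
(scaler bounds are inverted) so magnitudes keep their physical meaning;
pad positions are excluded from the class means. Equal means give +1,
zero denominators give signed infinities that are carried as flags and
excluded from peak finding.

## Synthetic generators

Toy structures place Cα atoms collinearly at 3.8 Å (extended), on a
parametric α-helix (2.3 Å radius, 1.5 Å rise, 100°/residue), or at
custom coordinates; side chains collapse to a single pseudo-carbon
1.53 Å off the backbone so neighbourhood and SASA arithmetic stays
hand-checkable.

Planted datasets draw baseline feature values from a half-normal
|N(0, σ²)| — mirroring the non-negativity of counts and SASA sums — and
shift the informative features of positive samples upward by
`effect_size·σ` at a chosen subsite or at all positions. Window
sequences are uniform random with forced S/T centres, so the one-hot
block carries no label signal by construction. Because the half-normal
baseline mean is σ√(2/π), a shift of exactly σ√(2/π) doubles the
positive-class mean, i.e. produces a subsite ratio of +2.

The fixed benchmark uses n = 2700 at positive fraction 1/27 (the ~1:26
imbalance of real O-GlcNAcome data), 5 informative of 60 features,
2σ effect planted at all window positions — neighbouring subsites'
structural features are spatially correlated in real structures, and the
benchmark probes group-level feature recovery, not positional attention.
Benchmark training runs the (SGL, SGL) configuration for up to 60
epochs, a budget at which the planted signal is fully separated.

What the generators do *not* emulate: real amino-acid composition,
sequence–structure coupling, motif context, homology redundancy, or the
actual effect sizes of O-GlcNAcylation biology. Passing the planted
recovery suite shows the estimator and selection machinery work at a
known signal-to-noise ratio; it does not certify real-data F1 levels.

## Known limitations

* Subgradient training does not produce exact zeros; group sparsity is a
  threshold statement.
* The LSTM treats the window as a sequence; genuinely spatial relations
  enter only through the precomputed radial features.
* SASA and neighbourhoods use a single static conformer; no ensemble
  averaging.
* The default class table is one reasonable inventory among several; any
  analysis that depends on a specific published feature schema must
  supply that schema's class table.
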