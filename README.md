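# oglcsite

Prediction of protein O-GlcNAcylation sites from 3D structural context,
with an interpretable sparse recurrent classifier.

O-GlcNAcylation — the attachment of O-linked N-acetylglucosamine to
serine/threonine residues — has no consensus sequence motif, which makes
site prediction from the primary sequence alone hard. This package is for
computational biologists who want to (i) derive *local environmental
features* from protein structures: for every residue, the number and total
solvent-accessible surface area (SASA) of neighbouring residues per
physicochemical class (hydrophobicity, polarity, charge, size, ...) within
radial cutoffs of 0, 5, 10, 15, 20 and 25 Å; (ii) train an LSTM over
±N-residue sequence windows whose per-position inputs combine one-hot
amino-acid encoding with those scaled structural features; and (iii) use
structured sparsity penalties to make the model select its own features.

## The model

Training minimizes a penalized objective over all network weights `W`:

    W* = argmin_W  L(y, ŷ) + λ · R(W)

where `L` is mean binary cross-entropy from the two-way softmax head and
`R` is either the Lasso penalty `R_L1(W) = ‖W‖₁` or the sparse group
Lasso

    R_SGL(W) = α · Σ_g √|g| · ‖w_g‖₂ + (1 − α) · ‖W‖₁

over structured groups: the *input group* of feature k is its column
across the four LSTM gate matrices (zeroing it removes the feature), and
the *hidden group* of unit j is its outgoing recurrent weights plus its
row of the first dense layer (zeroing it prunes the unit). Features are
then ranked by their input-group norms `‖w_k‖₂`; retraining on the
top-ranked fraction traces an F1-versus-fraction curve, and the signed
mean-ratio statistic

    ratio(x) =  x̄_pos / x̄_neg   if x̄_pos ≥ x̄_neg,   else  −x̄_neg / x̄_pos

profiles each feature across subsites −N…+N.

Everything numerical (LSTM forward/backward, Adam, the penalties and
their subgradients) is implemented in numpy with analytic gradients, so
runs are deterministic and the gradients are verified against finite
differences in the test-suite.

## Worked example

Embedded feature selection on a synthetic benchmark with known ground
truth (2700 windows at ~1:26 class imbalance, 5 informative out of 60
local-environment features, 2σ effect):

```bash
python examples/04_feature_selection.py
```

```
benchmark: 2700 samples, 100 positive, planted features ['env_007', 'env_019', 'env_023', 'env_041', 'env_055']
test F1 with all features: 100.0%
top 10% of 60 local-environment features: ['env_055', 'env_019', 'env_041', 'env_007', 'env_023', 'env_056']
planted features recovered: 5/5
```

The (SGL, SGL) model separates the planted signal (test F1 100%) and its
input-group weight norms place all five planted features in the top 10%
of the ranking — the embedded feature selection recovered exactly the
features that carry the label signal. The other examples walk through
structure featurization, window/dataset assembly, training, and subsite
ratio profiles; each prints the numbers it computes and what they mean.

A thin CLI mirrors the library for shell pipelines:

```bash
oglcsite featurize --structures pdbs/ --out features.tsv
oglcsite build-dataset --fasta seqs.fa --sites sites.tsv --features features.tsv --out ds.npz
oglcsite train --dataset ds.npz --reg-input sgl --reg-hidden sgl --lam auto --out model.npz
oglcsite rank --model model.npz --out ranking.tsv
```

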