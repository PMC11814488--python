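"""Training the sparse LSTM on an imbalanced synthetic dataset.

Generates windows with a planted feature-label signal at ~1:8 imbalance,
oversamples positives to balance the training split, trains an LSTM with
sparse-group-Lasso penalties on both input and hidden groups, and reports
thresholded test metrics.
"""

import oglcsite as og
from oglcsite.dataset import oversample_positives, split_train_test
from oglcsite.evaluate import confusion_counts, metrics

dataset = og.make_planted_dataset(
    og.PlantedDatasetSpec(
        n_samples=900, n_features=20, informative_features=(2, 11),
        effect_size=2.0, positive_fraction=1 / 9, half_width=5, seed=0,
    )
)
print(f"{len(dataset)} samples, {int(dataset.y.sum())} positive")

train_ds, test_ds = split_train_test(dataset, 0.2, seed=0)
fit_ds, val_ds = split_train_test(train_ds, 0.2, seed=0)
balanced = oversample_positives(fit_ds, seed=0)
print(f"after oversampling: {int(balanced.y.sum())} pos / "
      f"{int((balanced.y == 0).sum())} neg")

spec = og.RegularizedModelSpec(
    input_dim=len(dataset.feature_names), half_width=dataset.half_width,
    hidden_size=8, dense_sizes=(4,), reg_input="sgl", reg_hidden="sgl",
    lam=1e-3, max_epochs=60, batch_size=64, seed=0,
)
fitted = og.train(og.build_model(spec), balanced, val_ds, spec,
                  feature_names=list(dataset.feature_names))
print(f"stopped at epoch {fitted.stopped_epoch} (best epoch {fitted.best_epoch})")

probs = og.predict_proba(fitted, test_ds)
report = metrics(confusion_counts(test_ds.y, og.classify(probs, 0.5)))
for name, value in report.as_percent().items():
    print(f"test {name}: {value:.1f}%")
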