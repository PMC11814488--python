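"""From a protein sequence to a training-ready window dataset.

Finds candidate Ser/Thr sites, cuts +/-N windows (padded at the termini),
joins them with per-residue structural features, and min-max scales the
feature block with bounds learned on the training split only.
"""

import oglcsite as og
from oglcsite.dataset import assemble_samples, scale_dataset, split_train_test

sequence = "MKSTALGDSVKWTRES"
structure = og.make_toy_structure(og.ToyStructureSpec(sequence=sequence))

sites = og.extract_candidate_sites(sequence)
print(f"candidate Ser/Thr sites (1-based): {[s + 1 for s in sites]}")

windows = [og.build_window(sequence, s, half_width=3, protein_id="demo") for s in sites]
print(f"first window around position {sites[0] + 1}: {windows[0].window!r}")

env = og.featurize_sites(structure, list(range(len(sequence))), radii=(0.0, 5.0, 10.0))
env.index = env.index.set_levels(["demo"], level=0)
labels = [1 if sequence[s] == "S" else 0 for s in sites]  # demo labels only

dataset = assemble_samples(windows, env, labels)
train, test = split_train_test(dataset, 0.25, seed=0)
train, test = scale_dataset(train, test)
print(f"dataset: {len(dataset)} samples, window length {dataset.X.shape[1]}, "
      f"{dataset.X.shape[2]} features per position")
print(f"train/test: {len(train)}/{len(test)}, scaled feature range "
      f"[{train.X.min():.1f}, {train.X.max():.1f}]")
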