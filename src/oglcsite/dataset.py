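"""Training-ready datasets of labelled sequence windows.

Each sample couples a Ser/Thr-centred window with a per-position feature
matrix: a 20-column one-hot block followed by the local-environment
block, min–max scaled to [0, 1] with bounds learned on training data
only.  Pad positions are all-zero rows throughout.  Helpers cover
stratified train/test splitting, stratified k-folding and positive-class
oversampling for the ~1:26 class imbalance of O-GlcNAcylation data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .windows import AMINO_ACIDS, SequenceWindow, build_window, one_hot_encode

ONE_HOT_WIDTH = len(AMINO_ACIDS)


@dataclass
class SampleWindow:
    """One candidate site: window, (2N+1, m) feature matrix, binary label."""

    window: SequenceWindow
    features: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != 2 * self.window.half_width + 1:
            raise ValueError("feature matrix must have 2N+1 rows")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class Dataset:
    """A list of samples sharing one ordered feature schema."""

    samples: list[SampleWindow]
    feature_names: list[str]
    scaler_bounds: tuple[np.ndarray, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.feature_names)
        for s in self.samples:
            if s.features.shape[1] != m:
                raise ValueError("sample feature width does not match feature_names")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def X(self) -> np.ndarray:
        """(n, 2N+1, m) stacked feature tensor."""
        return np.stack([s.features for s in self.samples])

    @property
    def y(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    @property
    def half_width(self) -> int:
        return self.samples[0].window.half_width

    def subset(self, indices) -> "Dataset":
        return Dataset(
            samples=[self.samples[i] for i in indices],
            feature_names=list(self.feature_names),
            scaler_bounds=self.scaler_bounds,
            meta=dict(self.meta),
        )

    def restrict_features(self, keep: list[str]) -> "Dataset":
        """Drop feature columns not in ``keep`` (order of the schema preserved)."""
        idx = [i for i, n in enumerate(self.feature_names) if n in set(keep)]
        bounds = None
        if self.scaler_bounds is not None:
            bounds = (self.scaler_bounds[0][idx], self.scaler_bounds[1][idx])
        return Dataset(
            samples=[
                SampleWindow(s.window, s.features[:, idx], s.label)
                for s in self.samples
            ],
            feature_names=[self.feature_names[i] for i in idx],
            scaler_bounds=bounds,
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# scaling

def fit_scaler(table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (min, max) over the training rows."""
    table = np.asarray(table, dtype=float)
    if table.size == 0:
        raise ValueError("cannot fit a scaler on an empty table")
    return table.min(axis=0), table.max(axis=0)


def apply_scaler(
    table: np.ndarray, bounds: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """(x - min) / (max - min), clipped to [0, 1]; constant columns map to 0."""
    lo, hi = bounds
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    scaled = (np.asarray(table, dtype=float) - lo) / safe
    scaled[:, span <= 0] = 0.0
    return np.clip(scaled, 0.0, 1.0)


def scale_dataset(train: Dataset, *others: Dataset) -> tuple[Dataset, ...]:
    """Min–max scale the local-environment block, bounds learned on ``train``.

    The one-hot block (first 20 columns) is already in {0, 1} and passes
    through unchanged; pad positions stay all-zero after scaling.  Returns
    rescaled copies of ``train`` and every dataset in ``others``.
    """
    m = len(train.feature_names)
    rows = []
    for s in train.samples:
        rows.append(s.features[~s.window.pad_mask()])
    flat = np.concatenate(rows, axis=0)
    lo, hi = fit_scaler(flat)
    lo[:ONE_HOT_WIDTH] = 0.0
    hi[:ONE_HOT_WIDTH] = 1.0

    out = []
    for ds in (train, *others):
        if len(ds.feature_names) != m:
            raise ValueError("datasets must share one feature schema")
        samples = []
        for s in ds.samples:
            feats = apply_scaler(s.features, (lo, hi))
            feats[s.window.pad_mask()] = 0.0
            samples.append(SampleWindow(s.window, feats, s.label))
        out.append(
            Dataset(samples, list(ds.feature_names), (lo.copy(), hi.copy()), dict(ds.meta))
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# assembly

def assemble_samples(
    windows: list[SequenceWindow],
    env_features: pd.DataFrame,
    labels: list[int],
) -> Dataset:
    """Join windows with per-residue local-environment rows into a Dataset.

    ``env_features`` is indexed by ``(protein_id, 1-based position)`` as
    produced by :func:`oglcsite.features.featurize_sites` run over *all*
    residues of each protein.  Each window position takes the row of the
    residue it covers; pad positions take zero rows.  Feature order is the
    one-hot block then the local-environment block.  The result is
    unscaled — apply :func:`scale_dataset` after splitting.
    """
    if len(windows) != len(labels):
        raise ValueError("windows and labels differ in length")
    env_names = list(env_features.columns)
    feature_names = [f"aa_{a}" for a in AMINO_ACIDS] + env_names
    samples = []
    for win, label in zip(windows, labels):
        onehot = one_hot_encode(win)
        env = np.zeros((len(win.window), len(env_names)))
        for row, offset in enumerate(range(-win.half_width, win.half_width + 1)):
            if win.window[row] == "-":
                continue
            pos1 = win.site_position + offset + 1
            key = (win.protein_id, pos1)
            try:
                env[row] = env_features.loc[key].to_numpy()
            except KeyError as exc:
                raise KeyError(
                    f"no local-environment row for {win.protein_id} position {pos1}"
                ) from exc
        samples.append(
            SampleWindow(win, np.concatenate([onehot, env], axis=1), int(label))
        )
    return Dataset(samples, feature_names)


# ---------------------------------------------------------------------------
# splitting / resampling

def split_train_test(
    dataset: Dataset, test_fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Stratified, reproducible train/test split (default protocol: 80/20)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    y = dataset.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to stratify")
    idx_train, idx_test = train_test_split(
        np.arange(len(dataset)),
        test_size=test_fraction,
        stratify=y,
        random_state=seed,
    )
    return dataset.subset(sorted(idx_train)), dataset.subset(sorted(idx_test))


def oversample_positives(dataset: Dataset, seed: int) -> Dataset:
    """Replicate positives until they match the negative count.

    Whole copies first; a non-integral remainder is drawn without
    replacement with the given seed.  Negatives are untouched.
    """
    y = dataset.y
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0:
        raise ValueError("no positive samples to oversample")
    if len(pos) >= len(neg):
        return dataset.subset(range(len(dataset)))
    reps, remainder = divmod(len(neg), len(pos))
    rng = np.random.default_rng(seed)
    extra = rng.choice(pos, size=remainder, replace=False)
    indices = np.concatenate([neg, np.tile(pos, reps), extra])
    return dataset.subset(indices.tolist())


def kfold_partition(dataset: Dataset, k: int, seed: int) -> list[Dataset]:
    """k stratified, disjoint, near-equal folds (default protocol: k=5)."""
    if k < 2 or k > len(dataset):
        raise ValueError("need 2 <= k <= n")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        dataset.subset(sorted(test_idx))
        for _, test_idx in skf.split(np.zeros(len(dataset)), dataset.y)
    ]


# ---------------------------------------------------------------------------
# I/O

def save_dataset(dataset: Dataset, path: str | Path) -> None:
    """Serialize to a single .npz archive (features, labels, schema, bounds)."""
    path = Path(path)
    payload = {
        "X": dataset.X,
        "y": dataset.y,
        "windows": np.array([s.window.window for s in dataset.samples]),
        "protein_ids": np.array([s.window.protein_id for s in dataset.samples]),
        "site_positions": np.array(
            [s.window.site_position for s in dataset.samples], dtype=int
        ),
        "half_width": np.array(dataset.half_width),
        "feature_names": np.array(dataset.feature_names),
        "meta": np.array(json.dumps(dataset.meta)),
    }
    if dataset.scaler_bounds is not None:
        payload["scale_min"], payload["scale_max"] = dataset.scaler_bounds
    np.savez_compressed(path, **payload)


def load_dataset(path: str | Path) -> Dataset:
    with np.load(path, allow_pickle=False) as z:
        half = int(z["half_width"])
        samples = [
            SampleWindow(
                SequenceWindow(str(pid), int(pos), str(win), half),
                feats,
                int(label),
            )
            for pid, pos, win, feats, label in zip(
                z["protein_ids"], z["site_positions"], z["windows"], z["X"], z["y"]
            )
        ]
        bounds = None
        if "scale_min" in z:
            bounds = (z["scale_min"], z["scale_max"])
        return Dataset(
            samples,
            [str(n) for n in z["feature_names"]],
            bounds,
            json.loads(str(z["meta"])),
        )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_site_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns protein_id, position_1based, label."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "position_1based", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns {missing}")
    return df


def windows_from_tables(
    sequences: dict[str, str], sites: pd.DataFrame, half_width: int = 10
) -> tuple[list[SequenceWindow], list[int]]:
    """Build windows and labels from a FASTA dict and a site-label table."""
    windows, labels = [], []
    for row in sites.itertuples(index=False):
        seq = sequences[row.protein_id]
        windows.append(
            build_window(seq, int(row.position_1based) - 1, half_width, row.protein_id)
        )
        labels.append(int(row.label))
    return windows, labels
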