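import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import oglcsite as og
from oglcsite.dataset import Dataset, SampleWindow
from oglcsite.windows import SequenceWindow, one_hot_encode

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

GLY_ALA_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  CB  ALA A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      8  C   ALA A   2       3.463   3.711   1.139  1.00  0.00           C
ATOM      9  O   ALA A   2       2.814   3.245   2.080  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def gly_ala_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "gly_ala.pdb"
    path.write_text(GLY_ALA_PDB)
    return path


@pytest.fixture(scope="session")
def gly_pdb(tmp_path_factory):
    """A single glycine: 4 heavy atoms."""
    lines = [l for l in GLY_ALA_PDB.splitlines() if " GLY " in l]
    path = tmp_path_factory.mktemp("pdb") / "gly.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def single_atom_structure(element="C", aa="G"):
    """One residue holding one atom at the origin."""
    return og.make_toy_structure(
        og.ToyStructureSpec(
            sequence=aa,
            geometry="custom",
            custom_coords=[[("CA", element, (0.0, 0.0, 0.0))]],
        )
    )


def separable_dataset(n=500, half_width=2, n_env=3, seed=0):
    """Labelled windows where label == value of env feature 0 at the centre.

    Linearly separable by construction; all other env features are noise.
    """
    rng = np.random.default_rng(seed)
    T = 2 * half_width + 1
    letters = np.array(list(og.AMINO_ACIDS))
    samples = []
    labels = rng.integers(0, 2, size=n)
    for i in range(n):
        chars = letters[rng.integers(0, 20, size=T)]
        chars[half_width] = "S"
        win = SequenceWindow(f"p{i}", half_width, "".join(chars), half_width)
        env = rng.uniform(0, 1, size=(T, n_env))
        env[half_width, 0] = float(labels[i])
        samples.append(
            SampleWindow(win, np.concatenate([one_hot_encode(win), env], axis=1), int(labels[i]))
        )
    names = [f"aa_{a}" for a in og.AMINO_ACIDS] + [f"env_{k:03d}" for k in range(n_env)]
    return Dataset(samples, names)


@pytest.fixture(scope="session")
def small_planted():
    """2000 samples, balanced classes, one informative feature at subsite -2."""
    return og.make_planted_dataset(
        og.PlantedDatasetSpec(
            n_samples=2000,
            n_features=8,
            informative_features=(3,),
            effect_size=2.0,
            positive_fraction=0.5,
            half_width=3,
            label_position=-2,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def tiny_trained():
    """A quickly trained small model on separable data, shared across tests."""
    ds = separable_dataset(n=400, seed=3)
    train_ds, val_ds = og.split_train_test(ds, 0.2, 3)
    spec = og.RegularizedModelSpec(
        input_dim=len(ds.feature_names),
        half_width=ds.half_width,
        hidden_size=8,
        dense_sizes=(4,),
        reg_input="sgl",
        reg_hidden="sgl",
        lam=1e-3,
        max_epochs=40,
        seed=3,
    )
    fitted = og.train(og.build_model(spec), train_ds, val_ds, spec,
                      feature_names=list(ds.feature_names))
    return ds, fitted
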