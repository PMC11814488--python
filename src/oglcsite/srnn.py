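"""Sparse recurrent network: an LSTM classifier with structured penalties.

The classifier reads a sequence window position by position (2N+1 steps of
m-dimensional feature vectors), keeps the final hidden state as a context
vector, and maps it through dense layers to a two-way softmax.  The training
objective is

    W* = argmin_W  L(y, y_hat) + lambda * R(W)

where L is mean binary cross-entropy and R is either an elementwise L1
penalty or the sparse group Lasso

    R_SGL(W) = alpha * sum_g sqrt(|g|) * ||w_g||_2 + (1 - alpha) * ||W||_1

over structured weight groups: the *input group* of feature k collects the
k-th input row across the four LSTM gate matrices (zeroing it is embedded
feature selection), and the *hidden group* of unit j collects its outgoing
recurrent weights plus its row of the first dense layer (zeroing it prunes
the unit).  The sqrt group-size factor is standard and switchable.

Everything is plain numpy with analytic backpropagation through time, so
gradients are exactly checkable against finite differences and runs are
bit-reproducible from the spec seed on a single thread.  Optimisation is
Adam with the penalty subgradient added to the loss gradient; training
stops early on validation cross-entropy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

CLIP_EPS = 1e-7


@dataclass
class RegularizedModelSpec:
    """Architecture + regularization configuration.

    lambda (``lam``) balances loss against penalty; ``alpha`` balances the
    group-L2 and L1 parts of the SGL penalty.  ``reg_input``/``reg_hidden``
    select which layer's groups are penalized ('none', 'l1' or 'sgl').
    """

    input_dim: int
    half_width: int
    hidden_size: int = 16
    dense_sizes: tuple[int, ...] = (8,)
    reg_input: str = "none"
    reg_hidden: str = "none"
    lam: float = 0.0
    alpha: float = 0.5
    learning_rate: float = 1e-3
    max_epochs: int = 300
    patience: int = 10
    min_delta: float = 1e-4
    batch_size: int = 256
    seed: int = 0
    sqrt_group_scaling: bool = True

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.hidden_size < 1 or self.input_dim < 1:
            raise ValueError("hidden_size and input_dim must be >= 1")
        for reg in (self.reg_input, self.reg_hidden):
            if reg not in {"none", "l1", "sgl"}:
                raise ValueError(f"unknown regularization kind {reg!r}")
        self.dense_sizes = tuple(int(d) for d in self.dense_sizes)

    @property
    def window_length(self) -> int:
        return 2 * self.half_width + 1


@dataclass
class ParameterGroups:
    """Index sets into the flat parameter vector for each penalized group."""

    input_groups: list[np.ndarray]
    hidden_groups: list[np.ndarray]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class SparseLSTM:
    """LSTM -> dense stack -> 2-way softmax, parameters in a flat vector."""

    def __init__(self, spec: RegularizedModelSpec):
        self.spec = spec
        m, H = spec.input_dim, spec.hidden_size
        rng = np.random.default_rng(spec.seed)
        k = 1.0 / np.sqrt(H)
        self.Wx = rng.uniform(-k, k, size=(m, 4 * H))
        self.Wh = rng.uniform(-k, k, size=(H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.dense: list[tuple[np.ndarray, np.ndarray]] = []
        prev = H
        for d in (*spec.dense_sizes, 2):
            kk = np.sqrt(2.0 / prev)
            self.dense.append((rng.normal(0.0, kk, size=(prev, d)), np.zeros(d)))
            prev = d

    # -- flat parameter vector -------------------------------------------
    def _arrays(self) -> list[np.ndarray]:
        arrs = [self.Wx, self.Wh, self.b]
        for W, b in self.dense:
            arrs.extend([W, b])
        return arrs

    @property
    def n_parameters(self) -> int:
        return sum(a.size for a in self._arrays())

    def get_flat(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self._arrays()])

    def set_flat(self, flat: np.ndarray) -> None:
        arrs = self._arrays()
        if flat.size != sum(a.size for a in arrs):
            raise ValueError("flat vector size mismatch")
        off = 0
        for a in arrs:
            a[...] = flat[off : off + a.size].reshape(a.shape)
            off += a.size

    def _offsets(self) -> list[int]:
        offs, off = [], 0
        for a in self._arrays():
            offs.append(off)
            off += a.size
        return offs

    def parameter_groups(self) -> ParameterGroups:
        """Input group k = Wx row k; hidden group j = Wh row j + dense0 row j."""
        m, H = self.spec.input_dim, self.spec.hidden_size
        offs = self._offsets()
        wx_off, wh_off, dense0_off = offs[0], offs[1], offs[3]
        d1 = self.dense[0][0].shape[1]
        input_groups = [
            np.arange(wx_off + k * 4 * H, wx_off + (k + 1) * 4 * H) for k in range(m)
        ]
        hidden_groups = [
            np.concatenate(
                [
                    np.arange(wh_off + j * 4 * H, wh_off + (j + 1) * 4 * H),
                    np.arange(dense0_off + j * d1, dense0_off + (j + 1) * d1),
                ]
            )
            for j in range(H)
        ]
        return ParameterGroups(input_groups, hidden_groups)

    # -- forward / backward ----------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        n, T, m = X.shape
        if m != self.spec.input_dim:
            raise ValueError(
                f"input feature dim {m} != spec input_dim {self.spec.input_dim}"
            )
        H = self.spec.hidden_size
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        steps = []
        for t in range(T):
            x = X[:, t, :]
            z = x @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if cache:
                steps.append((x, h, c, i, f, g, o, tc))
            h, c = h_new, c_new
        a = h
        acts = [a]
        for idx, (W, b) in enumerate(self.dense):
            z = a @ W + b
            a = z if idx == len(self.dense) - 1 else np.maximum(z, 0.0)
            acts.append(a)
        logits = acts[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        if cache:
            return probs, (X, steps, acts)
        return probs

    def backward(self, cache, dlogits: np.ndarray) -> np.ndarray:
        """Gradient of the (mean) loss wrt the flat parameter vector."""
        X, steps, acts = cache
        n, T, _ = X.shape
        H = self.spec.hidden_size
        dW_dense = []
        da = dlogits
        for idx in range(len(self.dense) - 1, -1, -1):
            W, _ = self.dense[idx]
            a_in = acts[idx]
            if idx != len(self.dense) - 1:
                da = da * (acts[idx + 1] > 0)  # ReLU mask on this layer's output
            dW = a_in.T @ da
            db = da.sum(axis=0)
            dW_dense.append((dW, db))
            da = da @ W.T
        dW_dense.reverse()

        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db_g = np.zeros_like(self.b)
        dh = da
        dc = np.zeros((n, H))
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, g, o, tc = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x.T @ dz
            dWh += h_prev.T @ dz
            db_g += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f

        grads = [dWx, dWh, db_g]
        for dW, db in dW_dense:
            grads.extend([dW, db])
        return np.concatenate([a.ravel() for a in grads])

    def copy(self) -> "SparseLSTM":
        clone = SparseLSTM(self.spec)
        clone.set_flat(self.get_flat())
        return clone


def build_model(spec: RegularizedModelSpec) -> SparseLSTM:
    """Seed-deterministic untrained model for the given spec."""
    return SparseLSTM(spec)


# ---------------------------------------------------------------------------
# loss and penalties

def cross_entropy(y: np.ndarray, p_pos: np.ndarray, eps: float = CLIP_EPS) -> float:
    """Mean binary cross-entropy, probabilities clipped at eps."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p_pos, dtype=float), eps, 1.0 - eps)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def l1_penalty(w: np.ndarray) -> float:
    """Elementwise L1 norm of the parameter vector."""
    return float(np.abs(np.asarray(w, dtype=float)).sum())


def sgl_penalty(
    w: np.ndarray,
    groups: list[np.ndarray] | None = None,
    alpha: float = 0.5,
    sqrt_group_scaling: bool = True,
) -> float:
    """Sparse-group-Lasso penalty over one layer's weights.

    ``groups`` are index sets into ``w`` (default: one group spanning all of
    it); they must be disjoint.  The group term is scaled by sqrt(group
    size) unless disabled.
    """
    w = np.asarray(w, dtype=float).ravel()
    if groups is None:
        groups = [np.arange(w.size)]
    seen: set[int] = set()
    for g in groups:
        gset = set(int(i) for i in np.asarray(g).ravel())
        if seen & gset:
            raise ValueError("groups within a layer must be disjoint")
        seen |= gset
    group_term = 0.0
    for g in groups:
        scale = np.sqrt(len(g)) if sqrt_group_scaling else 1.0
        group_term += scale * float(np.linalg.norm(w[g]))
    return alpha * group_term + (1.0 - alpha) * l1_penalty(w)


def _layer_penalty_and_grad(
    flat: np.ndarray,
    kind: str,
    groups: list[np.ndarray],
    alpha: float,
    sqrt_scaling: bool,
) -> tuple[float, np.ndarray]:
    grad = np.zeros_like(flat)
    if kind == "none":
        return 0.0, grad
    covered = np.concatenate(groups)
    wl = flat[covered]
    if kind == "l1":
        grad[covered] = np.sign(wl)
        return l1_penalty(wl), grad
    # sgl
    value = 0.0
    for g in groups:
        wg = flat[g]
        nrm = float(np.linalg.norm(wg))
        scale = np.sqrt(len(g)) if sqrt_scaling else 1.0
        value += alpha * scale * nrm
        if nrm > 0:
            grad[g] += alpha * scale * wg / nrm
    value += (1.0 - alpha) * l1_penalty(wl)
    grad[covered] += (1.0 - alpha) * np.sign(wl)
    return value, grad


def penalty_and_grad(
    model: SparseLSTM, spec: RegularizedModelSpec
) -> tuple[float, np.ndarray]:
    """R(W) and its (sub)gradient for the spec's reg_input / reg_hidden choices."""
    flat = model.get_flat()
    groups = model.parameter_groups()
    v1, g1 = _layer_penalty_and_grad(
        flat, spec.reg_input, groups.input_groups, spec.alpha, spec.sqrt_group_scaling
    )
    v2, g2 = _layer_penalty_and_grad(
        flat, spec.reg_hidden, groups.hidden_groups, spec.alpha, spec.sqrt_group_scaling
    )
    return v1 + v2, g1 + g2


def regularized_loss(
    y: np.ndarray,
    p_pos: np.ndarray,
    model: SparseLSTM,
    spec: RegularizedModelSpec,
) -> float:
    """Cross-entropy plus lambda times the configured penalty."""
    value = cross_entropy(y, p_pos)
    if spec.lam > 0:
        value += spec.lam * penalty_and_grad(model, spec)[0]
    return value


def loss_and_grad(
    model: SparseLSTM,
    X: np.ndarray,
    y: np.ndarray,
    spec: RegularizedModelSpec | None = None,
) -> tuple[float, np.ndarray]:
    """Objective value and analytic gradient wrt the flat parameter vector."""
    spec = spec or model.spec
    y = np.asarray(y, dtype=int)
    probs, cache = model.forward(X, cache=True)
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(y)), y] = 1.0
    grad = model.backward(cache, (probs - onehot) / len(y))
    value = cross_entropy(y, probs[:, 1])
    if spec.lam > 0:
        pen, pen_grad = penalty_and_grad(model, spec)
        value += spec.lam * pen
        grad += spec.lam * pen_grad
    return value, grad


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainedModel:
    """A fitted model with its spec, loss trace and early-stopping record."""

    spec: RegularizedModelSpec
    model: SparseLSTM
    training_log: list[tuple[float, float]] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    feature_names: list[str] | None = None
    #: parameters at the last optimization step (the model itself holds the
    #: best-validation parameters); useful for inspecting penalty-driven
    #: sparsity even when validation selection prefers an earlier epoch
    last_parameters: np.ndarray | None = None

    @property
    def parameters(self) -> np.ndarray:
        return self.model.get_flat()


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(data, "X") and hasattr(data, "y"):
        return data.X, data.y
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int)


def train(
    model: SparseLSTM,
    train_data,
    validation_data,
    spec: RegularizedModelSpec | None = None,
    feature_names: list[str] | None = None,
) -> TrainedModel:
    """Adam + early stopping on validation cross-entropy.

    ``train_data``/``validation_data`` are Datasets or (X, y) pairs; the
    training set is expected to be class-balanced already (oversampling is
    the caller's step), the validation set untouched.  The parameters with
    the best validation loss are restored before returning.
    """
    spec = spec or model.spec
    Xtr, ytr = _as_arrays(train_data)
    Xva, yva = _as_arrays(validation_data)
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("training and validation sets must be non-empty")
    # canonical content order: results do not depend on input sample order
    digests = [
        hashlib.md5(Xtr[i].tobytes() + bytes([ytr[i]])).digest()
        for i in range(len(ytr))
    ]
    order0 = sorted(range(len(ytr)), key=digests.__getitem__)
    Xtr, ytr = Xtr[order0], ytr[order0]
    if feature_names is None and hasattr(train_data, "feature_names"):
        feature_names = list(train_data.feature_names)

    rng = np.random.default_rng(spec.seed + 1)
    flat = model.get_flat()
    m_adam = np.zeros_like(flat)
    v_adam = np.zeros_like(flat)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_val = np.inf
    best_flat = flat.copy()
    best_epoch = 0
    log: list[tuple[float, float]] = []
    stall = 0
    epoch = 0
    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(len(Xtr))
        batch_losses = []
        for start in range(0, len(order), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            value, grad = loss_and_grad(model, Xtr[idx], ytr[idx], spec)
            batch_losses.append(value)
            step += 1
            m_adam = beta1 * m_adam + (1 - beta1) * grad
            v_adam = beta2 * v_adam + (1 - beta2) * grad * grad
            mhat = m_adam / (1 - beta1**step)
            vhat = v_adam / (1 - beta2**step)
            flat = model.get_flat() - spec.learning_rate * mhat / (np.sqrt(vhat) + eps)
            model.set_flat(flat)
        val_loss = cross_entropy(yva, model.forward(Xva)[:, 1])
        log.append((float(np.mean(batch_losses)), val_loss))
        if val_loss < best_val - spec.min_delta:
            best_val = val_loss
            best_flat = model.get_flat().copy()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= spec.patience:
                break
    last_flat = model.get_flat().copy()
    model.set_flat(best_flat)
    return TrainedModel(
        spec=spec,
        model=model,
        training_log=log,
        stopped_epoch=epoch,
        best_epoch=best_epoch,
        feature_names=feature_names,
        last_parameters=last_flat,
    )


def predict_proba(model: SparseLSTM | TrainedModel, samples) -> np.ndarray:
    """Probability of the positive class for each sample."""
    net = model.model if isinstance(model, TrainedModel) else model
    X = samples.X if hasattr(samples, "X") else np.asarray(samples, dtype=float)
    out = []
    for start in range(0, len(X), 4096):
        out.append(net.forward(X[start : start + 4096])[:, 1])
    return np.concatenate(out) if out else np.empty(0)


def classify(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff p >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(probabilities) >= threshold).astype(int)


LAMBDA_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)


def select_lambda_cv(
    dataset,
    spec: RegularizedModelSpec,
    grid=LAMBDA_GRID,
    k: int = 5,
    seed: int = 0,
) -> tuple[float, dict[float, float]]:
    """Pick lambda by stratified k-fold CV maximizing mean validation F1.

    Each fold's training part is oversampled to class balance; the held-out
    fold doubles as the early-stopping validation set.  Returns the best
    lambda (ties -> smaller) and the mean-F1 table.
    """
    from dataclasses import replace
    from .dataset import kfold_partition, oversample_positives, Dataset
    from .evaluate import confusion_counts, metrics

    folds = kfold_partition(dataset, k, seed)
    table: dict[float, float] = {}
    for lam in grid:
        scores = []
        for i, fold in enumerate(folds):
            rest = [f for j, f in enumerate(folds) if j != i]
            train_ds = Dataset(
                [s for f in rest for s in f.samples],
                list(dataset.feature_names),
                dataset.scaler_bounds,
            )
            balanced = oversample_positives(train_ds, seed + i)
            fold_spec = replace(spec, lam=float(lam))
            fitted = train(build_model(fold_spec), balanced, fold, fold_spec)
            pred = classify(predict_proba(fitted, fold))
            scores.append(metrics(confusion_counts(fold.y, pred)).f1)
        table[float(lam)] = float(np.mean(scores))
    best = max(sorted(table), key=lambda lam: table[lam])
    return best, table


# ---------------------------------------------------------------------------
# checkpointing

def save_model(trained: TrainedModel, path: str | Path) -> None:
    """Single-archive checkpoint: spec, flat weights, feature names."""
    payload = {
        "format_version": np.array(1),
        "spec": np.array(json.dumps(asdict(trained.spec))),
        "W": trained.model.get_flat(),
        "training_log": np.array(trained.training_log, dtype=float).reshape(-1, 2),
        "stopped_epoch": np.array(trained.stopped_epoch),
        "best_epoch": np.array(trained.best_epoch),
    }
    if trained.feature_names is not None:
        payload["feature_names"] = np.array(trained.feature_names)
    np.savez_compressed(Path(path), **payload)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        cfg = json.loads(str(z["spec"]))
        cfg["dense_sizes"] = tuple(cfg["dense_sizes"])
        spec = RegularizedModelSpec(**cfg)
        model = SparseLSTM(spec)
        model.set_flat(z["W"])
        names = (
            [str(n) for n in z["feature_names"]] if "feature_names" in z else None
        )
        return TrainedModel(
            spec=spec,
            model=model,
            training_log=[tuple(row) for row in z["training_log"]],
            stopped_epoch=int(z["stopped_epoch"]),
            best_epoch=int(z["best_epoch"]),
            feature_names=names,
        )
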