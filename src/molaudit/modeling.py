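"""Binary property classifiers and their training regime.

Two architectures are provided, both implemented directly on NumPy so that
training is exactly reproducible from a seed on any machine:

* a multi-layer perceptron over fingerprint bit-vectors, and
* a message-passing neural network over attributed molecular graphs
  (shared-weight message passing followed by a readout and an MLP head).

Training minimises a class-weighted binary cross-entropy with the AdamW
optimiser (decoupled weight decay), mini-batches of 64, and early stopping
that returns the parameter snapshot of the epoch with the lowest validation
loss.  Shadow models reuse the same loop with early stopping disabled and a
fixed epoch count.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .featurization import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolGraph

Array = np.ndarray


class TrialPruned(Exception):
    """Raised inside the training loop when an epoch callback requests pruning."""


# ---------------------------------------------------------------------------
# Hyperparameters and training configuration
# ---------------------------------------------------------------------------

@dataclass
class MLPHyperparams:
    """Search-space point for the fingerprint MLP."""

    n_layers: int = 2
    hidden_dim: int = 256
    dropout: float = 0.2
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5


@dataclass
class MPNNHyperparams(MLPHyperparams):
    """Search-space point for the graph message-passing network.

    The MLP fields parameterise the classifier head; the extra fields control
    the message-passing encoder.
    """

    message_steps: int = 3
    encoder_dim: int = 128
    encoder_bias: bool = True
    aggregation: str = "mean"  # "mean" | "sum"


@dataclass
class TrainingConfig:
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 64
    optimizer: str = "adamw"
    class_weighting: bool = True
    early_stopping: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# Loss, weights, optimiser
# ---------------------------------------------------------------------------

def class_weights(labels: Sequence[int] | Array) -> Array:
    """Inverse-frequency class weights, normalised to mean 1 over samples.

    Returns ``array([w0, w1])`` with ``w_c = n / (2 * n_c)`` so that the
    average weight across the training samples equals one; the weight ratio
    equals the inverse label-frequency ratio.
    """
    y = np.asarray(labels, dtype=int)
    n = y.size
    counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
    if counts.min() == 0:
        raise ValueError("degenerate_labels: both classes must be present")
    return n / (2.0 * counts)


def _softplus(z: Array) -> Array:
    return np.logaddexp(0.0, z)


def sigmoid(z: Array) -> Array:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def weighted_bce(logits: Array, y: Array, sample_weights: Array) -> float:
    """Mean class-weighted binary cross-entropy on logits."""
    per = _softplus(logits) - y * logits
    return float(np.mean(sample_weights * per))


class AdamW:
    """Adam with decoupled weight decay on a flat parameter list."""

    def __init__(
        self,
        params: list[Array],
        lr: float,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[Array]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p -= self.lr * (update + self.weight_decay * p)


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

class MLPNet:
    """Plain feed-forward network with ReLU hidden layers and one logit output."""

    def __init__(self, in_dim: int, hp: MLPHyperparams, rng: np.random.Generator):
        dims = [in_dim] + [hp.hidden_dim] * hp.n_layers + [1]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self.dropout = hp.dropout
        self.in_dim = in_dim

    def parameters(self) -> list[Array]:
        return self.W + self.b

    def forward(self, X: Array, rng: np.random.Generator | None = None) -> Array:
        h = X
        for i in range(len(self.W) - 1):
            h = np.maximum(h @ self.W[i] + self.b[i], 0.0)
            if rng is not None and self.dropout > 0.0:
                mask = rng.random(h.shape) >= self.dropout
                h = h * mask / (1.0 - self.dropout)
        return (h @ self.W[-1] + self.b[-1]).ravel()

    def loss_and_grads(
        self,
        X: Array,
        y: Array,
        sw: Array,
        rng: np.random.Generator | None,
    ) -> tuple[float, list[Array]]:
        loss, grads, _ = self.loss_grads_input(X, y, sw, rng)
        return loss, grads

    def loss_grads_input(
        self,
        X: Array,
        y: Array,
        sw: Array,
        rng: np.random.Generator | None,
    ) -> tuple[float, list[Array], Array]:
        """Loss, parameter gradients, and the gradient w.r.t. the input."""
        acts = [X]
        masks: list[Array | None] = []
        h = X
        for i in range(len(self.W) - 1):
            z = h @ self.W[i] + self.b[i]
            h = np.maximum(z, 0.0)
            if rng is not None and self.dropout > 0.0:
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        logits = (h @ self.W[-1] + self.b[-1]).ravel()
        loss = weighted_bce(logits, y, sw)
        n = X.shape[0]
        dlogit = (sw * (sigmoid(logits) - y) / n)[:, None]
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        gW[-1] = acts[-1].T @ dlogit
        gb[-1] = dlogit.sum(axis=0)
        dh = dlogit @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            if masks[i] is not None:
                dh = dh * masks[i]
            dh = dh * (acts[i + 1] > 0.0)
            gW[i] = acts[i].T @ dh
            gb[i] = dh.sum(axis=0)
            dh = dh @ self.W[i].T
        return loss, gW + gb, dh


# ---------------------------------------------------------------------------
# Graph batching and MPNN
# ---------------------------------------------------------------------------

@dataclass
class GraphBatch:
    """A list of molecular graphs flattened into shared index arrays."""

    atom_features: Array  # (A, d_a)
    bond_features: Array  # (E, d_b) directed
    src: Array  # (E,) global atom index of the message source
    dst: Array  # (E,) global atom index of the message destination
    mol_index: Array  # (A,) molecule id per atom
    n_mols: int


def batch_graphs(graphs: Sequence[MolGraph]) -> GraphBatch:
    atom_feats, bond_feats, src, dst, mol_idx = [], [], [], [], []
    offset = 0
    for i, g in enumerate(graphs):
        atom_feats.append(g.atom_features)
        mol_idx.append(np.full(g.n_atoms, i, dtype=np.int64))
        if g.edges.shape[0]:
            src.append(g.edges[:, 0].astype(np.int64) + offset)
            dst.append(g.edges[:, 1].astype(np.int64) + offset)
            bond_feats.append(g.bond_features)
        offset += g.n_atoms
    return GraphBatch(
        atom_features=np.concatenate(atom_feats).astype(float),
        bond_features=(
            np.concatenate(bond_feats).astype(float)
            if bond_feats
            else np.zeros((0, BOND_FEATURE_DIM))
        ),
        src=np.concatenate(src) if src else np.zeros(0, dtype=np.int64),
        dst=np.concatenate(dst) if dst else np.zeros(0, dtype=np.int64),
        mol_index=np.concatenate(mol_idx),
        n_mols=len(graphs),
    )


class MPNNNet:
    """Message-passing network: shared-weight updates, readout, MLP head.

    Atom states are initialised by a linear encoder; each of ``message_steps``
    rounds aggregates neighbour states plus encoded bond features and applies
    a shared ReLU update.  Mean or sum readout pools atoms per molecule;
    dropout is applied in the head only.
    """

    def __init__(self, hp: MPNNHyperparams, rng: np.random.Generator):
        d = hp.encoder_dim
        self.hp = hp
        s = lambda fan_in, shape: rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        self.W_enc = s(ATOM_FEATURE_DIM, (ATOM_FEATURE_DIM, d))
        self.b_enc = np.zeros(d) if hp.encoder_bias else None
        self.W_bond = s(BOND_FEATURE_DIM, (BOND_FEATURE_DIM, d))
        self.W_self = s(d, (d, d))
        self.W_msg = s(d, (d, d))
        self.b_upd = np.zeros(d)
        self.head = MLPNet(d, hp, rng)

    def parameters(self) -> list[Array]:
        params = [self.W_enc, self.W_bond, self.W_self, self.W_msg, self.b_upd]
        if self.b_enc is not None:
            params.append(self.b_enc)
        return params + self.head.parameters()

    # -- forward -----------------------------------------------------------
    def _encode(self, batch: GraphBatch) -> tuple[Array, Array, list[dict]]:
        z0 = batch.atom_features @ self.W_enc
        if self.b_enc is not None:
            z0 = z0 + self.b_enc
        h = np.maximum(z0, 0.0)
        caches: list[dict] = [{"z": z0, "h_in": None}]
        eb = batch.bond_features @ self.W_bond  # (E, d)
        for _ in range(self.hp.message_steps):
            msg = np.zeros_like(h)
            if batch.src.size:
                np.add.at(msg, batch.dst, h[batch.src] + eb)
            z = h @ self.W_self + msg @ self.W_msg + self.b_upd
            caches.append({"z": z, "h_in": h, "msg": msg})
            h = np.maximum(z, 0.0)
        return h, eb, caches

    def _readout(self, h: Array, batch: GraphBatch) -> tuple[Array, Array]:
        pooled = np.zeros((batch.n_mols, h.shape[1]))
        np.add.at(pooled, batch.mol_index, h)
        counts = np.bincount(batch.mol_index, minlength=batch.n_mols).astype(float)
        if self.hp.aggregation == "mean":
            pooled = pooled / counts[:, None]
        return pooled, counts

    def forward(self, batch: GraphBatch, rng: np.random.Generator | None = None) -> Array:
        h, _, _ = self._encode(batch)
        pooled, _ = self._readout(h, batch)
        return self.head.forward(pooled, rng)

    def loss_and_grads(
        self,
        batch: GraphBatch,
        y: Array,
        sw: Array,
        rng: np.random.Generator | None,
    ) -> tuple[float, list[Array]]:
        h, eb, caches = self._encode(batch)
        pooled, counts = self._readout(h, batch)
        loss, head_grads, dpooled = self.head.loss_grads_input(pooled, y, sw, rng)
        if self.hp.aggregation == "mean":
            datoms = dpooled[batch.mol_index] / counts[batch.mol_index][:, None]
        else:
            datoms = dpooled[batch.mol_index]
        gW_self = np.zeros_like(self.W_self)
        gW_msg = np.zeros_like(self.W_msg)
        gb_upd = np.zeros_like(self.b_upd)
        g_eb = np.zeros_like(eb)
        dh = datoms
        for cache in caches[:0:-1]:
            dz = dh * (cache["z"] > 0.0)
            gW_self += cache["h_in"].T @ dz
            gW_msg += cache["msg"].T @ dz
            gb_upd += dz.sum(axis=0)
            dmsg = dz @ self.W_msg.T
            dh = dz @ self.W_self.T
            if batch.src.size:
                dedge = dmsg[batch.dst]
                np.add.at(dh, batch.src, dedge)
                g_eb += dedge
        dz0 = dh * (caches[0]["z"] > 0.0)
        gW_enc = batch.atom_features.T @ dz0
        gW_bond = batch.bond_features.T @ g_eb
        grads = [gW_enc, gW_bond, gW_self, gW_msg, gb_upd]
        if self.b_enc is not None:
            grads.append(dz0.sum(axis=0))
        return loss, grads + head_grads


# ---------------------------------------------------------------------------
# Trained-model container and the training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """An opaque fitted classifier plus its provenance."""

    architecture: str  # "mlp" | "mpnn"
    net: MLPNet | MPNNNet
    scheme: str
    data_hash: str
    hyperparams: MLPHyperparams
    history: dict = field(default_factory=dict)


class EarlyStopper:
    """Track the best validation loss and signal a stop after ``patience``
    consecutive non-improving epochs."""

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.bad = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one epoch; returns True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.bad = 0
            return False
        self.bad += 1
        return self.bad >= self.patience


def _features_hash(y: Array) -> str:
    return hashlib.sha256(np.ascontiguousarray(y).tobytes()).hexdigest()[:16]


def _prepare(features, labels):
    y = np.asarray(labels, dtype=float)
    if isinstance(features, np.ndarray):
        return features.astype(float), y, "mlp"
    return features, y, "mpnn"


def _batch_forward(net, features, idx, rng=None):
    if isinstance(net, MLPNet):
        return net.forward(features[idx], rng)
    return net.forward(batch_graphs([features[i] for i in idx]), rng)


def _batch_loss_grads(net, features, idx, y, sw, rng):
    if isinstance(net, MLPNet):
        return net.loss_and_grads(features[idx], y[idx], sw[idx], rng)
    return net.loss_and_grads(
        batch_graphs([features[i] for i in idx]), y[idx], sw[idx], rng
    )


def evaluate_loss(net, features, labels, sample_weights=None) -> float:
    """Class-weighted BCE of ``net`` on a dataset (no dropout)."""
    y = np.asarray(labels, dtype=float)
    sw = np.ones_like(y) if sample_weights is None else sample_weights
    idx = np.arange(len(y))
    logits = _batch_forward(net, features, idx)
    return weighted_bce(logits, y, sw)


def train_model(
    train_features,
    train_labels,
    val_features,
    val_labels,
    hp: MLPHyperparams,
    cfg: TrainingConfig,
    epoch_callback: Callable[[int, float], bool] | None = None,
) -> TrainedModel:
    """Fit a classifier with weighted BCE, AdamW and early stopping.

    ``train_features`` is either a fingerprint matrix (MLP) or a list of
    :class:`MolGraph` (MPNN); the architecture follows the type of ``hp``.
    With early stopping enabled the snapshot of the epoch with minimal
    validation loss is returned and training halts after ``cfg.patience``
    non-improving epochs; otherwise the final epoch's parameters are kept
    (the shadow-model regime).  ``epoch_callback(epoch, val_loss)`` may
    return True to prune the run (used by the hyperparameter search).
    """
    X, y, arch = _prepare(train_features, train_labels)
    if len(y) == 0:
        raise ValueError("empty training set")
    if cfg.early_stopping and (val_features is None or len(val_labels) == 0):
        raise ValueError("early stopping requires a validation set")
    if isinstance(hp, MPNNHyperparams) != (arch == "mpnn"):
        raise ValueError("hyperparameter type does not match the feature type")

    weights = (
        class_weights(y) if cfg.class_weighting else np.ones(2, dtype=float)
    )
    sw = weights[y.astype(int)]
    rng = np.random.default_rng(cfg.seed)
    if arch == "mlp":
        net: MLPNet | MPNNNet = MLPNet(X.shape[1], hp, rng)
    else:
        net = MPNNNet(hp, rng)
    opt = AdamW(net.parameters(), lr=hp.learning_rate, weight_decay=hp.weight_decay)

    if val_features is not None and len(val_labels):
        yv = np.asarray(val_labels, dtype=float)
        swv = weights[yv.astype(int)]
    else:
        yv = swv = None

    stopper = EarlyStopper(cfg.patience)
    best_params = None
    history: dict = {"train_loss": [], "val_loss": []}
    n = len(y)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = _batch_loss_grads(net, X, idx, y, sw, rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={hp.learning_rate}, wd={hp.weight_decay})"
                )
            opt.step(grads)
            epoch_losses.append(loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if yv is not None:
            val_loss = evaluate_loss(net, val_features, yv, swv)
            history["val_loss"].append(val_loss)
            if epoch_callback is not None and epoch_callback(epoch, val_loss):
                raise TrialPruned(f"pruned at epoch {epoch}")
            if cfg.early_stopping:
                improved_to_best = val_loss < stopper.best
                stop = stopper.update(epoch, val_loss)
                if improved_to_best:
                    best_params = [p.copy() for p in net.parameters()]
                if stop:
                    break

    if cfg.early_stopping and best_params is not None:
        for p, bp in zip(net.parameters(), best_params):
            p[...] = bp
    history["best_epoch"] = stopper.best_epoch if cfg.early_stopping else len(
        history["train_loss"]
    )
    return TrainedModel(
        architecture=arch,
        net=net,
        scheme="graph" if arch == "mpnn" else "fingerprint",
        data_hash=_features_hash(y),
        hyperparams=hp,
        history=history,
    )


def predict_logit(model: TrainedModel, features) -> Array:
    """Raw logits of the fitted model for a feature matrix or graph list."""
    if isinstance(features, np.ndarray):
        if model.architecture != "mlp":
            raise ValueError("scheme mismatch: model expects molecular graphs")
        if features.shape[1] != model.net.in_dim:
            raise ValueError(
                f"scheme mismatch: model expects {model.net.in_dim} features, "
                f"got {features.shape[1]}"
            )
        return model.net.forward(features.astype(float))
    if model.architecture != "mpnn":
        raise ValueError("scheme mismatch: model expects fingerprint vectors")
    return model.net.forward(batch_graphs(list(features)))


def predict_proba(model: TrainedModel, features) -> Array:
    """P(label=1); strictly inside (0,1) and monotone in the logit."""
    return sigmoid(predict_logit(model, features))
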