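"""Hyperparameter search: tree-structured Parzen estimator with pruning.

The search minimises validation cross-entropy over a declared space of
uniform / log-uniform / integer / categorical dimensions.  After a random
start-up phase, candidates are drawn from a Parzen mixture fitted to the
best-performing quantile of past trials and ranked by the density ratio
l(x)/g(x) against the remaining trials — the standard TPE acquisition.

Trials are capped at 20 epochs and pruned early when the validation loss
fails to improve for two consecutive epochs, or when it is worse than the
median across trials at the 15-epoch checkpoint.  Wall-clock budgets are
replaced by a trial-count budget so that searches are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Sequence

import numpy as np

from .modeling import (
    MLPHyperparams,
    MPNNHyperparams,
    TrainingConfig,
    TrialPruned,
    train_model,
)

# -- search-space dimensions -------------------------------------------------

@dataclass(frozen=True)
class Uniform:
    low: float
    high: float
    log: bool = False

    def transform(self, x: float) -> float:
        return float(np.log(x)) if self.log else float(x)

    def inverse(self, t: float) -> float:
        x = float(np.exp(t)) if self.log else float(t)
        return float(np.clip(x, self.low, self.high))

    def sample(self, rng: np.random.Generator) -> float:
        if self.log:
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return float(rng.uniform(self.low, self.high))

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high


@dataclass(frozen=True)
class IntUniform:
    low: int
    high: int
    log: bool = False

    def transform(self, x: int) -> float:
        return float(np.log(x)) if self.log else float(x)

    def inverse(self, t: float) -> int:
        x = np.exp(t) if self.log else t
        return int(np.clip(int(round(x)), self.low, self.high))

    def sample(self, rng: np.random.Generator) -> int:
        if self.log:
            return self.inverse(rng.uniform(np.log(self.low), np.log(self.high)))
        return int(rng.integers(self.low, self.high + 1))

    def contains(self, x: int) -> bool:
        return self.low <= x <= self.high and float(x).is_integer()


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def sample(self, rng: np.random.Generator):
        return self.choices[rng.integers(len(self.choices))]

    def contains(self, x) -> bool:
        return x in self.choices


Dimension = Uniform | IntUniform | Categorical
SearchSpace = dict[str, Dimension]


def mlp_search_space() -> SearchSpace:
    """Default intervals for the fingerprint MLP."""
    return {
        "n_layers": IntUniform(1, 3),
        "hidden_dim": IntUniform(64, 1024, log=True),
        "dropout": Uniform(0.0, 0.5),
        "learning_rate": Uniform(1e-4, 1e-2, log=True),
        "weight_decay": Uniform(1e-6, 1e-2, log=True),
    }


def mpnn_search_space() -> SearchSpace:
    """Default intervals for the graph message-passing network."""
    return {
        **mlp_search_space(),
        "message_steps": IntUniform(1, 4),
        "encoder_dim": IntUniform(64, 512, log=True),
        "encoder_bias": Categorical((True, False)),
        "aggregation": Categorical(("mean", "sum")),
    }


# -- TPE sampler -------------------------------------------------------------

class TPESampler:
    """Independent per-dimension Parzen-estimator sampler."""

    def __init__(
        self,
        space: SearchSpace,
        seed: int,
        n_startup: int = 10,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ) -> None:
        if not space:
            raise ValueError("empty search space")
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    def suggest(self, history: Sequence[tuple[dict, float]]) -> dict:
        if len(history) < self.n_startup:
            return {k: d.sample(self.rng) for k, d in self.space.items()}
        ordered = sorted(history, key=lambda pair: pair[1])
        n_good = max(1, int(np.ceil(self.gamma * len(ordered))))
        good = [p for p, _ in ordered[:n_good]]
        bad = [p for p, _ in ordered[n_good:]] or good
        return {
            k: self._suggest_dim(k, d, good, bad)
            for k, d in self.space.items()
        }

    def _suggest_dim(self, name: str, dim: Dimension, good: list, bad: list):
        if isinstance(dim, Categorical):
            k = len(dim.choices)
            cg = np.array(
                [sum(p[name] == c for p in good) + 1.0 for c in dim.choices]
            )
            cb = np.array(
                [sum(p[name] == c for p in bad) + 1.0 for c in dim.choices]
            )
            ratio = (cg / cg.sum()) / (cb / cb.sum())
            best = int(np.argmax(ratio))
            # sample from the good distribution, tilted toward the best ratio
            return dim.choices[best]
        lo, hi = dim.transform(dim.low), dim.transform(dim.high)
        width = hi - lo
        gv = np.array([dim.transform(p[name]) for p in good])
        bv = np.array([dim.transform(p[name]) for p in bad])
        sig_g = max(width / np.sqrt(len(gv) + 1), width * 0.01)
        sig_b = max(width / np.sqrt(len(bv) + 1), width * 0.01)
        centers = self.rng.choice(gv, size=self.n_candidates)
        cands = np.clip(
            centers + self.rng.normal(0.0, sig_g, self.n_candidates), lo, hi
        )
        score = self._log_parzen(cands, gv, sig_g, lo, hi) - self._log_parzen(
            cands, bv, sig_b, lo, hi
        )
        return dim.inverse(float(cands[int(np.argmax(score))]))

    @staticmethod
    def _log_parzen(x: np.ndarray, obs: np.ndarray, sigma: float, lo: float, hi: float) -> np.ndarray:
        # mixture of Gaussians at the observations plus one uniform prior component
        diffs = (x[:, None] - obs[None, :]) / sigma
        comp = np.exp(-0.5 * diffs**2) / (sigma * np.sqrt(2 * np.pi))
        uniform = 1.0 / max(hi - lo, 1e-12)
        dens = (comp.sum(axis=1) + uniform) / (obs.size + 1)
        return np.log(dens + 1e-300)


# -- pruning -----------------------------------------------------------------

class Pruner:
    """Per-trial pruning: 2-epoch stagnation and epoch-15 median rules."""

    CHECKPOINT_EPOCH = 15

    def __init__(self) -> None:
        self.checkpoint_losses: list[float] = []

    def make_callback(self):
        state = {"best": np.inf, "bad": 0}

        def callback(epoch: int, val_loss: float) -> bool:
            if val_loss < state["best"]:
                state["best"] = val_loss
                state["bad"] = 0
            else:
                state["bad"] += 1
                if state["bad"] >= 2:
                    return True
            if epoch == self.CHECKPOINT_EPOCH:
                if (
                    self.checkpoint_losses
                    and val_loss > float(np.median(self.checkpoint_losses))
                ):
                    self.checkpoint_losses.append(val_loss)
                    return True
                self.checkpoint_losses.append(val_loss)
            return False

        return callback


# -- driver ------------------------------------------------------------------

@dataclass
class HPOResult:
    best_params: MLPHyperparams
    best_loss: float
    trials: list[dict]


def optimize_hyperparams(
    train_features,
    train_labels,
    val_features,
    val_labels,
    space: SearchSpace | None = None,
    budget: int = 30,
    seed: int = 0,
    architecture: str = "mlp",
    max_epochs: int = 20,
    batch_size: int = 64,
) -> HPOResult:
    """TPE search for the classifier hyperparameters.

    Each trial trains for at most ``max_epochs`` (default 20) epochs and is
    scored by its lowest observed validation cross-entropy; pruned trials keep
    the loss observed up to the pruning point.  Returns the best point found,
    with every value inside its declared interval.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if space is None:
        space = mlp_search_space() if architecture == "mlp" else mpnn_search_space()
    if not space:
        raise ValueError("empty search space")
    hp_cls = MPNNHyperparams if architecture == "mpnn" else MLPHyperparams
    sampler = TPESampler(space, seed)
    pruner = Pruner()
    history: list[tuple[dict, float]] = []
    trials: list[dict] = []
    seeds = np.random.SeedSequence(seed).spawn(budget)
    for trial_idx in range(budget):
        params = sampler.suggest(history)
        hp = hp_cls(**params)
        cfg = TrainingConfig(
            max_epochs=max_epochs,
            batch_size=batch_size,
            early_stopping=False,
            seed=int(seeds[trial_idx].generate_state(1)[0] % (2**31)),
        )
        losses: list[float] = []

        prune_cb = pruner.make_callback()

        def callback(epoch: int, val_loss: float) -> bool:
            losses.append(val_loss)
            return prune_cb(epoch, val_loss)

        status = "complete"
        try:
            train_model(
                train_features,
                train_labels,
                val_features,
                val_labels,
                hp,
                cfg,
                epoch_callback=callback,
            )
        except TrialPruned:
            status = "pruned"
        except FloatingPointError:
            status = "failed"
        best = float(np.min(losses)) if losses else np.inf
        history.append((params, best))
        trials.append({"params": params, "loss": best, "status": status})
    best_idx = int(np.argmin([t["loss"] for t in trials]))
    return HPOResult(
        best_params=hp_cls(**trials[best_idx]["params"]),
        best_loss=trials[best_idx]["loss"],
        trials=trials,
    )
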