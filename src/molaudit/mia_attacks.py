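"""Black-box membership inference: shadow ensembles, LiRA and RMIA.

The privacy game: an adversary holding data from the same chemical space as
the target model's training set asks, for each query molecule, whether it was
part of training.  Both attacks calibrate on an ensemble of *shadow models* —
models with the target's hyperparameters trained on random 50% subsets of a
pool drawn from the same distribution — with recorded per-record IN/OUT
membership:

* **LiRA** fits per-query Gaussians to the rescaled correct-class confidences
  of the IN and OUT shadows and scores the target model's confidence by the
  log density ratio.
* **RMIA** compares the ratio P(m|f)/P(m) for the query against the same
  ratio for random reference molecules z from the population, scoring the
  fraction of z dominated by a factor γ (default 2).

Higher scores always mean "more member-like".  One ensemble serves both
attacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chem_data import DatasetSplit, MoleculeRecord
from .modeling import (
    MLPHyperparams,
    TrainedModel,
    TrainingConfig,
    predict_proba,
    train_model,
)

#: Probability clamp used when rescaling confidences to logit space.
LOGIT_EPS = 1e-6

#: Variance floor for the per-query Gaussian fits in LiRA.
VARIANCE_FLOOR = 1e-4

#: Probability floor used in RMIA's ratio denominators.
RMIA_EPS = 1e-8


# ---------------------------------------------------------------------------
# Query assembly
# ---------------------------------------------------------------------------

@dataclass
class QuerySet:
    """Membership queries: all training records (members) plus half as many
    population records (nonmembers), the 2:1 design with member fraction 2/3.

    ``z_records`` are the population records *not* used as nonmember queries;
    they supply RMIA's reference points and stay disjoint from the training
    set.
    """

    records: list[MoleculeRecord]
    truth: np.ndarray  # bool, True = member
    z_records: list[MoleculeRecord]
    seed: int

    @property
    def member_fraction(self) -> float:
        return float(self.truth.mean())

    @property
    def n_members(self) -> int:
        return int(self.truth.sum())


def assemble_query_set(split: DatasetSplit, seed: int) -> QuerySet:
    """Build the 2:1 member:nonmember query set from a dataset split.

    All N training records enter as members; ⌈N/2⌉ population records are
    drawn (seed-deterministically) as nonmembers.  The remaining population
    records become RMIA's reference pool.
    """
    n = len(split.train)
    n_non = int(np.ceil(n / 2))
    if len(split.population) < n_non:
        raise ValueError(
            f"population pool ({len(split.population)}) smaller than the "
            f"required {n_non} nonmember queries"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(split.population))
    nonmembers = [split.population[i] for i in order[:n_non]]
    z_records = [split.population[i] for i in order[n_non:]]
    records = list(split.train) + nonmembers
    truth = np.zeros(len(records), dtype=bool)
    truth[:n] = True
    return QuerySet(records=records, truth=truth, z_records=z_records, seed=seed)


# ---------------------------------------------------------------------------
# Shadow ensemble
# ---------------------------------------------------------------------------

@dataclass
class ShadowEnsemble:
    """Trained shadow models with per-record membership masks.

    ``mask[s, i]`` is True when pool record ``i`` was in shadow ``s``'s
    training subset.  Every query record is guaranteed at least one IN and
    one OUT shadow.
    """

    models: list[TrainedModel]
    pool_records: list[MoleculeRecord]
    mask: np.ndarray  # (n_shadows, n_pool) bool
    epochs: int
    fraction: float

    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {r.smiles: i for i, r in enumerate(self.pool_records)}

    @property
    def n_shadows(self) -> int:
        return len(self.models)

    def membership_of(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        """(n_shadows, n_records) IN mask for records that are in the pool."""
        idx = [self._index[r.smiles] for r in records]
        return self.mask[:, idx]

    def predict_correct_class(
        self, features, labels: Sequence[int]
    ) -> np.ndarray:
        """(n_shadows, n_records) probability each shadow gives the true label."""
        return np.stack(
            [correct_class_proba(m, features, labels) for m in self.models]
        )


def _repair_mask(
    mask: np.ndarray, query_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Flip single entries so every query record has ≥1 IN and ≥1 OUT shadow."""
    n_shadows = mask.shape[0]
    for i in query_idx:
        col = mask[:, i]
        if col.all():
            mask[rng.integers(n_shadows), i] = False
        elif not col.any():
            mask[rng.integers(n_shadows), i] = True
    return mask


def train_shadow_ensemble(
    pool_records: Sequence[MoleculeRecord],
    pool_features,
    query_records: Sequence[MoleculeRecord],
    hp: MLPHyperparams,
    n_shadows: int = 10,
    fraction: float = 0.5,
    epochs: int = 15,
    seed: int = 0,
    batch_size: int = 64,
    max_resample: int = 20,
) -> ShadowEnsemble:
    """Train ``n_shadows`` models on random ``fraction`` subsets of the pool.

    The pool is the union of the target's training set and the population
    subset, so both member and nonmember queries can appear IN and OUT of
    shadows.  Shadows share the target's hyperparameters and train for
    exactly ``epochs`` epochs (no early stopping).  Subsets are redrawn, then
    minimally flipped, until every query record is IN at least one shadow and
    OUT of at least one; an error is raised only if coverage is impossible.
    """
    if n_shadows < 2:
        raise ValueError("need at least two shadow models for IN/OUT coverage")
    index = {r.smiles: i for i, r in enumerate(pool_records)}
    missing = [r.smiles for r in query_records if r.smiles not in index]
    if missing:
        raise ValueError(
            f"{len(missing)} query records are outside the shadow pool"
        )
    query_idx = np.asarray([index[r.smiles] for r in query_records])
    n_pool = len(pool_records)
    n_subset = int(round(fraction * n_pool))
    rng = np.random.default_rng(seed)

    mask = None
    for _ in range(max_resample):
        cand = np.zeros((n_shadows, n_pool), dtype=bool)
        for s in range(n_shadows):
            cand[s, rng.permutation(n_pool)[:n_subset]] = True
        col = cand[:, query_idx]
        if col.any(axis=0).all() and (~col).any(axis=0).all():
            mask = cand
            break
        mask = cand
    if mask is None or not (
        mask[:, query_idx].any(axis=0).all()
        and (~mask[:, query_idx]).any(axis=0).all()
    ):
        mask = _repair_mask(mask, query_idx, rng)

    labels = np.asarray([r.label for r in pool_records])
    is_matrix = isinstance(pool_features, np.ndarray)
    models: list[TrainedModel] = []
    shadow_seeds = np.random.SeedSequence(seed).spawn(n_shadows)
    for s in range(n_shadows):
        idx = np.flatnonzero(mask[s])
        feats = (
            pool_features[idx]
            if is_matrix
            else [pool_features[i] for i in idx]
        )
        cfg = TrainingConfig(
            max_epochs=epochs,
            batch_size=batch_size,
            early_stopping=False,
            seed=int(shadow_seeds[s].generate_state(1)[0] % (2**31)),
        )
        models.append(
            train_model(feats, labels[idx], None, None, hp, cfg)
        )
    return ShadowEnsemble(
        models=models,
        pool_records=list(pool_records),
        mask=mask,
        epochs=epochs,
        fraction=fraction,
    )


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def correct_class_proba(
    model: TrainedModel, features, labels: Sequence[int]
) -> np.ndarray:
    """Model probability of each record's true label."""
    p1 = predict_proba(model, features)
    y = np.asarray(labels)
    return np.where(y == 1, p1, 1.0 - p1)


def correct_class_logit(
    model: TrainedModel, features, labels: Sequence[int]
) -> np.ndarray:
    """Rescaled confidence log(p/(1−p)) computed directly from the raw logit.

    For a one-logit binary model the logit-rescaled correct-class confidence
    equals the signed output logit, which avoids the precision loss of
    passing through the sigmoid when the model is very confident.
    """
    from .modeling import predict_logit

    z = predict_logit(model, features)
    y = np.asarray(labels)
    return np.where(y == 1, z, -z)


def rescaled_confidence(p_correct: np.ndarray | float) -> np.ndarray | float:
    """Logit-rescaled correct-class probability, clamped away from {0, 1}."""
    p = np.clip(np.asarray(p_correct, dtype=float), LOGIT_EPS, 1.0 - LOGIT_EPS)
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def lira_log_ratio(
    c_star: float, mu_in: float, sigma_in: float, mu_out: float, sigma_out: float
) -> float:
    """Closed-form Gaussian log density ratio log N(c*; in) − log N(c*; out)."""
    return float(
        np.log(sigma_out / sigma_in)
        - 0.5 * ((c_star - mu_in) / sigma_in) ** 2
        + 0.5 * ((c_star - mu_out) / sigma_out) ** 2
    )


def lira_score_from_confidences(
    c_star: float,
    in_confidences: np.ndarray,
    out_confidences: np.ndarray,
    variance_floor: float = VARIANCE_FLOOR,
) -> float:
    """LiRA score of one query from its IN/OUT shadow confidences.

    Fits Normal(μ, σ²) to each group (population variance, floored at
    ``variance_floor``) and returns the log density ratio at the target
    model's rescaled confidence ``c_star``.
    """
    in_c = np.asarray(in_confidences, dtype=float)
    out_c = np.asarray(out_confidences, dtype=float)
    if in_c.size == 0 or out_c.size == 0:
        raise ValueError("query needs at least one IN and one OUT shadow")
    mu_in, mu_out = in_c.mean(), out_c.mean()
    sd_in = np.sqrt(max(in_c.var(), variance_floor))
    sd_out = np.sqrt(max(out_c.var(), variance_floor))
    return lira_log_ratio(c_star, mu_in, sd_in, mu_out, sd_out)


def lira_scores(
    target_confidences: np.ndarray,
    shadow_confidences: np.ndarray,
    in_mask: np.ndarray,
    variance_floor: float = VARIANCE_FLOOR,
) -> np.ndarray:
    """Vectorised LiRA over queries.

    ``shadow_confidences``: (n_shadows, n_queries) rescaled correct-class
    confidences; ``in_mask``: matching IN/OUT flags.
    """
    n_q = shadow_confidences.shape[1]
    return np.array(
        [
            lira_score_from_confidences(
                float(target_confidences[q]),
                shadow_confidences[in_mask[:, q], q],
                shadow_confidences[~in_mask[:, q], q],
                variance_floor,
            )
            for q in range(n_q)
        ]
    )


@dataclass
class RMIAConfig:
    """RMIA settings: dominance threshold γ and the reference-point cap."""

    gamma: float = 2.0
    n_z: int | None = None  # None = use every available reference point

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def rmia_scores(
    target_p_m: np.ndarray,
    shadow_p_m: np.ndarray,
    target_p_z: np.ndarray,
    shadow_p_z: np.ndarray,
    gamma: float = 2.0,
    eps: float = RMIA_EPS,
) -> np.ndarray:
    """RMIA scores for all queries against shared reference points.

    ``target_p_m``: (n_queries,) target-model correct-class probability of
    each query m; ``shadow_p_m``: (n_shadows, n_queries) the same under each
    shadow; ``target_p_z`` / ``shadow_p_z``: likewise for reference points z.
    The score of m is the fraction of z with ratio(m)/ratio(z) ≥ γ, where
    ratio(·) = P(·|f_target) / mean_shadows P(·|shadow).
    """
    if target_p_z.size == 0:
        raise ValueError("RMIA needs at least one reference point z")
    p_m = np.maximum(shadow_p_m.mean(axis=0), eps)
    p_z = np.maximum(shadow_p_z.mean(axis=0), eps)
    ratio_m = np.maximum(target_p_m, eps) / p_m  # (n_queries,)
    ratio_z = np.maximum(target_p_z, eps) / p_z  # (n_z,)
    # relative tolerance so exact boundary cases are not lost to rounding
    dominance = ratio_m[:, None] / ratio_z[None, :] >= gamma * (1.0 - 1e-12)
    return dominance.mean(axis=1)


def rmia_score(
    target_p_m: float,
    shadow_p_m: np.ndarray,
    target_p_z: np.ndarray,
    shadow_p_z: np.ndarray,
    cfg: RMIAConfig | None = None,
) -> float:
    """Single-query RMIA score (see :func:`rmia_scores`)."""
    cfg = cfg or RMIAConfig()
    return float(
        rmia_scores(
            np.asarray([target_p_m]),
            np.asarray(shadow_p_m)[:, None],
            np.asarray(target_p_z),
            np.asarray(shadow_p_z),
            gamma=cfg.gamma,
        )[0]
    )


# ---------------------------------------------------------------------------
# Attack results
# ---------------------------------------------------------------------------

@dataclass
class AttackResult:
    """Per-query membership scores for one attack; higher = more member-like."""

    attack: str  # "LiRA" | "RMIA"
    keys: list[str]
    scores: np.ndarray
    truth: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.keys) or len(self.truth) != len(self.keys):
            raise ValueError("scores, truth and keys must be the same length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "smiles": self.keys,
                "truth": self.truth.astype(int),
                "score": self.scores,
                "attack": self.attack,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AttackResult":
        df = pd.read_csv(path)
        return cls(
            attack=str(df["attack"].iloc[0]),
            keys=list(df["smiles"].astype(str)),
            scores=df["score"].to_numpy(float),
            truth=df["truth"].to_numpy(int).astype(bool),
        )


def decide(result: AttackResult, threshold: float) -> set[str]:
    """Records predicted member: score strictly greater than the threshold."""
    return {k for k, s in zip(result.keys, result.scores) if s > threshold}


# ---------------------------------------------------------------------------
# High-level attack driver (shared shadow ensemble)
# ---------------------------------------------------------------------------

def run_attacks(
    target_model: TrainedModel,
    ensemble: ShadowEnsemble,
    query_set: QuerySet,
    featurizer: Callable[[Sequence[MoleculeRecord]], object],
    rmia_cfg: RMIAConfig | None = None,
    seed: int = 0,
) -> dict[str, AttackResult]:
    """Score every query with both LiRA and RMIA from one shadow ensemble."""
    rmia_cfg = rmia_cfg or RMIAConfig()
    q_records = query_set.records
    q_labels = [r.label for r in q_records]
    q_feats = featurizer(q_records)

    target_p = correct_class_proba(target_model, q_feats, q_labels)
    shadow_p = ensemble.predict_correct_class(q_feats, q_labels)
    in_mask = ensemble.membership_of(q_records)

    target_conf = correct_class_logit(target_model, q_feats, q_labels)
    shadow_conf = np.stack(
        [correct_class_logit(m, q_feats, q_labels) for m in ensemble.models]
    )
    lira = lira_scores(target_conf, shadow_conf, in_mask)

    z_records = query_set.z_records
    if rmia_cfg.n_z is not None and len(z_records) > rmia_cfg.n_z:
        rng = np.random.default_rng(seed)
        pick = rng.permutation(len(z_records))[: rmia_cfg.n_z]
        z_records = [z_records[i] for i in pick]
    z_labels = [r.label for r in z_records]
    z_feats = featurizer(z_records)
    target_pz = correct_class_proba(target_model, z_feats, z_labels)
    shadow_pz = ensemble.predict_correct_class(z_feats, z_labels)

    rmia = rmia_scores(
        target_p, shadow_p, target_pz, shadow_pz, gamma=rmia_cfg.gamma
    )

    keys = [r.smiles for r in q_records]
    truth = query_set.truth.copy()
    return {
        "LiRA": AttackResult("LiRA", keys, lira, truth),
        "RMIA": AttackResult("RMIA", keys, rmia, truth),
    }
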