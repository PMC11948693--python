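"""Synthetic molecule libraries and oracle adversaries.

The generator assembles drug-like SMILES from a small fragment grammar
(ring systems joined by linkers, with terminal decorations) and plants a
learnable structure–activity rule: a molecule is active iff it carries a
designated pharmacophore-like substructure (a sulfonamide), with optional
label-flip noise.  This emulates the shape of the real assay datasets the
package targets — valid unique canonical SMILES, controllable class
imbalance, a learnable rule — without requiring any download.

A chemistry-free mode (random bit-vectors with a linear rule) exercises the
attack machinery without touching the chemistry toolkit, and a
uniform-score ``random_adversary`` provides the analytic random-guessing
oracle used to calibrate the evaluation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

from .chem_data import DatasetSplit, MoleculeRecord, split_dataset, standardize_molecule
from .featurization import fingerprint_matrix
from .mia_attacks import (
    AttackResult,
    QuerySet,
    ShadowEnsemble,
    assemble_query_set,
    train_shadow_ensemble,
)
from .modeling import (
    MLPHyperparams,
    TrainedModel,
    TrainingConfig,
    predict_proba,
    train_model,
)

# -- fragment grammar --------------------------------------------------------

_RINGS = (
    "c1ccccc1",
    "c1ccncc1",
    "c1cnccn1",
    "c1ccsc1",
    "c1ccoc1",
    "c1cc[nH]c1",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1CCOCC1",
    "C1CCCC1",
)
_LINKERS = ("", "C", "CC", "CCC", "O", "N", "CO", "CN", "C(=O)", "C(=O)N", "S", "C=C")
_TAILS = ("", "C", "CC", "O", "OC", "N", "F", "Cl", "Br", "C(C)C", "C(=O)O", "C#N")

#: The planted pharmacophore-like fragment: a primary sulfonamide.
PHARMACOPHORE_SMILES = "S(=O)(=O)N"
PHARMACOPHORE = Chem.MolFromSmarts("S(=O)(=O)N")


@dataclass
class SyntheticLibrary:
    """Generated molecule records emulating a labelled screening library."""

    records: list[MoleculeRecord]
    positive_rate: float
    noise: float
    seed: int
    rule: str = PHARMACOPHORE_SMILES

    @property
    def empirical_positive_rate(self) -> float:
        return float(np.mean([r.label for r in self.records]))


def has_pharmacophore(smiles: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    return mol is not None and mol.HasSubstructMatch(PHARMACOPHORE)


def generate_synthetic_library(
    n: int,
    positive_rate: float = 0.25,
    noise: float = 0.0,
    seed: int = 0,
    max_attempts_per_molecule: int = 50,
) -> SyntheticLibrary:
    """Generate ``n`` unique canonical molecules with a planted activity rule.

    Each molecule is two or three ring systems joined by linkers with a
    terminal decoration; with adjusted probability the sulfonamide
    pharmacophore is attached.  The raw label is 1 iff the pharmacophore is
    present, then flipped with probability ``noise``; the attachment
    probability is corrected so the *post-noise* positive rate targets
    ``positive_rate``.  Duplicates are regenerated until ``n`` unique
    canonical SMILES exist.
    """
    if n < 20:
        raise ValueError("n must be at least 20")
    if not 0.0 < positive_rate < 1.0:
        raise ValueError("positive_rate must be in (0, 1)")
    if not 0.0 <= noise < 0.5:
        raise ValueError("noise must be in [0, 0.5)")
    if noise > min(positive_rate, 1.0 - positive_rate):
        raise ValueError(
            "noise exceeds the target positive rate; the post-noise rate "
            "cannot reach the target"
        )
    # P(pharmacophore) solving p'(1-noise) + (1-p')noise = positive_rate
    p_attach = (
        (positive_rate - noise) / (1.0 - 2.0 * noise)
        if noise < 0.5
        else positive_rate
    )
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    attempts = 0
    budget = max_attempts_per_molecule * n
    while len(records) < n:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"could not reach {n} unique molecules within {budget} attempts"
            )
        parts = [rng.choice(_RINGS), rng.choice(_LINKERS), rng.choice(_RINGS)]
        if rng.random() < 0.4:
            parts += [rng.choice(_LINKERS), rng.choice(_RINGS)]
        active = bool(rng.random() < p_attach)
        if active:
            parts.append(PHARMACOPHORE_SMILES)
        else:
            parts.append(rng.choice(_TAILS))
        smiles = "".join(parts)
        canonical = standardize_molecule(smiles)
        if not isinstance(canonical, str) or canonical in seen:
            continue
        label = int(has_pharmacophore(canonical))
        if noise > 0.0 and rng.random() < noise:
            label = 1 - label
        seen.add(canonical)
        records.append(MoleculeRecord(canonical, label))
    return SyntheticLibrary(
        records=records, positive_rate=positive_rate, noise=noise, seed=seed
    )


def make_fingerprint_featurizer(scheme: str) -> Callable:
    """Featurizer closure with a per-call cache keyed by canonical SMILES."""
    cache: dict[str, np.ndarray] = {}

    def featurize(records: Sequence[MoleculeRecord]) -> np.ndarray:
        missing = [r for r in records if r.smiles not in cache]
        if missing:
            mat = fingerprint_matrix(missing, scheme)
            for r, row in zip(missing, mat):
                cache[r.smiles] = row
        return np.stack([cache[r.smiles] for r in records]).astype(np.float32)

    return featurize


# -- chemistry-free mode -----------------------------------------------------

@dataclass
class ChemFreeLibrary:
    """Random-bit-vector records with a linear label rule (no chemistry).

    Record keys are synthetic identifiers, not SMILES; the featurizer maps
    keys back to their fixed random bit-vectors.  Useful for fast attack
    unit tests whose correctness does not depend on the chemistry toolkit.
    """

    records: list[MoleculeRecord]
    features: dict[str, np.ndarray]
    weights: np.ndarray
    seed: int

    def featurizer(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        return np.stack([self.features[r.smiles] for r in records]).astype(float)


def generate_chemistry_free_library(
    n: int,
    dim: int = 128,
    positive_rate: float = 0.3,
    noise: float = 0.05,
    seed: int = 0,
) -> ChemFreeLibrary:
    """Random binary feature vectors labelled by a noisy linear rule."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, dim)) < 0.2).astype(float)
    w = rng.normal(size=dim)
    margin = X @ w
    threshold = np.quantile(margin, 1.0 - positive_rate)
    labels = (margin > threshold).astype(int)
    flip = rng.random(n) < noise
    labels[flip] = 1 - labels[flip]
    if labels.min() == labels.max():  # degenerate draw; force both classes
        labels[0] = 1 - labels[0]
    records = [
        MoleculeRecord(f"cf-{seed}-{i:06d}", int(labels[i])) for i in range(n)
    ]
    features = {r.smiles: X[i] for i, r in enumerate(records)}
    return ChemFreeLibrary(records=records, features=features, weights=w, seed=seed)


# -- oracle adversaries ------------------------------------------------------

def random_adversary(m_members: int, n_nonmembers: int, seed: int = 0) -> AttackResult:
    """Uniform-score adversary: scores carry no membership information."""
    if m_members < 1 or n_nonmembers < 1:
        raise ValueError("need at least one member and one nonmember")
    rng = np.random.default_rng(seed)
    total = m_members + n_nonmembers
    truth = np.zeros(total, dtype=bool)
    truth[:m_members] = True
    return AttackResult(
        attack="random",
        keys=[f"q{i}" for i in range(total)],
        scores=rng.random(total),
        truth=truth,
    )


def mean_identified_random(
    m_members: int,
    n_nonmembers: int,
    rank: int = 1,
    n_replicates: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo mean (and standard error) of the number of members a
    uniform-score adversary flags when the threshold sits at the ``rank``-th
    highest nonmember score (rank 1 = FPR 0; strict-greater rule).

    The exact order-statistics expectation is m·rank/(n+1).
    """
    if rank < 1 or rank > n_nonmembers:
        raise ValueError("rank must be between 1 and the nonmember count")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_replicates)
    # chunked to bound memory for large replicate counts
    chunk = max(1, int(5e7 // (m_members + n_nonmembers)) or 1)
    done = 0
    while done < n_replicates:
        size = min(chunk, n_replicates - done)
        member = rng.random((size, m_members))
        non = rng.random((size, n_nonmembers))
        thr = np.partition(non, n_nonmembers - rank, axis=1)[:, n_nonmembers - rank]
        counts[done : done + size] = (member > thr[:, None]).sum(axis=1)
        done += size
    return float(counts.mean()), float(counts.std(ddof=1) / np.sqrt(n_replicates))


def expected_identified_random(m_members: int, n_nonmembers: int, rank: int = 1) -> float:
    """Closed-form expectation m·rank/(n+1) for the uniform-score adversary."""
    return m_members * rank / (n_nonmembers + 1)


# -- memorization testbed ----------------------------------------------------

@dataclass
class TestbedConfig:
    """Settings for a deliberately leaky target model on synthetic data."""

    __test__ = False  # not a pytest collection target

    n: int = 500
    representation: str = "ECFP4"  # fingerprint scheme, or "chemfree"
    positive_rate: float = 0.25
    noise: float = 0.05
    chemfree_dim: int = 128
    n_shadows: int = 8
    shadow_epochs: int = 15
    target_epochs: int = 40
    hidden_dim: int = 256
    n_layers: int = 1
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    memorization_threshold: float = 0.99


@dataclass
class Testbed:
    """A leaky target model with its query set and shadow ensemble."""

    __test__ = False  # not a pytest collection target

    target_model: TrainedModel
    query_set: QuerySet
    ensemble: ShadowEnsemble
    featurizer: Callable
    split: DatasetSplit
    train_accuracy: float
    population_accuracy: float
    memorized: bool  # train accuracy reached the memorisation threshold


def _records_and_featurizer(cfg: TestbedConfig, seed: int):
    if cfg.representation == "chemfree":
        lib = generate_chemistry_free_library(
            cfg.n, cfg.chemfree_dim, cfg.positive_rate, cfg.noise, seed
        )
        return lib.records, lib.featurizer
    lib = generate_synthetic_library(cfg.n, cfg.positive_rate, cfg.noise, seed)
    return lib.records, make_fingerprint_featurizer(cfg.representation)


def memorization_testbed(
    cfg: TestbedConfig | None = None,
    records: Sequence[MoleculeRecord] | None = None,
    featurizer: Callable | None = None,
) -> Testbed:
    """Build a target model that overfits a small library, plus the attack
    inputs needed to probe it.

    With dropout and weight decay at zero and a fixed epoch budget the MLP
    memorises its training set (≥ 99% training accuracy is asserted via the
    ``memorized`` flag), producing a measurable generalisation gap for the
    attacks to exploit.  Pass ``records``/``featurizer`` to reuse one
    library across repetitions; everything downstream is seed-deterministic.
    """
    cfg = cfg or TestbedConfig()
    if records is None or featurizer is None:
        records, featurizer = _records_and_featurizer(cfg, cfg.seed)
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    s_split, s_query, s_shadow, s_train = (
        int(s.generate_state(1)[0] % (2**31)) for s in seeds
    )
    split = split_dataset(list(records), s_split)
    query_set = assemble_query_set(split, s_query)

    hp = MLPHyperparams(
        n_layers=cfg.n_layers,
        hidden_dim=cfg.hidden_dim,
        dropout=0.0,
        learning_rate=cfg.learning_rate,
        weight_decay=0.0,
    )
    X_train = featurizer(split.train)
    y_train = np.array([r.label for r in split.train])
    X_val = featurizer(split.validation)
    y_val = np.array([r.label for r in split.validation])
    target = train_model(
        X_train,
        y_train,
        X_val,
        y_val,
        hp,
        TrainingConfig(
            max_epochs=cfg.target_epochs,
            batch_size=cfg.batch_size,
            early_stopping=False,
            seed=s_train,
        ),
    )
    train_acc = float(
        ((predict_proba(target, X_train) > 0.5).astype(int) == y_train).mean()
    )
    X_pop = featurizer(split.population)
    y_pop = np.array([r.label for r in split.population])
    pop_acc = float(
        ((predict_proba(target, X_pop) > 0.5).astype(int) == y_pop).mean()
    )

    pool = list(split.train) + list(split.population)
    ensemble = train_shadow_ensemble(
        pool,
        featurizer(pool),
        query_set.records,
        hp,
        n_shadows=cfg.n_shadows,
        epochs=cfg.shadow_epochs,
        seed=s_shadow,
        batch_size=cfg.batch_size,
    )
    return Testbed(
        target_model=target,
        query_set=query_set,
        ensemble=ensemble,
        featurizer=featurizer,
        split=split,
        train_accuracy=train_acc,
        population_accuracy=pop_acc,
        memorized=train_acc >= cfg.memorization_threshold,
    )


def null_testbed(cfg: TestbedConfig | None = None) -> Testbed:
    """Negative control: the target model never saw any query record.

    Queries and shadows are built from one library while the target trains
    on a second, disjoint library from the same generator.  Since the
    "members" were never in the target's training data, both attacks should
    be uninformative (ROC area ≈ 0.5) — the calibration check that score
    pipelines do not leak through bookkeeping.
    """
    cfg = cfg or TestbedConfig()
    seeds = np.random.SeedSequence(cfg.seed).spawn(6)
    ints = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    s_lib_b, s_split, s_query, s_shadow, s_train, s_split_b = ints

    records_a, featurizer_a = _records_and_featurizer(cfg, cfg.seed)
    cfg_b = TestbedConfig(**{**cfg.__dict__, "seed": s_lib_b})
    records_b, featurizer_b = _records_and_featurizer(cfg_b, s_lib_b)
    keys_a = {r.smiles for r in records_a}
    records_b = [r for r in records_b if r.smiles not in keys_a]

    if cfg.representation == "chemfree":
        # merge the two key->vector maps into one featurizer
        def featurizer(records):
            out = []
            for r in records:
                src = featurizer_a if r.smiles in keys_a else featurizer_b
                out.append(src([r])[0])
            return np.stack(out).astype(float)
    else:
        featurizer = featurizer_a

    split = split_dataset(list(records_a), s_split)
    query_set = assemble_query_set(split, s_query)
    hp = MLPHyperparams(
        n_layers=cfg.n_layers,
        hidden_dim=cfg.hidden_dim,
        dropout=0.0,
        learning_rate=cfg.learning_rate,
        weight_decay=0.0,
    )
    split_b = split_dataset(list(records_b), s_split_b)
    Xb = featurizer(split_b.train)
    yb = np.array([r.label for r in split_b.train])
    target = train_model(
        Xb,
        yb,
        None,
        None,
        hp,
        TrainingConfig(
            max_epochs=cfg.target_epochs,
            batch_size=cfg.batch_size,
            early_stopping=False,
            seed=s_train,
        ),
    )
    train_acc = float(((predict_proba(target, Xb) > 0.5).astype(int) == yb).mean())

    pool = list(split.train) + list(split.population)
    ensemble = train_shadow_ensemble(
        pool,
        featurizer(pool),
        query_set.records,
        hp,
        n_shadows=cfg.n_shadows,
        epochs=cfg.shadow_epochs,
        seed=s_shadow,
        batch_size=cfg.batch_size,
    )
    X_pop = featurizer(split.population)
    y_pop = np.array([r.label for r in split.population])
    pop_acc = float(
        ((predict_proba(target, X_pop) > 0.5).astype(int) == y_pop).mean()
    )
    return Testbed(
        target_model=target,
        query_set=query_set,
        ensemble=ensemble,
        featurizer=featurizer,
        split=split,
        train_accuracy=train_acc,
        population_accuracy=pop_acc,
        memorized=train_acc >= cfg.memorization_threshold,
    )
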