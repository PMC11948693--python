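"""Orchestration of the full privacy-auditing workflow.

One *experiment* = repeated runs of: split the data 45/10/45, (optionally)
search hyperparameters, train the target classifier, train a shadow
ensemble shared by both attacks, score every query with LiRA and RMIA, and
evaluate TPR at the configured FPRs against the 2/N baseline, together with
the between-attack overlap and its hypergeometric null.  Each repetition is
a deterministic function of (config, master seed, repetition index), so
repetitions can be re-run or resumed individually.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from . import privacy_eval
from .chem_data import MoleculeRecord, load_and_clean, split_dataset
from .featurization import mol_to_graph
from .hpo import optimize_hyperparams
from .mia_attacks import (
    AttackResult,
    QuerySet,
    RMIAConfig,
    assemble_query_set,
    run_attacks,
    train_shadow_ensemble,
)
from .modeling import (
    MLPHyperparams,
    MPNNHyperparams,
    TrainingConfig,
    predict_proba,
    train_model,
)
from .privacy_eval import (
    EvaluationReport,
    OverlapStats,
    baseline_tpr,
    identified_members,
    overlap_stats,
    overlap_significance,
    significance_vs_baseline,
    tpr_at_fpr,
)
from .synthetic_fixtures import (
    generate_chemistry_free_library,
    generate_synthetic_library,
    make_fingerprint_featurizer,
)

FINGERPRINT_SCHEMES = ("ECFP4", "ECFP6", "MACCS", "RDKitFP")


@dataclass
class ExperimentConfig:
    """Declarative description of one privacy audit."""

    dataset: str | None = None  # CSV path with smiles,label
    synthetic: dict | None = None  # {n, positive_rate, noise[, mode]}
    representations: list[str] = field(default_factory=lambda: ["ECFP4"])
    attacks: list[str] = field(default_factory=lambda: ["LiRA", "RMIA"])
    repetitions: int = 20
    fpr_grid: list[float] = field(default_factory=lambda: [0.0, 1e-3])
    n_shadows: int = 10
    shadow_epochs: int = 15
    hpo_budget: int = 30
    freeze_hyperparams: bool = False  # search once, reuse across repetitions
    hyperparams: dict | None = None  # skip the search entirely
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 64
    gamma: float = 2.0
    n_z: int | None = None
    seed: int = 0
    out_dir: str | None = None  # per-repetition JSON cache for resumption

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not self.representations or not self.attacks:
            raise ValueError("need at least one representation and one attack")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def _load_records(cfg: ExperimentConfig):
    """Returns (records, chemfree_featurizer_or_None)."""
    if cfg.dataset is not None:
        return load_and_clean(cfg.dataset), None
    spec = dict(cfg.synthetic or {"n": 500})
    mode = spec.pop("mode", "chemistry")
    if mode == "chemfree":
        lib = generate_chemistry_free_library(seed=cfg.seed, **spec)
        return lib.records, lib.featurizer
    lib = generate_synthetic_library(seed=cfg.seed, **spec)
    return lib.records, None


def _make_featurizer(representation: str, chemfree_featurizer):
    if chemfree_featurizer is not None:
        return chemfree_featurizer, "mlp"
    if representation in FINGERPRINT_SCHEMES:
        return make_fingerprint_featurizer(representation), "mlp"
    if representation == "graph":
        cache: dict[str, object] = {}

        def featurize(records: Sequence[MoleculeRecord]):
            for r in records:
                if r.smiles not in cache:
                    cache[r.smiles] = mol_to_graph(r)
            return [cache[r.smiles] for r in records]

        return featurize, "mpnn"
    raise ValueError(f"unknown representation {representation!r}")


def _default_hyperparams(arch: str, overrides: dict | None):
    cls = MPNNHyperparams if arch == "mpnn" else MLPHyperparams
    return cls(**overrides) if overrides else cls()


def run_repetition(
    cfg: ExperimentConfig,
    records: Sequence[MoleculeRecord],
    chemfree_featurizer,
    representation: str,
    rep_index: int,
    frozen_hp=None,
) -> dict:
    """One repetition for one representation: split → (HPO) → train → attack."""
    featurizer, arch = _make_featurizer(representation, chemfree_featurizer)
    ss = np.random.SeedSequence([cfg.seed, rep_index])
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    s_split, s_query, s_hpo, s_train, s_shadow = seeds

    split = split_dataset(list(records), s_split)
    X_train = featurizer(split.train)
    y_train = np.array([r.label for r in split.train])
    X_val = featurizer(split.validation)
    y_val = np.array([r.label for r in split.validation])

    if frozen_hp is not None:
        hp = frozen_hp
    elif cfg.hyperparams is not None:
        hp = _default_hyperparams(arch, cfg.hyperparams)
    elif cfg.hpo_budget > 0:
        hp = optimize_hyperparams(
            X_train,
            y_train,
            X_val,
            y_val,
            budget=cfg.hpo_budget,
            seed=s_hpo,
            architecture=arch,
            batch_size=cfg.batch_size,
        ).best_params
    else:
        hp = _default_hyperparams(arch, None)

    target = train_model(
        X_train,
        y_train,
        X_val,
        y_val,
        hp,
        TrainingConfig(
            max_epochs=cfg.max_epochs,
            patience=cfg.patience,
            batch_size=cfg.batch_size,
            seed=s_train,
        ),
    )
    X_pop = featurizer(split.population)
    y_pop = np.array([r.label for r in split.population])
    auroc = float(roc_auc_score(y_pop, predict_proba(target, X_pop)))

    query_set = assemble_query_set(split, s_query)
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
    results = run_attacks(
        target,
        ensemble,
        query_set,
        featurizer,
        rmia_cfg=RMIAConfig(gamma=cfg.gamma, n_z=cfg.n_z),
        seed=s_query,
    )

    n_train = len(split.train)
    out: dict = {
        "repetition": rep_index,
        "representation": representation,
        "hyperparams": asdict(hp),
        "architecture": arch,
        "n_train": n_train,
        "n_nonmembers": int((~query_set.truth).sum()),
        "baseline_tpr": baseline_tpr(n_train),
        "model_auroc": auroc,
        "attacks": {},
    }
    identified_at_zero: dict[str, set] = {}
    for name in cfg.attacks:
        res = results[name]
        metrics = {
            f"tpr_at_fpr_{alpha:g}": tpr_at_fpr(res.scores, res.truth, alpha)
            for alpha in cfg.fpr_grid
        }
        ident = identified_members(res.scores, res.truth, res.keys, alpha=0.0)
        identified_at_zero[name] = ident
        metrics["n_identified_fpr0"] = len(ident)
        metrics["identified_fpr0"] = sorted(ident)
        out["attacks"][name] = metrics
    if {"LiRA", "RMIA"} <= set(cfg.attacks):
        a, b = identified_at_zero["LiRA"], identified_at_zero["RMIA"]
        ov = overlap_stats(a, b, n_train)
        out["overlap"] = {
            "f": ov.f,
            "intersection": ov.intersection,
            "expected_intersection": ov.expected_intersection,
            "union_size": len(a | b),
        }
    return out


def combine_attacks(
    result_a: AttackResult, result_b: AttackResult, n_training: int, alpha: float = 0.0
) -> tuple[set[str], OverlapStats]:
    """Union of identified sets at FPR ``alpha`` plus their overlap statistic."""
    if result_a.keys != result_b.keys or not np.array_equal(
        result_a.truth, result_b.truth
    ):
        raise ValueError("attack results must share the same query set")
    a = identified_members(result_a.scores, result_a.truth, result_a.keys, alpha)
    b = identified_members(result_b.scores, result_b.truth, result_b.keys, alpha)
    return a | b, overlap_stats(a, b, n_training)


def run_experiment(cfg: ExperimentConfig) -> EvaluationReport:
    """Run the configured audit and aggregate a report across repetitions."""
    records, chemfree_featurizer = _load_records(cfg)
    report = EvaluationReport()
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    per_cell: dict[tuple[str, str], list[dict]] = {}
    overlaps: dict[str, list[dict]] = {}
    for representation in cfg.representations:
        frozen_hp = None
        for rep in range(cfg.repetitions):
            cache = (
                out_dir / f"{representation}_rep{rep}.json" if out_dir else None
            )
            if cache and cache.exists():
                row = json.loads(cache.read_text())
            else:
                try:
                    row = run_repetition(
                        cfg, records, chemfree_featurizer, representation, rep,
                        frozen_hp,
                    )
                except Exception as exc:  # recorded, not fatal
                    row = {
                        "repetition": rep,
                        "representation": representation,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                if cache:
                    cache.write_text(
                        json.dumps(row, default=privacy_eval._json_default)
                    )
            if "error" in row:
                report.add_row(
                    repetition=rep,
                    representation=representation,
                    attack=None,
                    metric="error",
                    value=row["error"],
                )
                continue
            if cfg.freeze_hyperparams and frozen_hp is None:
                hp_cls = (
                    MPNNHyperparams
                    if row.get("architecture") == "mpnn"
                    else MLPHyperparams
                )
                frozen_hp = hp_cls(**row["hyperparams"])
            for attack, metrics in row["attacks"].items():
                per_cell.setdefault((representation, attack), []).append(row)
                for metric, value in metrics.items():
                    if metric == "identified_fpr0":
                        continue
                    report.add_row(
                        repetition=rep,
                        representation=representation,
                        attack=attack,
                        metric=metric,
                        value=value,
                    )
            report.add_row(
                repetition=rep,
                representation=representation,
                attack=None,
                metric="model_auroc",
                value=row["model_auroc"],
            )
            if "overlap" in row:
                overlaps.setdefault(representation, []).append(row["overlap"])
                for metric in ("f", "intersection", "expected_intersection"):
                    report.add_row(
                        repetition=rep,
                        representation=representation,
                        attack="LiRA+RMIA",
                        metric=f"overlap_{metric}",
                        value=row["overlap"][metric],
                    )

    summary: dict = {"config": {k: v for k, v in asdict(cfg).items()}}
    for (representation, attack), rows in per_cell.items():
        tprs = [r["attacks"][attack]["tpr_at_fpr_0"] for r in rows]
        baseline = rows[0]["baseline_tpr"]
        cell = {
            "median_tpr_at_fpr0": float(np.median(tprs)),
            "baseline_tpr": baseline,
        }
        if len(tprs) >= 6:
            sig = significance_vs_baseline(tprs, baseline)
            cell["p_vs_baseline"] = sig.p_value
            cell["stars"] = sig.stars
        summary[f"{representation}/{attack}"] = cell
    for representation, rows in overlaps.items():
        obs = [r["intersection"] for r in rows]
        exp = [r["expected_intersection"] for r in rows]
        fs = [r["f"] for r in rows if not np.isnan(r["f"])]
        cell = {"mean_f": float(np.mean(fs)) if fs else float("nan")}
        if len(obs) >= 6:
            sig = overlap_significance(obs, exp)
            cell["p_vs_chance"] = sig.p_value
            cell["stars"] = sig.stars
        summary[f"{representation}/overlap"] = cell
    report.summary = summary
    return report
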