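"""Evaluation statistics for membership inference attacks.

Success is measured as the true positive rate (TPR) for flagging training
molecules at a fixed, low false positive rate (FPR) — FPR 0 being the most
stringent setting, where the decision threshold sits strictly above every
nonmember score.  Under the 2:1 member:nonmember query design the analytic
random-guessing baseline at FPR 0 is 2/N for a training set of N molecules.

Also provided: Wilcoxon signed-rank comparison of repetition TPRs against
the baseline, the between-attack overlap statistic f(A,B) = |A∩B|/min(|A|,|B|)
with its hypergeometric null, and characterisation of the identified
molecules (label balance, molecular size, Tanimoto-similarity profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd
from scipy import stats
from rdkit import Chem

from .chem_data import MoleculeRecord
from .featurization import fingerprint_matrix

FPR_GRID = (0.0, 1e-3)


def _check_classes(truth: np.ndarray) -> None:
    if truth.all() or not truth.any():
        raise ValueError("need both members and nonmembers to build a ROC")


# ---------------------------------------------------------------------------
# ROC / TPR at fixed FPR
# ---------------------------------------------------------------------------

def roc_points(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve points under the strict-greater decision rule.

    A query is flagged member when its score is strictly greater than the
    threshold; thresholds run over every distinct score (plus ±∞), so tied
    scores move along the diagonal together.  Returns (fpr, tpr) arrays
    running monotonically from (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    _check_classes(truth)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1], [-np.inf]))
    member = scores[truth]
    nonmember = scores[~truth]
    fpr = np.array([(nonmember > t).mean() for t in thresholds])
    tpr = np.array([(member > t).mean() for t in thresholds])
    return fpr, tpr


def tpr_at_fpr(scores: np.ndarray, truth: np.ndarray, alpha: float) -> float:
    """TPR at the loosest threshold whose FPR does not exceed ``alpha``.

    For ``alpha=0`` this is the fraction of members scoring strictly above
    the maximum nonmember score; members tied with it are not counted.
    """
    fpr, tpr = roc_points(scores, truth)
    ok = fpr <= alpha
    return float(tpr[ok].max())


def identified_members(
    scores: np.ndarray,
    truth: np.ndarray,
    keys: Sequence[str],
    alpha: float = 0.0,
) -> set[str]:
    """Keys of member queries flagged at FPR ≤ ``alpha`` (strict-greater rule)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    _check_classes(truth)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    nonmember = scores[~truth]
    best_t = np.inf
    best_tpr = -1.0
    member = scores[truth]
    for t in thresholds:
        if (nonmember > t).mean() <= alpha:
            tpr = (member > t).mean()
            if tpr > best_tpr:
                best_tpr, best_t = tpr, t
    return {
        k for k, s, m in zip(keys, scores, truth) if m and s > best_t
    }


def baseline_tpr(n_training: int) -> float:
    """Random-guessing TPR at FPR 0 under the 2:1 query design: 2/N, capped at 1."""
    if n_training < 1:
        raise ValueError("training-set size must be positive")
    return min(2.0 / n_training, 1.0)


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

@dataclass
class SignificanceResult:
    p_value: float
    stars: str
    all_ties: bool = False

    @staticmethod
    def star_band(p: float) -> str:
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return ""


def significance_vs_baseline(
    tpr_per_repetition: Sequence[float], baseline: float
) -> SignificanceResult:
    """One-sided Wilcoxon signed-rank test of TPR − baseline > 0.

    Requires at least 6 repetitions (the signed-rank null cannot reach
    p < 0.05 below that).  When every repetition equals the baseline the
    test is degenerate: p = 1 is returned with ``all_ties`` set.
    """
    tprs = np.asarray(tpr_per_repetition, dtype=float)
    if tprs.size < 6:
        raise ValueError("need at least 6 repetitions for the signed-rank test")
    diffs = tprs - baseline
    if np.all(diffs == 0):
        return SignificanceResult(1.0, "", all_ties=True)
    res = stats.wilcoxon(diffs, alternative="greater", zero_method="wilcox")
    p = float(res.pvalue)
    return SignificanceResult(p, SignificanceResult.star_band(p))


# ---------------------------------------------------------------------------
# Attack overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapStats:
    """Overlap between the molecule sets identified by two attacks."""

    size_a: int
    size_b: int
    intersection: int
    f: float  # |A∩B| / min(|A|,|B|); NaN when a set is empty
    expected_intersection: float  # hypergeometric mean nK/N

    @property
    def defined(self) -> bool:
        return not np.isnan(self.f)


def overlap_fraction(a: set, b: set) -> float:
    """Fraction of the maximum possible overlap, |A∩B| / min(|A|, |B|).

    Undefined (NaN) when either set is empty; NaN rows are excluded from
    aggregation downstream.
    """
    if min(len(a), len(b)) == 0:
        return float("nan")
    return len(a & b) / min(len(a), len(b))


def expected_overlap(n_training: int, size_a: int, size_b: int) -> float:
    """Mean of the hypergeometric null: nK/N for independent uniform subsets."""
    if n_training <= 0:
        raise ValueError("training-set size must be positive")
    if max(size_a, size_b) > n_training:
        raise ValueError("identified sets cannot exceed the training set")
    return min(size_a, size_b) * max(size_a, size_b) / n_training


def overlap_stats(a: set, b: set, n_training: int) -> OverlapStats:
    return OverlapStats(
        size_a=len(a),
        size_b=len(b),
        intersection=len(a & b),
        f=overlap_fraction(a, b),
        expected_intersection=expected_overlap(n_training, len(a), len(b)),
    )


def overlap_significance(
    observed: Sequence[float], expected: Sequence[float]
) -> SignificanceResult:
    """Signed-rank test (one-sided) of observed − expected overlap > 0 across
    repetitions."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    diffs = obs - exp
    if np.all(diffs == 0):
        return SignificanceResult(1.0, "", all_ties=True)
    res = stats.wilcoxon(diffs, alternative="greater", zero_method="wilcox")
    p = float(res.pvalue)
    return SignificanceResult(p, SignificanceResult.star_band(p))


# ---------------------------------------------------------------------------
# Characterisation of identified molecules
# ---------------------------------------------------------------------------

def _heavy_atoms(smiles: str) -> int | None:
    mol = Chem.MolFromSmiles(smiles)
    return mol.GetNumHeavyAtoms() if mol is not None else None


def characterize_identified(
    identified: set[str],
    train: Sequence[MoleculeRecord],
    scores: np.ndarray | None = None,
    truth: np.ndarray | None = None,
    keys: Sequence[str] | None = None,
    alpha: float = 0.0,
) -> dict:
    """Label and size statistics of the identified training molecules.

    Reports the positive fraction among identified molecules with a
    Mann–Whitney test against the not-identified remainder, the minority
    class and (when attack scores are supplied) the minority-class TPR, and
    heavy-atom-count distributions with a two-sided Mann–Whitney test.
    Statistics are flagged undefined for an empty identified set.
    """
    train_keys = {r.smiles for r in train}
    if not identified <= train_keys:
        raise ValueError("identified set must be a subset of the training set")
    labels = np.array([r.label for r in train])
    id_mask = np.array([r.smiles in identified for r in train])
    out: dict = {"n_identified": int(id_mask.sum()), "n_train": len(train)}
    pos_rate = labels.mean()
    minority = 1 if pos_rate < 0.5 else 0
    out["overall_positive_fraction"] = float(pos_rate)
    out["minority_class"] = minority

    if not id_mask.any():
        out.update(
            identified_positive_fraction=float("nan"),
            label_p_value=float("nan"),
            minority_tpr=float("nan"),
            size_p_value=float("nan"),
            defined=False,
        )
        return out
    out["defined"] = True
    out["identified_positive_fraction"] = float(labels[id_mask].mean())
    if id_mask.all():
        out["label_p_value"] = float("nan")
    else:
        mw = stats.mannwhitneyu(
            labels[id_mask], labels[~id_mask], alternative="two-sided"
        )
        out["label_p_value"] = float(mw.pvalue)

    # minority-class TPR: restrict members to the minority class
    if scores is not None and truth is not None and keys is not None:
        scores = np.asarray(scores, dtype=float)
        truth = np.asarray(truth, dtype=bool)
        label_of = {r.smiles: r.label for r in train}
        keep = np.array(
            [
                (not t) or label_of.get(k) == minority
                for k, t in zip(keys, truth)
            ]
        )
        minority_members = truth & keep
        if minority_members.any():
            out["minority_tpr"] = tpr_at_fpr(scores[keep], truth[keep], alpha)
        else:
            out["minority_tpr"] = float("nan")

    sizes = np.array([_heavy_atoms(r.smiles) for r in train], dtype=float)
    valid = ~np.isnan(sizes)
    if valid.sum() and (id_mask & valid).any() and (~id_mask & valid).any():
        mw = stats.mannwhitneyu(
            sizes[id_mask & valid],
            sizes[~id_mask & valid],
            alternative="two-sided",
        )
        out["size_p_value"] = float(mw.pvalue)
        out["identified_mean_atoms"] = float(sizes[id_mask & valid].mean())
        out["other_mean_atoms"] = float(sizes[~id_mask & valid].mean())
    else:
        out["size_p_value"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# Similarity profile
# ---------------------------------------------------------------------------

@dataclass
class SimilarityProfile:
    """Per-molecule Tanimoto similarity to the rest of the training set,
    with identification fractions across ten bins."""

    nearest: np.ndarray  # max Tanimoto to any other training molecule
    mean: np.ndarray  # mean Tanimoto to all others
    nearest_bin_edges: np.ndarray  # 10 equal-width bins on [0, 1]
    nearest_bin_fraction: np.ndarray  # identified fraction per bin (NaN = empty)
    mean_bin_edges: np.ndarray  # decile (equal-count) bins
    mean_bin_fraction: np.ndarray
    nearest_p_value: float  # one-tailed MWU: identified lower
    mean_p_value: float
    degenerate: bool = False


def _bin_fractions(
    values: np.ndarray, id_mask: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    frac = np.full(len(edges) - 1, np.nan)
    for i in range(len(edges) - 1):
        hi_ok = values <= edges[i + 1] if i == len(edges) - 2 else values < edges[i + 1]
        in_bin = (values >= edges[i]) & hi_ok
        if in_bin.any():
            frac[i] = id_mask[in_bin].mean()
    return frac


def similarity_profile(
    train: Sequence[MoleculeRecord], identified: set[str]
) -> SimilarityProfile:
    """Tanimoto-similarity structure of the training set vs identification.

    Pairwise similarities use Morgan radius-2 fingerprints folded to 2048
    bits.  Self-similarity is excluded from both the nearest-neighbour
    maximum and the mean.  Nearest-neighbour values are binned into ten
    equal-width 0.1 bins; mean values into deciles.  One-tailed Mann–Whitney
    tests ask whether identified molecules sit at *lower* similarity.
    """
    if len(train) < 2:
        raise ValueError("need at least two training molecules")
    X = fingerprint_matrix(list(train), "ECFP4").astype(bool)
    inter = (X.astype(np.int32) @ X.astype(np.int32).T).astype(float)
    counts = X.sum(axis=1).astype(float)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(sim, np.nan)
    nearest = np.nanmax(sim, axis=1)
    mean = np.nanmean(sim, axis=1)

    id_mask = np.array([r.smiles in identified for r in train])
    nearest_edges = np.linspace(0.0, 1.0, 11)
    mean_edges = np.quantile(mean, np.linspace(0.0, 1.0, 11))
    degenerate = bool(np.unique(mean_edges).size < 11)

    def mwu(values: np.ndarray) -> float:
        if not id_mask.any() or id_mask.all():
            return float("nan")
        res = stats.mannwhitneyu(
            values[id_mask], values[~id_mask], alternative="less"
        )
        return float(res.pvalue)

    return SimilarityProfile(
        nearest=nearest,
        mean=mean,
        nearest_bin_edges=nearest_edges,
        nearest_bin_fraction=_bin_fractions(nearest, id_mask, nearest_edges),
        mean_bin_edges=mean_edges,
        mean_bin_fraction=_bin_fractions(mean, id_mask, mean_edges),
        nearest_p_value=mwu(nearest),
        mean_p_value=mwu(mean),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Tidy per-repetition attack metrics plus aggregate significance."""

    rows: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def add_row(self, **kwargs) -> None:
        self.rows.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {"summary": self.summary, "rows": self.rows}
        Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
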