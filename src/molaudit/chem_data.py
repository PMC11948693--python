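"""Reading, standardising, cleaning and splitting labelled molecule datasets.

The unit of membership throughout the package is a :class:`MoleculeRecord`:
one canonical SMILES string paired with a binary property label.  Raw inputs
(CSV or SDF) are standardised — sanitised for bonding/aromaticity, stripped of
salt counter-ions, neutralised and canonicalised — before duplicate and
conflict removal, so that membership questions are always asked about a
well-defined chemical entity rather than a particular SMILES spelling.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Canonical SMILES longer than this are excluded from every dataset.
MAX_SMILES_LENGTH = 200

#: Cleaned-data split fractions: training / validation / population pool.
TRAIN_FRACTION = 0.45
VALIDATION_FRACTION = 0.10


@dataclass(frozen=True)
class MoleculeRecord:
    """One canonical molecule with a binary property label."""

    smiles: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if len(self.smiles) > MAX_SMILES_LENGTH:
            raise ValueError("canonical SMILES exceeds the 200-character limit")


@dataclass(frozen=True)
class Rejection:
    """Marker for a raw structure that failed standardisation."""

    raw_smiles: str
    reason: str  # "invalid" | "too_long"


@dataclass
class DatasetSplit:
    """Disjoint train (45%) / validation (10%) / population (45%) partition."""

    train: list[MoleculeRecord]
    validation: list[MoleculeRecord]
    population: list[MoleculeRecord]
    seed: int

    def parts(self) -> tuple[list[MoleculeRecord], ...]:
        return self.train, self.validation, self.population


@dataclass
class CleaningReport:
    """Counts of records removed per reason during cleaning."""

    n_input: int = 0
    n_kept: int = 0
    n_invalid: int = 0
    n_too_long: int = 0
    n_duplicate: int = 0
    n_conflicting: int = 0
    bad_labels: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


_uncharger = rdMolStandardize.Uncharger()


def standardize_molecule(raw_smiles: str) -> str | Rejection:
    """Standardise a raw SMILES string to its canonical parent form.

    The molecule is sanitised (bonding, aromaticity, hybridisation), salts are
    stripped by keeping the largest fragment (most heavy atoms; ties broken by
    the lexicographically smallest canonical SMILES), remaining formal charges
    are neutralised where possible, and the result is canonicalised.

    Returns the canonical SMILES, or a :class:`Rejection` with reason
    ``"invalid"`` (unparsable) or ``"too_long"`` (canonical form over 200
    characters).  Idempotent: re-standardising an output returns it unchanged.
    """
    if not isinstance(raw_smiles, str) or not raw_smiles.strip():
        return Rejection(str(raw_smiles), "invalid")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        return Rejection(raw_smiles, "invalid")
    try:
        mol = rdMolStandardize.Cleanup(mol)
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
        if not frags:
            return Rejection(raw_smiles, "invalid")
        # largest fragment = most heavy atoms, tie -> smallest canonical SMILES
        mol = min(
            frags,
            key=lambda m: (-m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)),
        )
        mol = _uncharger.uncharge(mol)
        canonical = Chem.MolToSmiles(mol)
    except Exception:
        return Rejection(raw_smiles, "invalid")
    if not canonical:
        return Rejection(raw_smiles, "invalid")
    if len(canonical) > MAX_SMILES_LENGTH:
        return Rejection(raw_smiles, "too_long")
    return canonical


def clean_dataset(
    records: Iterable[tuple[str, int]],
    report: CleaningReport | None = None,
) -> list[MoleculeRecord]:
    """Standardise raw (smiles, label) pairs and remove duplicates/conflicts.

    Molecules are keyed by canonical SMILES after salt stripping.  Exact
    duplicates keep one copy; molecules observed with conflicting labels are
    removed entirely.  Output order is the input order of first occurrence.
    """
    if report is None:
        report = CleaningReport()
    seen: "OrderedDict[str, int]" = OrderedDict()
    conflicted: set[str] = set()
    for raw, label in records:
        report.n_input += 1
        try:
            label = int(label)
        except (TypeError, ValueError):
            report.bad_labels += 1
            continue
        if label not in (0, 1):
            report.bad_labels += 1
            continue
        result = standardize_molecule(raw)
        if isinstance(result, Rejection):
            if result.reason == "too_long":
                report.n_too_long += 1
            else:
                report.n_invalid += 1
            continue
        if result in seen:
            if seen[result] != label:
                conflicted.add(result)
            else:
                report.n_duplicate += 1
        else:
            seen[result] = label
    cleaned = [
        MoleculeRecord(s, lab) for s, lab in seen.items() if s not in conflicted
    ]
    report.n_conflicting = len(conflicted)
    report.n_kept = len(cleaned)
    return cleaned


def split_dataset(records: Sequence[MoleculeRecord], seed: int) -> DatasetSplit:
    """Randomly partition cleaned records 45% / 10% / 45%.

    Train and validation sizes are floored; the remainder forms the population
    pool that supplies nonmember queries and attack reference points.  The
    permutation is driven solely by ``seed``.
    """
    n = len(records)
    if n < 20:
        raise ValueError("insufficient_records: need at least 20 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(TRAIN_FRACTION * n))
    n_val = int(np.floor(VALIDATION_FRACTION * n))
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_pop = order[n_train + n_val :]
    return DatasetSplit(
        train=[records[i] for i in idx_train],
        validation=[records[i] for i in idx_val],
        population=[records[i] for i in idx_pop],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_csv(path: str | Path, smiles_col: str = "smiles", label_col: str = "label") -> list[tuple[str, int]]:
    """Read raw (smiles, label) pairs from a headed CSV."""
    df = pd.read_csv(path)
    for col in (smiles_col, label_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    return list(zip(df[smiles_col].astype(str), df[label_col]))


def read_sdf(path: str | Path, label_prop: str) -> list[tuple[str, int]]:
    """Read raw pairs from an SDF file, taking the label from a property field."""
    out: list[tuple[str, int]] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False)
    for mol in supplier:
        if mol is None or not mol.HasProp(label_prop):
            continue
        try:
            smiles = Chem.MolToSmiles(mol)
        except Exception:
            continue
        out.append((smiles, int(float(mol.GetProp(label_prop)))))
    return out


def write_csv(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"smiles": [r.smiles for r in records], "label": [r.label for r in records]}
    ).to_csv(path, index=False)


def load_and_clean(
    path: str | Path,
    smiles_col: str = "smiles",
    label_col: str = "label",
    report_path: str | Path | None = None,
) -> list[MoleculeRecord]:
    """Read a CSV, clean it, and optionally write the cleaning report JSON."""
    report = CleaningReport()
    cleaned = clean_dataset(read_csv(path, smiles_col, label_col), report)
    if report_path is not None:
        report.to_json(report_path)
    return cleaned
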