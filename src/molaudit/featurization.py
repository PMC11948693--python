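"""Molecular representations: fingerprints, graphs and SMILES token sequences.

Four bit-vector schemes are supported — ECFP4 (Morgan radius 2), ECFP6
(Morgan radius 3), MACCS structural keys and the RDKit path fingerprint
(subgraphs up to 7 bonds) — alongside an attributed molecular graph for
message-passing networks and a regex SMILES tokenizer.  Every representation
is a deterministic function of the canonical molecule.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .chem_data import MoleculeRecord

SCHEMES = ("ECFP4", "ECFP6", "MACCS", "RDKitFP")

#: Bit-vector length per scheme.  MACCS defines 166 structural patterns
#: (RDKit's key 0 is a placeholder and is dropped).
SCHEME_LENGTHS = {"ECFP4": 2048, "ECFP6": 2048, "MACCS": 166, "RDKitFP": 2048}

_GENERATORS = {
    "ECFP4": rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048),
    "ECFP6": rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048),
    "RDKitFP": rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=7, fpSize=2048),
}


def _mol(record: MoleculeRecord | str) -> Chem.Mol:
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"not a valid molecule: {smiles!r}")
    return mol


def fingerprint(record: MoleculeRecord | str, scheme: str) -> np.ndarray:
    """Binary fingerprint of ``record`` under ``scheme`` (uint8 0/1 vector)."""
    if scheme not in SCHEMES:
        raise ValueError(f"unsupported scheme {scheme!r}; choose from {SCHEMES}")
    mol = _mol(record)
    if scheme == "MACCS":
        bv = MACCSkeys.GenMACCSKeys(mol)
        arr = np.zeros(167, dtype=np.uint8)
        for bit in bv.GetOnBits():
            arr[bit] = 1
        return arr[1:]  # drop the unused key 0
    bv = _GENERATORS[scheme].GetFingerprint(mol)
    arr = np.zeros(SCHEME_LENGTHS[scheme], dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_matrix(records: Sequence[MoleculeRecord], scheme: str) -> np.ndarray:
    """Stack fingerprints into an (n_records, length) float32 matrix."""
    if len(records) == 0:
        return np.zeros((0, SCHEME_LENGTHS[scheme]), dtype=np.float32)
    return np.stack([fingerprint(r, scheme) for r in records]).astype(np.float32)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| of two binary fingerprints."""
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


# ---------------------------------------------------------------------------
# Molecular graphs
# ---------------------------------------------------------------------------

_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B")
_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
)
_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)

#: Version tag for the graph feature layout below; bump on any change.
GRAPH_FEATURE_VERSION = 1

ATOM_FEATURE_DIM = len(_ELEMENTS) + 1 + 6 + 1 + 1 + len(_HYBRIDIZATIONS) + 1
BOND_FEATURE_DIM = len(_BOND_TYPES) + 1


@dataclass
class MolGraph:
    """Attributed molecular graph (heavy atoms as nodes, bonds as edges).

    Atom features: element one-hot over {C,N,O,S,F,Cl,Br,I,P,B} + other slot;
    degree one-hot (0–5); formal charge; aromatic flag; hybridisation one-hot
    over {SP, SP2, SP3} + other slot.  Bond features: bond-type one-hot over
    {single, double, triple, aromatic} + in-ring flag.  ``edges`` lists each
    bond in both directions.
    """

    atom_features: np.ndarray  # (n_atoms, ATOM_FEATURE_DIM)
    bond_features: np.ndarray  # (n_directed_edges, BOND_FEATURE_DIM)
    edges: np.ndarray  # (n_directed_edges, 2) int32 [src, dst]

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.edges.shape[0] // 2


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    f = np.zeros(ATOM_FEATURE_DIM, dtype=np.float32)
    sym = atom.GetSymbol()
    f[_ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)] = 1.0
    off = len(_ELEMENTS) + 1
    f[off + min(atom.GetDegree(), 5)] = 1.0
    off += 6
    f[off] = float(atom.GetFormalCharge())
    f[off + 1] = float(atom.GetIsAromatic())
    off += 2
    hyb = atom.GetHybridization()
    f[off + (_HYBRIDIZATIONS.index(hyb) if hyb in _HYBRIDIZATIONS else len(_HYBRIDIZATIONS))] = 1.0
    return f


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    f = np.zeros(BOND_FEATURE_DIM, dtype=np.float32)
    bt = bond.GetBondType()
    if bt in _BOND_TYPES:
        f[_BOND_TYPES.index(bt)] = 1.0
    f[len(_BOND_TYPES)] = float(bond.IsInRing())
    return f


def mol_to_graph(record: MoleculeRecord | str) -> MolGraph:
    """Convert a molecule to its attributed graph (one node per heavy atom)."""
    mol = _mol(record)
    if mol.GetNumAtoms() == 0:
        raise ValueError("molecule has no heavy atoms")
    atoms = np.stack([_atom_features(a) for a in mol.GetAtoms()])
    edges = []
    bonds = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = _bond_features(bond)
        edges.append((i, j))
        bonds.append(bf)
        edges.append((j, i))
        bonds.append(bf)
    edge_arr = (
        np.asarray(edges, dtype=np.int32)
        if edges
        else np.zeros((0, 2), dtype=np.int32)
    )
    bond_arr = (
        np.stack(bonds).astype(np.float32)
        if bonds
        else np.zeros((0, BOND_FEATURE_DIM), dtype=np.float32)
    )
    return MolGraph(atom_features=atoms, bond_features=bond_arr, edges=edge_arr)


# ---------------------------------------------------------------------------
# SMILES tokenization
# ---------------------------------------------------------------------------

#: Context length of the token representation (200 SMILES tokens + BOS/EOS).
MAX_TOKENS = 202

_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOPSFIbcnops]|[=#$:/\\().+\-@]|\d)"
)

BOS, EOS = "<bos>", "<eos>"


def split_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into chemically meaningful tokens.

    Multi-character atom symbols (Cl, Br, bracket atoms) and two-digit ring
    closures (%nn) are single tokens.  Raises if any character cannot be
    consumed, naming the offending symbol.
    """
    tokens = _SMILES_TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        consumed = 0
        for tok in tokens:
            if smiles[consumed : consumed + len(tok)] != tok:
                break
            consumed += len(tok)
        raise ValueError(f"untokenizable symbol {smiles[consumed]!r} in {smiles!r}")
    return tokens


@dataclass
class SmilesVocabulary:
    """Token → integer mapping built from a corpus plus special tokens."""

    token_to_id: dict[str, int]

    @classmethod
    def from_corpus(cls, smiles_list: Iterable[str]) -> "SmilesVocabulary":
        tokens = sorted({t for s in smiles_list for t in split_smiles(s)})
        mapping = {BOS: 0, EOS: 1}
        for t in tokens:
            mapping[t] = len(mapping)
        return cls(mapping)

    @property
    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}

    def __len__(self) -> int:
        return len(self.token_to_id)


@dataclass
class TokenSequence:
    """Integer token sequence (BOS ... EOS) over a fixed SMILES vocabulary."""

    tokens: np.ndarray  # int32, length ≤ MAX_TOKENS
    vocab: SmilesVocabulary

    def to_smiles(self) -> str:
        inv = self.vocab.id_to_token
        return "".join(
            inv[int(i)] for i in self.tokens if inv[int(i)] not in (BOS, EOS)
        )


def tokenize_smiles(
    record: MoleculeRecord | str, vocab: SmilesVocabulary
) -> TokenSequence:
    """Encode a canonical SMILES as a BOS/EOS-delimited integer sequence."""
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    parts = split_smiles(smiles)
    unknown = [t for t in parts if t not in vocab.token_to_id]
    if unknown:
        raise ValueError(f"tokens not in vocabulary: {sorted(set(unknown))}")
    ids = [vocab.token_to_id[BOS]] + [vocab.token_to_id[t] for t in parts]
    ids.append(vocab.token_to_id[EOS])
    if len(ids) > MAX_TOKENS:
        raise ValueError(
            f"sequence of {len(ids)} tokens exceeds the {MAX_TOKENS}-token limit"
        )
    return TokenSequence(np.asarray(ids, dtype=np.int32), vocab)


# ---------------------------------------------------------------------------
# Feature matrix I/O
# ---------------------------------------------------------------------------

def save_features(matrix: np.ndarray, scheme: str, path: str | Path) -> None:
    """Write a feature matrix as .npz with a JSON sidecar naming the scheme."""
    path = Path(path)
    np.savez_compressed(path, features=matrix)
    sidecar = {"scheme": scheme, "length": int(matrix.shape[1]), "n": int(matrix.shape[0])}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_features(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    matrix = np.load(path.with_suffix(".npz"))["features"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return matrix, meta
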