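"""Convert molecules to the representations the attacks are compared on.

Shows the four fingerprint schemes, the attributed molecular graph used by
the message-passing network, and the SMILES tokenizer.
"""

from molaudit import (
    SmilesVocabulary,
    fingerprint,
    mol_to_graph,
    tanimoto,
    tokenize_smiles,
)

smiles = "CC(=O)Nc1ccc(O)cc1"  # paracetamol
for scheme in ("ECFP4", "ECFP6", "MACCS", "RDKitFP"):
    fp = fingerprint(smiles, scheme)
    print(f"{scheme:8s} length={len(fp):4d}  bits set={int(fp.sum())}")

aspirin = fingerprint("CC(=O)Oc1ccccc1C(=O)O", "ECFP4")
para = fingerprint(smiles, "ECFP4")
print(f"Tanimoto(paracetamol, aspirin) on ECFP4 = {tanimoto(para, aspirin):.3f} "
      "(1.0 would mean identical fingerprints)")

g = mol_to_graph(smiles)
print(f"graph: {g.n_atoms} heavy atoms, {g.n_bonds} bonds, "
      f"atom feature dim {g.atom_features.shape[1]}")

vocab = SmilesVocabulary.from_corpus([smiles, "CCl", "c1ccccc1Br"])
seq = tokenize_smiles("CCl", vocab)
print(f"'CCl' tokenizes to {len(seq.tokens)} tokens (Cl is one token), "
      f"round-trips to {seq.to_smiles()!r}")
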