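"""Generate a synthetic screening library and run it through data cleaning.

Builds 200 unique molecules with a planted sulfonamide activity rule, then
shows how the cleaning pipeline treats alternative SMILES spellings, salts,
duplicates and label conflicts, and finally splits the cleaned data
45/10/45 into training / validation / population subsets.
"""

from molaudit import clean_dataset, generate_synthetic_library, split_dataset
from molaudit.chem_data import CleaningReport

lib = generate_synthetic_library(n=200, positive_rate=0.25, noise=0.05, seed=7)
print(f"library: {len(lib.records)} molecules, "
      f"positive rate {lib.empirical_positive_rate:.3f} (target 0.25)")

# a messy raw table: spellings, a salt, a conflict, and garbage
raw = [
    ("CCO", 1), ("OCC", 1),                 # same molecule twice -> kept once
    ("CC(=O)[O-].[Na+]", 0), ("CC(=O)O", 0),  # salt == parent acid -> one copy
    ("CCN", 1), ("NCC", 0),                 # conflicting labels -> dropped
    ("C(", 1),                               # unparsable -> rejected
]
report = CleaningReport()
cleaned = clean_dataset(raw, report)
print(f"cleaning kept {report.n_kept} of {report.n_input} rows "
      f"(invalid={report.n_invalid}, duplicates={report.n_duplicate}, "
      f"conflicts={report.n_conflicting})")

split = split_dataset(lib.records, seed=1)
print(f"split sizes: train={len(split.train)} (45%), "
      f"validation={len(split.validation)} (10%), "
      f"population={len(split.population)} (45%)")
print("the population subset supplies nonmember queries and attack reference points")
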