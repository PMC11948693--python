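# Methods

This note records the models, procedures, defaults and numerical choices
behind `molaudit`, and what the synthetic testbeds do and do not show.

## The privacy game

The audit follows the standard membership-inference game: a training set D
is sampled from a chemical space Π, a model f is trained on D, and an
adversary holding black-box access to f (output logits only) plus data from
the same space must decide, per molecule, whether it was in D.  The package
realises the game end to end: data cleaning and splitting, model training,
shadow-model calibration, attack scoring, and evaluation at low false
positive rates.

## Data handling

Raw SMILES are sanitised (bonding, aromaticity, hybridisation), salts are
stripped by keeping the largest fragment — most heavy atoms, ties broken by
the lexicographically smallest canonical SMILES — residual charges are
neutralised, and the result is canonicalised with RDKit.  Canonical forms
longer than 200 characters are excluded.  Duplicates are detected *after*
standardisation on the canonical SMILES key; molecules observed with
conflicting labels are removed entirely.  Counts on real datasets may
differ slightly from pipelines that deduplicate before salt stripping.
Cleaned data are split 45% training / 10% validation / 45% population;
train and validation sizes are floored and the remainder goes to the
population pool.  Tests never assert dialect-specific canonical strings,
only equalities, so the canonicalisation dialect is whatever the installed
RDKit produces.

## Representations

ECFP4/ECFP6 are Morgan fingerprints of radius 2/3 folded to 2048 binary
bits; RDKitFP enumerates subgraphs up to 7 bonds into 2048 bits; MACCS
uses the 166 structural keys (RDKit's placeholder key 0 is dropped).
Fingerprints are binary, not count-based.  The molecular graph uses one
node per heavy atom with element one-hot (C,N,O,S,F,Cl,Br,I,P,B + other),
degree one-hot (0–5), formal charge, aromaticity flag and hybridisation
one-hot (SP/SP2/SP3 + other); bonds carry a type one-hot
(single/double/triple/aromatic) and an in-ring flag.  This layout is
versioned (`GRAPH_FEATURE_VERSION`).  A regex SMILES tokenizer with a
corpus-built vocabulary (202-token context, BOS/EOS) is provided; no
classifier consumes tokens — the pre-trained sequence encoder that would
sit on top is outside the package's scope, and the fingerprint/graph pair
already spans the bitstring-vs-structure representation axis the attacks
are compared on.

## Classifiers and training

Both architectures are implemented directly on NumPy (forward and backward
passes, verified against central finite differences to ~1e-9), which keeps
training bit-reproducible from a seed across machines:

* **MLP** over fingerprints: 1–3 ReLU hidden layers, inverted dropout, one
  output logit.
* **MPNN** over graphs: a linear atom encoder (optional bias), T rounds of
  shared-weight message passing where each atom aggregates neighbour
  states plus linearly encoded bond features through a ReLU update, a mean
  or sum readout, and an MLP head (dropout in the head only).

Training minimises class-weighted binary cross-entropy — weights inversely
proportional to class frequency, normalised so the mean sample weight is
one — with AdamW (decoupled weight decay, β = 0.9/0.999) in mini-batches
of 64.  Target models use early stopping with patience 10 and return the
parameter snapshot of the epoch with the lowest validation loss; shadow
models train for exactly 15 epochs with no early stopping.  Non-finite
losses abort with diagnostics rather than propagate.

Hyperparameters are searched with a tree-structured Parzen estimator over
dropout 0–0.5, 1–3 hidden layers, widths 64–1024 (log), learning rate
1e-4–1e-2 (log) and weight decay 1e-6–1e-2 (log); the graph model adds
message steps 1–4, encoder width 64–512 (log), encoder bias and
aggregation (mean/sum).  After a 10-trial random start-up the sampler
splits past trials at the best quartile, fits per-dimension Gaussian
mixtures (bandwidth (hi−lo)/√(k+1) with a 1% floor, plus a uniform prior
component) and maximises the density ratio over 24 candidates.  Trials are
capped at 20 epochs and pruned after two consecutive non-improving epochs
or when worse than the across-trial median at the 15-epoch checkpoint;
pruning on *worse* than the median is the only reading under which the
checkpoint rule is useful.  The budget is a trial count (default 30)
rather than wall-clock time, so searches are reproducible.

## Attacks

**Query design.**  All N training molecules enter as members and ⌈N/2⌉
population molecules as nonmembers — a deterministic 2:1 assembly rather
than Bernoulli(0.67) sampling, which removes baseline variance while
keeping the member fraction at 2/3.  The population molecules not used as
nonmember queries form RMIA's reference pool Z (disjoint from the training
set by construction); by default all of them are used, with a configurable
cap for large datasets.

**Shadow pool.**  Shadows must contain every query molecule IN some
models and OUT of others, including nonmembers; the pool is therefore the
union of the training set and the population subset, and each of the
(default 10, testbed 8) shadows trains on an independent 50% subset with
the target's hyperparameters.  Subsets are redrawn, then minimally
flipped, until every query has at least one IN and one OUT shadow.  One
ensemble serves both attacks.

**LiRA** fits per-query Gaussians (population variance, floored at 1e-4)
to the IN and OUT shadow confidences and scores the target's confidence by
the log density ratio — the online variant, since IN and OUT models are
both available.  Rescaled confidences log(p/(1−p)) are computed directly
from the raw output logit (for a one-logit binary model the two are
identical), which avoids the precision collapse of clamping saturated
sigmoid probabilities; the probability-input path clamps at ε = 1e-6.

**RMIA** approximates P(x|f) by the correct-class probability and P(x) by
its mean over all shadows (floored at 1e-8), and scores a query by the
fraction of reference points it dominates by γ = 2.  The dominance
comparison carries a 1e-12 relative tolerance so exact boundary ratios are
not lost to floating-point rounding.

## Evaluation

A query is flagged member when its score is *strictly greater* than the
threshold; "FPR 0" therefore means members scoring above every nonmember,
with ties excluded — the conservative reading.  TPR at FPR α takes the
loosest threshold whose FPR does not exceed α.  The random-guessing
baseline at FPR 0 under the 2:1 design is 2/N (the exact order-statistics
expectation is m/(n+1) = N/(N/2+1) identified members, i.e. just under 2);
the package verifies this against a uniform-score adversary by
simulation.  Attack-vs-baseline significance uses one-sided Wilcoxon
signed-rank tests over repetitions (all-tie inputs are flagged and
reported as p = 1); overlap significance likewise (one-sided, observed
minus the hypergeometric mean nK/N).  Directional hypotheses (higher TPR,
lower similarity) use one-sided tests; the molecular-size comparison is
two-sided.  Raw p-values are reported without multiple-testing correction,
mirroring star-band reporting practice; a Benjamini–Hochberg flag can be
layered on by callers.  Similarity profiles use Morgan radius-2/2048-bit
fingerprints with self-similarity excluded from both the
nearest-neighbour and mean Tanimoto; nearest-neighbour values are binned
into ten equal-width 0.1 bins and mean values into deciles (degenerate
quantile edges are flagged).

## Synthetic libraries and testbeds

The generator assembles molecules from a fragment grammar — two or three
ring systems (benzene, pyridine, pyrazine, thiophene, furan, pyrrole and
saturated counterparts) joined by short linkers with terminal decorations
— and plants a learnable rule: label 1 iff a primary-sulfonamide
pharmacophore is attached, then flipped with probability `noise`.  The
attachment probability is corrected so the *post-noise* positive rate hits
the target, which also bounds admissible noise by the class imbalance.
Duplicates are regenerated until n unique canonical SMILES exist.  Grammar
assembly guarantees chemical validity and determinism without a
chemistry-aware sampler.  Defaults (positive rate 0.25, noise 0.05) give a
mildly imbalanced, mostly-learnable task whose label-noise molecules are
memorisable — the regime in which membership leakage is observable at
desk scale.  A chemistry-free mode (random 0/1 vectors, noisy linear rule)
decouples attack correctness from the chemistry toolkit for fast unit
tests.

The *memorisation testbed* trains an ECFP4 MLP with dropout and weight
decay at zero for a fixed 40 epochs on a 225-molecule training split
(n = 500 library), which reliably reaches 100% training accuracy with a
~5–10 point generalisation gap; the `memorized` flag records whether the
99% threshold was met.  The *null testbed* trains the target on a second,
disjoint library so that no query was ever seen — both attacks must then
score at chance (ROC area ≈ 0.5), a closed-loop check that no membership
information leaks through bookkeeping.

What these testbeds do **not** show: synthetic libraries are far less
diverse than real screening collections, have no activity cliffs, assay
noise structure or scaffold clustering, and the planted rule is much
simpler than real structure–activity landscapes.  Passing the testbed
demonstrates the correctness and calibration of the attack and evaluation
machinery, not the leakage level of any particular real model; on real
data, leakage depends on dataset size, imbalance and regularisation.

## Problem sizes and runtime defaults

The bundled experiments are sized for a single CPU: libraries of 200–500
molecules, 3–10 shadow models, 20 repetitions for the significance tests,
2000 replicates for the baseline simulations and 10⁴ draws for the
hypergeometric check.  All statistical checks use 3-standard-error bands
around their analytic expectations.  Larger audits scale through
`ExperimentConfig` (repetitions, shadows, HPO budget, reference-point cap
`n_z`).

## Known limitations

* Binary classification only; regression targets and multi-task heads are
  out of scope.
* No white-box attacks, query augmentation, or scaffold-level inference.
* The token representation has no trained classifier (see above).
* The adversary is assumed to hold data from the same distribution as the
  training set; distribution shift between attacker and target data — the
  common real-world complication — is not modelled.
* Shadow ensembles with few models give coarse per-query Gaussian fits in
  LiRA; the variance floor prevents degeneracy but very small ensembles
  (< 4 shadows) make FPR-0 estimates noisy.
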