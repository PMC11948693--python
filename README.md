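# molaudit

**Membership-inference privacy auditing for molecular property prediction
models.**

Organisations in drug discovery train neural networks on proprietary
compound collections and then share the models — as weights or as
prediction services.  Even in a black-box setting, where only output
logits are visible, an adversary can often tell whether a *specific
molecule* was in the training set.  Since the presence of a compound in a
training set signals active research interest, this is a concrete
intellectual-property leak.  `molaudit` lets modellers quantify that risk
before publishing: it trains QSAR-style binary classifiers under several
molecular representations (ECFP4/ECFP6, MACCS keys, RDKit path
fingerprints, molecular graphs) and attacks them with the two
state-of-the-art black-box membership inference attacks, reporting how
many training molecules each attack recovers.

## The attacks and the statistic

Both attacks calibrate on *shadow models*: models with the target's
hyperparameters trained on random 50% subsets of a pool drawn from the
same chemical space, with known per-molecule IN/OUT membership.

**LiRA** (likelihood-ratio attack).  For a query molecule *m* with
rescaled confidence c = log(p/(1−p)) of the correct class, fit
Normal(μ_in, σ_in²) to the confidences of shadows that trained on *m* and
Normal(μ_out, σ_out²) to those that did not; the score is the log density
ratio log N(c*; μ_in, σ_in) − log N(c*; μ_out, σ_out) at the target
model's confidence c*.

**RMIA** (robust membership inference attack).  With
ratio(x) = P(x | f_target) / P̄(x), where P̄ is the mean correct-class
probability over all shadows, the score of *m* is

    Score(m) = P_{z∼Π} ( ratio(m) / ratio(z) ≥ γ ),   γ = 2,

the fraction of random reference molecules z from the population that *m*
dominates by a factor γ.

**Evaluation.**  Success is the true positive rate at a fixed low false
positive rate.  At FPR 0 (the decision threshold strictly above every
nonmember score) the random-guessing baseline under the 2:1
member:nonmember query design is **2/N** for a training set of N
molecules.  Attacks are compared to this baseline with one-sided Wilcoxon
signed-rank tests over repetitions; the identified molecules from two
attacks are compared with the overlap statistic
f(A,B) = |A∩B| / min(|A|,|B|) against its hypergeometric chance level
nK/N, and characterised by label balance, molecular size and Tanimoto
similarity to the rest of the training set.

## Worked example

`examples/04_attack_a_model.py` builds a deliberately overfit ECFP4 MLP on
500 synthetic molecules and attacks it with both methods from one shared
shadow ensemble:

```
target model: training accuracy 1.000, population accuracy 0.933 -> generalisation gap 0.067
query set: 225 members + 113 nonmembers (member fraction 0.67)
random-guessing baseline TPR at FPR 0: 2/N = 0.0089 (2 molecules)
LiRA: TPR@FPR0 = 0.0356 -> identified 8 of 225 training molecules (above baseline)
RMIA: TPR@FPR0 = 0.0356 -> identified 8 of 225 training molecules (above baseline)
```

Both attacks recover four times more training molecules than chance at the
most stringent operating point — the model leaks.  The other examples walk
through data cleaning and splitting (45/10/45), featurization, training
with the TPE search, combining attacks and characterising the identified
molecules, and the analytic baseline calibration.

A full audit (repeated split → hyperparameter search → target training →
shared shadow ensemble → both attacks → report) is driven by
`ExperimentConfig`/`run_experiment`, or from the shell:

```bash
audit synth --n 1000 --positive-rate 0.25 --seed 7 --out lib.csv
audit run --config audit.yaml --out report.json
```

where `audit.yaml` sets the dataset (CSV with `smiles,label` columns, or a
synthetic spec), representations, attacks, repetitions and seeds.

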