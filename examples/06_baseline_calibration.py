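"""Verify the analytic random-guessing baselines by simulation.

A uniform-score adversary facing m members and n nonmembers flags on
average m·r/(n+1) members when the threshold sits at the r-th highest
nonmember score.  With the 2:1 design (m = N training molecules,
n = N/2) and r = 1 (FPR 0) this is the 2/N baseline; with equal member
and nonmember counts and r = 10 (FPR ≈ 1.1e-2) the expectation is ten.
"""

from molaudit import baseline_tpr
from molaudit.synthetic_fixtures import (
    expected_identified_random,
    mean_identified_random,
)

m, n = 859, 430
mean, se = mean_identified_random(m, n, rank=1, n_replicates=2000, seed=0)
print(f"FPR 0, {m} members vs {n} nonmembers:")
print(f"  simulated mean identified = {mean:.3f} ± {se:.3f}")
print(f"  closed form m/(n+1)       = {expected_identified_random(m, n):.3f}")
print(f"  2/N baseline rate x N     = {baseline_tpr(m) * m:.3f} molecules")

mean10, se10 = mean_identified_random(859, 859, rank=10, n_replicates=2000, seed=1)
print(f"threshold at 10th-highest of 859 nonmember scores (FPR ~ 1.1e-2):")
print(f"  simulated mean identified = {mean10:.3f} ± {se10:.3f} (expected ~10)")
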