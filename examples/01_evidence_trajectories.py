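"""Generate a few cumulative two-group trials and watch the evidence grow.

Each trial shows pink (control) and blue (experimental) samples doubling
from 10 to 320 points per group.  At every array size we print the observed
Cohen's d and the log likelihood ratio (LLR) of a true d=0.3 effect versus
null; the optimal array index is the first one where |LLR| reaches ln(40)
(odds of 40:1), which is where a correct response earns the bonus.
"""

import numpy as np

import beeswarmsim as bs

rng = np.random.default_rng(1)
trials = bs.generate_stimulus_set(4, prop_true=0.5, rng=rng)

for trial in trials:
    traj = bs.EvidenceTrajectory.from_trial(trial)
    opt = bs.optimal_array_index(traj)
    label = "TRUE EFFECT" if trial.truth else "NULL"
    print(f"\ntrial {trial.trial_id} ({label}), optimal array index = {opt}")
    print(f"  {'n/group':>8} {'observed d':>11} {'LLR':>8}")
    for k in range(6):
        marker = " <- optimal" if k + 1 == opt else ""
        print(f"  {traj.n[k]:>8} {traj.observed_d[k]:>11.3f} {traj.llr[k]:>8.2f}{marker}")

print(
    "\nObserved d is noisy at small arrays and settles near its population"
    "\nvalue (0.3 or 0) as n grows; the LLR drifts towards +inf on true"
    "\ntrials and -inf on null trials, crossing the 40:1 line (|LLR|=3.69)"
    "\nat the trial's optimal array."
)
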