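"""Simulate one player's full 80-trial session and summarise each block.

A learner plays naively (early responses driven by the sign of the
evidence, 30% response error) in blocks 1-3, then adopts the
threshold-waiting strategy (10% error) in block 4.  The block summaries
show the analysis variables: earnings (+4/-4 with a +2 bonus at the
optimal array), percent correct, mean array index, mean |LLR| at response
and the signal-detection indices d' and beta.
"""

import numpy as np

import beeswarmsim as bs

rng = np.random.default_rng(3)
stimuli = bs.generate_stimulus_set(80, prop_true=0.5, rng=rng)

blocks = bs.simulate_participant_session(stimuli, learner=True, rng=rng)

print(f"{'block':>5} {'earnings':>9} {'% correct':>10} {'mean index':>11} "
      f"{'mean |LLR|':>11} {'d-prime':>8} {'beta':>6}")
for b in blocks:
    print(
        f"{b.block:>5} {b.earnings:>9} {b.percent_correct:>10.1f} "
        f"{b.mean_array_index:>11.2f} {b.mean_abs_llr:>11.2f} "
        f"{b.d_prime:>8.2f} {b.beta:>6.2f}"
    )

total = sum(b.earnings for b in blocks)
print(f"\ntotal points: {total} -> payment {bs.earnings_to_payment(total)}p")
print(
    "Block 4 shows the learner jump: accuracy, d' and earnings rise because"
    "\nthe player waits for 40:1 evidence (and banks the bonus) instead of"
    "\nguessing from the evidence sign at a haphazard array."
)
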