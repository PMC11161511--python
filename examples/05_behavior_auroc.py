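"""Group comparison of differential anticipatory licking by auROC.

Simulates a control group of sessions that learned the cue-outcome
contingencies (strong Cue 1 vs Cue 2 lick-rate difference) and a group
whose learning was disrupted (no differential licking), then computes the
auROC time-course at 10 ms steps with a 200-resample permutation test and
reports the significant span.
"""
import numpy as np

from bfphys.behavior import auroc_timecourse, session_lick_difference, significant_spans
from bfphys.synthetic import SessionConfig, generate_session

control, disrupted = [], []
for s in range(8):
    trials, licks = generate_session(SessionConfig(n_trials=60, learning=6.0, seed=s))
    control.append(session_lick_difference(licks, trials))
    trials, licks = generate_session(SessionConfig(n_trials=60, learning=0.0, seed=50 + s))
    disrupted.append(session_lick_difference(licks, trials))

tc = auroc_timecourse(np.array(control), np.array(disrupted), n_resamples=200, seed=0)
late = tc.bin_centers >= 0.6
print(f"auROC (0.6-1.1 s window): mean {tc.auroc[late].mean():.2f}")
print(f"permutation p floor: {tc.p_floor:.4f}")
for lo, hi in significant_spans(tc, alpha=0.05):
    print(f"significant span: {lo:.2f}-{hi:.2f} s from cue onset")
print("-> groups separate where anticipatory licking diverges, before reinforcement")
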