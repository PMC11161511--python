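"""Isosbestic-corrected dF/F and event-aligned averaging.

Simulates a two-channel bulk-calcium recording with shared motion artifact,
bleaching and a punishment response; runs the full chain (20 Hz low-pass,
isosbestic fit, dF/F, 0.2 Hz high-pass) and reports the z-scored
punishment-aligned response.
"""
import numpy as np

from bfphys.photometry import align_average, process
from bfphys.synthetic import (
    PhotometryConfig,
    ResponseProfile,
    SessionConfig,
    event_times,
    generate_photometry,
    generate_session,
)

trials, _ = generate_session(SessionConfig(n_trials=80, p_cue1=0.0, seed=7))
rec = generate_photometry(
    trials, ResponseProfile(gains={"punishment": 2.0}), PhotometryConfig(seed=5)
)
trace = process(rec)
print(f"isosbestic fit: slope {trace.fit_slope:.3f}, intercept {trace.fit_intercept:.3f}")

ev = event_times(trials, "punishment")
cues = trials.loc[trials["outcome"] == "punishment", "cue_onset"].to_numpy()
out = align_average(trace, ev, baseline_events=cues)
post = (out.peth.bin_centers >= 0) & (out.peth.bin_centers <= 1)
print(
    f"{out.peth.n_events} punishment trials ({out.n_dropped} dropped at edges); "
    f"peak z = {out.peth.rate[post].max():.1f}, "
    f"peak dF/F = {out.trials.mean(axis=0).max():.2f} %"
)
print("-> the shared artifact cancels in the fit; the calcium transient survives")
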