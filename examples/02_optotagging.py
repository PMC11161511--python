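"""Optogenetic tagging with the stimulus-associated latency test.

Simulates the tagging protocol (25 blocks of 1 ms pulses at 20 Hz for 2 s,
3 s pauses) for a light-driven unit and for an unrelated Poisson unit, then
runs SALT on both. The driven unit shows a large Jensen-Shannon divergence
between post-pulse and baseline latency histograms and p < 0.01; the
Poisson unit does not.
"""
from bfphys.synthetic import generate_tagging_epoch
from bfphys.tagging import salt, tag_decision

for label, tagged in (("ChR2-expressing unit", True), ("untagged unit", False)):
    ep = generate_tagging_epoch(
        tagged, latency=0.003, jitter=0.0005, reliability=0.9, seed=42
    )
    r = salt(ep.spikes, ep.pulse_times, ep.baseline_epochs, seed=42)
    d = tag_decision(r)
    print(
        f"{label}: p = {r.p_salt:.4f}, divergence = {r.divergence:.3f} bits, "
        f"latency = {r.median_latency:.2f} ms (jitter {r.latency_jitter:.2f} ms), "
        f"tagged = {d.tagged}"
    )
print("-> p < 0.01 identifies the light-activated unit; latency ~3 ms is recovered")
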