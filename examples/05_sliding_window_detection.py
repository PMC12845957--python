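"""Real-time-style detection: slide the 6 s window over a longer recording.

Trains a quick model, then applies it to a fresh 30 s synthetic recording
with the 6 s / 3 s sliding window — a new humpback probability every three
seconds, the refresh pattern a deployed monitor would use.
"""

from whalesong import SynthParams, run_experiment, sliding_window_predict, synth_call_source

params = SynthParams(n_call_sources=8, n_nocall_sources=8, duration_range_s=(4.0, 30.0), seed=6)
result = run_experiment(synth_params=params, augment=False, seed=6)
model = result["model"]

recording = synth_call_source(30.0, SynthParams(), seed=99, source_id="hydrophone")
windows = sliding_window_predict(model, recording)

print(f"{'start (s)':>10s} {'p(humpback)':>12s}")
for w in windows:
    bar = "#" * int(round(20 * w["p_humpback"]))
    print(f"{w['start_s']:>10.0f} {w['p_humpback']:>12.3f}  {bar}")
# Overlapping windows give each call at least two chances to be seen whole,
# halving the odds that a call straddling a boundary is missed.
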