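"""Replay the stressor game's biofeedback engine over a simulated session.

A virtual participant's heart rate drifts upward mid-session; the engine
tracks the rolling 30-beat BPM, maps it onto the sigmoid stress score and
drives the green/amber/red display, with five prespecified death points.
"""

import numpy as np

from biofeedbacklab import (
    BeatSeries,
    BiofeedbackParams,
    boat_speed,
    run_session,
    stress_score,
)

params = BiofeedbackParams(ref_bpm=70.0, range_bpm=25.0)

# the printed anchors of the score: 0.5 at the training HR, 0.9/0.1 one Range away
for bpm in (70.0, 95.0, 45.0):
    c, score = stress_score(bpm, params)
    print(f"BPM {bpm:5.1f} -> C = {c:+.4f}, stress score = {score:.3f}")

# a session whose HR climbs from 70 to 90 bpm between 150 s and 350 s
rng = np.random.default_rng(7)
ibis = []
t = 0.0
while t < 600.0:
    hr = 70.0 + 20.0 * np.clip((t - 150.0) / 200.0, 0.0, 1.0)
    ibi = 60000.0 / hr + rng.normal(0.0, 25.0)
    ibis.append(ibi)
    t += ibi / 1000.0
beats = BeatSeries.from_peak_times(np.concatenate([[0.0], np.cumsum(ibis) / 1000.0]))

timeline = run_session(beats, params)
lights, counts = np.unique(timeline.lights, return_counts=True)
print("\nlight occupancy:", dict(zip(lights, counts)), "of", len(timeline.lights), "beats")
if timeline.died:
    print(f"participant died at {timeline.death_time:.1f} s (red light at a death point)")
else:
    print("participant survived the full session")

print(f"\nboat speed at mean HR 70: {boat_speed(70.0, params):.0f} units "
      "(the shipped HR + 50 mapping; faster heart = faster boat)")
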