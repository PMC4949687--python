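"""Word-display scheduling and target-detection scoring.

Schedules display durations for a 64-word, 16 s comprehension block
(narrow words clamped at 175 ms, wider words linearly longer so the block
length is exact), and scores a simulated target-detection session with
the 1 s post-event response window.
"""

import numpy as np

from cortimap import DetectionRule, schedule_word_durations, score_detections

rng = np.random.default_rng(2)
widths = rng.uniform(1.0, 10.0, 64)  # rendered word widths, arbitrary units
sched = schedule_word_durations(widths, block_s=16.0, clamp_fraction=0.70)
print(f"words: {len(widths)}, block total: {sched.durations_s.sum():.3f} s")
print(f"clamp duration: {sched.clamp_s * 1000:.0f} ms "
      f"(70% of the {16/64*1000:.0f} ms average)")
print(f"duration range: {sched.durations_s.min()*1000:.0f}-"
      f"{sched.durations_s.max()*1000:.0f} ms")

targets = [(t, t + 0.25) for t in np.arange(20) * 12.0]  # color-change events
presses = sorted(t + rng.uniform(0.2, 0.9) for t, _ in targets[:18])
hit_rate, mean_rt = score_detections(targets, presses, DetectionRule(window_s=1.0))
print(f"targets: {len(targets)}, presses: {len(presses)}, "
      f"hit rate: {hit_rate:.0%}, mean RT: {mean_rt:.2f} s")
# a press counts if it lands within 1 s after the color change ends; RT is
# measured from target onset.
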