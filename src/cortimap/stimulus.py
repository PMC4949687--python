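"""Reading-experiment design utilities: word timing, block order, scoring.

Word display durations follow natural reading: narrow words get a fixed
minimum (the clamp), wider words get linearly increasing durations with
the slope solved in closed form so a block's durations sum exactly to the
block length.  With 64 words in a 16 s block and a clamp fraction of
0.70, the mean duration is 250 ms and the clamp is 175 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class WordSchedule:
    """Per-word widths and assigned display durations for one block."""

    widths: np.ndarray
    durations_s: np.ndarray
    block_s: float
    clamp_s: float
    slope: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "width": self.widths,
                "duration_ms": np.round(self.durations_s * 1000.0, 1),
            }
        )


@dataclass(frozen=True)
class DetectionRule:
    """Response window: a press within ``window_s`` after target end counts."""

    window_s: float = 1.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window must be positive")


def schedule_word_durations(
    widths, block_s: float = 16.0, clamp_fraction: float = 0.70
) -> WordSchedule:
    """Assign display durations so the block totals ``block_s`` exactly.

    Words no wider than ``clamp_fraction`` times the mean width get the
    clamp duration ``clamp_fraction * block_s / n``; wider words get
    clamp + slope * (width - clamp_fraction * mean_width), with

        slope = (block_s - n * clamp) / sum_wide(width - threshold)

    so durations sum to the block length in closed form.  With all widths
    equal, every word gets block_s / n.
    """
    widths = np.asarray(widths, dtype=float)
    if widths.size == 0 or np.any(widths <= 0):
        raise ValueError("need at least one positive width")
    if block_s <= 0:
        raise ValueError("block length must be positive")
    if not (0 < clamp_fraction < 1):
        raise ValueError("clamp_fraction must lie in (0, 1)")
    n = widths.size
    clamp = clamp_fraction * block_s / n
    threshold = clamp_fraction * widths.mean()
    excess = np.maximum(widths - threshold, 0.0)
    total_excess = excess.sum()
    remaining = block_s - n * clamp
    if total_excess <= 0:
        if abs(remaining) > 1e-9:
            raise ValueError(
                "all words at or below the clamp threshold; the clamp alone "
                "cannot sum to the block length"
            )
        slope = 0.0
    else:
        slope = remaining / total_excess
    durations = clamp + slope * excess
    return WordSchedule(widths, durations, block_s, clamp, slope)


def generate_block_order(n_blocks: int, conditions, seed: int) -> list:
    """Balanced random block order, deterministic per seed.

    Each condition appears exactly ``n_blocks / len(conditions)`` times.
    """
    conditions = list(conditions)
    if n_blocks % len(conditions):
        raise ValueError("n_blocks must be divisible by the number of conditions")
    reps = n_blocks // len(conditions)
    order = np.repeat(np.arange(len(conditions)), reps)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    return [conditions[i] for i in order]


def score_detections(
    targets, presses, rule: DetectionRule = DetectionRule()
) -> tuple[float, float]:
    """Hit rate and mean reaction time for a target-detection task.

    A target (onset, end) is hit iff at least one press falls in
    (onset, end + window] — the upper boundary inclusive.  Each press is
    credited to at most one target (greedy earliest-eligible matching);
    RT is measured from target onset.  Returns (hit_rate, mean_rt_s);
    the RT is NaN when there are no hits.
    """
    targets = sorted((float(a), float(b)) for a, b in targets)
    presses = sorted(float(t) for t in presses)
    used = [False] * len(presses)
    rts = []
    hits = 0
    for onset, end in targets:
        for i, t in enumerate(presses):
            if used[i]:
                continue
            if onset < t <= end + rule.window_s:
                used[i] = True
                hits += 1
                rts.append(t - onset)
                break
            if t > end + rule.window_s:
                break
    hit_rate = hits / len(targets) if targets else np.nan
    mean_rt = float(np.mean(rts)) if rts else np.nan
    return hit_rate, mean_rt
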