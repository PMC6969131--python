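"""Build the block-design auditory stimulation schedule and summarize it.

Writes the events table of a 12-block session and a one-line summary of the
timing arithmetic (20 syllables per 20-s block, SOA 600 ms, ITI 1.6 s,
40 s silence) under results/paradigm/.
"""

from pathlib import Path

import numpy as np

from nvcouple.paradigm import build_paradigm, write_events

OUT = Path(__file__).resolve().parents[1] / "results" / "paradigm"
OUT.mkdir(parents=True, exist_ok=True)

schedule = build_paradigm(n_blocks=12, seed=0)
write_events(schedule, OUT / "events.tsv")

per_block = [sum(ev.block_index == b for ev in schedule.events) for b in range(12)]
last_offsets = [
    max(ev.onset_s + ev.duration_s - schedule.block_onsets_s[ev.block_index]
        for ev in schedule.events if ev.block_index == b)
    for b in range(12)
]
print(f"blocks: {schedule.n_blocks}, events per block: {set(per_block)}")
print(f"block period: {schedule.block_period_s:.0f} s, total: {schedule.duration_s:.0f} s")
print(f"last syllable offset within block: {max(last_offsets):.3f} s (< 20 s stimulation)")
print(f"events table -> {OUT / 'events.tsv'}")
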