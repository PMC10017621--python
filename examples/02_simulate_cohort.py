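"""Simulate a paired two-rater annotation cohort and write it as CSVs.

Draws 5 ground-truth procedure timelines from the longer-procedure center
profile (~108 min, ~10 phases, ~33 steps per video), has two simulated
raters annotate each video under independent noise (boundary jitter, label
substitutions, spurious insertions, omissions), and writes standard
annotation CSVs.  The printed counts show the generator's realism: mean
phases/steps per video and mean duration.
"""

import numpy as np

from surgagree import (
    INTER_RATER_NOISE, STRASBOURG_LIKE, generate_cohort, load_packaged_lrygb,
    write_annotation_file,
)
from pathlib import Path

onto = load_packaged_lrygb()
cohort = generate_cohort(onto, STRASBOURG_LIKE, INTER_RATER_NOISE,
                         INTER_RATER_NOISE, n=5, seed=17)

out = Path("scratch_cohort")
for sub, vas in (("a", cohort.rater_a), ("b", cohort.rater_b)):
    (out / sub).mkdir(parents=True, exist_ok=True)
    for va in vas:
        write_annotation_file(va, out / sub / f"{va.video_id}.csv")

phases = [len(t.phase_track.intervals) for t in cohort.truths]
steps = [len(t.step_track.intervals) for t in cohort.truths]
durs = [t.duration_ms / 60000 for t in cohort.truths]
print(f"wrote 5 paired videos under {out}/")
print(f"mean phases/video: {np.mean(phases):.1f}  (profile expectation 10)")
print(f"mean steps/video:  {np.mean(steps):.1f}  (profile expectation ~33)")
print(f"mean duration:     {np.mean(durs):.0f} min")
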