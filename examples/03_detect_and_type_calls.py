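"""Detect calls from the Hilbert envelope and type them.

The detector thresholds the smoothed amplitude envelope against the
estimated chamber noise floor, then types each event by duration and
sustained intensity: short calls are brief and weak, alarm calls long and
loud, peeps everything between.
"""

from peepwatch import detect_and_classify, hilbert_envelope, synth_group_recording
from peepwatch.call_detection import count_by_type
from peepwatch.synth import GroupScenario

for n in (1, 3, 15):
    wave, annotation = synth_group_recording(GroupScenario(n_chicks=n, duration=30.0), seed=3)
    events = detect_and_classify(hilbert_envelope(wave))
    truth = len(annotation.merged_intervals())
    counts = count_by_type(events)
    print(
        f"{n:2d} chick(s): {truth:3d} observable events, {len(events):3d} detected -> "
        f"peep {counts['peep']:3d}, short {counts['short_call']:3d}, "
        f"alarm {counts['alarm_call']:3d}"
    )

print(
    "\nDetected counts track the annotated (overlap-merged) ground truth; "
    "the isolated chick is typed almost entirely as alarm calls."
)
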