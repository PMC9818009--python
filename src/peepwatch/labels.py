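"""Welfare-state label constants shared across the package."""

DISTRESS = "distress"
INTERMEDIATE = "intermediate"
NORMAL = "normal"

#: the two terminal welfare classes a classifier predicts
BINARY_LABELS = (DISTRESS, NORMAL)

#: labels a raw feature table may carry before the intermediate class is resolved
ALL_LABELS = (DISTRESS, INTERMEDIATE, NORMAL)
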