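"""End-to-end glue: recording -> per-window feature table.

Ties together windowing, energy / centroid extraction, call detection and
the mass normalization into the tabular row type the classifiers consume.
"""

from __future__ import annotations

import pandas as pd

from .audio_io import DEFAULT_WINDOW_S, Waveform, segment_windows
from .call_detection import DetectorConfig, count_by_type, detect_and_classify
from .features import (
    DEFAULT_CALIBRATION,
    energy_unit,
    hilbert_envelope,
    signal_energy,
    spectral_centroid,
    stft,
)


def extract_feature_table(
    w: Waveform,
    n_chicks: int,
    mean_weight: float,
    window_s: float = DEFAULT_WINDOW_S,
    calibration: float = DEFAULT_CALIBRATION,
    detector: DetectorConfig = DetectorConfig(),
    recording_id: str = "",
) -> pd.DataFrame:
    """One feature row per analysis window.

    Columns: recording_id, window_start_s, n_chicks, mean_weight_kg,
    energy_rel, energy_unit_kcal_per_kg, centroid (kHz), and per-type call
    counts (n_peep, n_short_call, n_alarm_call).
    """
    rows = []
    for win in segment_windows(w, window_s=window_s, recording_id=recording_id):
        e = signal_energy(win.waveform)
        cent = spectral_centroid(stft(win.waveform))
        events = detect_and_classify(hilbert_envelope(win.waveform), detector)
        counts = count_by_type(events)
        rows.append(
            {
                "recording_id": recording_id,
                "window_start_s": win.start,
                "n_chicks": n_chicks,
                "mean_weight_kg": mean_weight,
                "weight_kg": mean_weight,
                "energy_rel": e.energy,
                "energy_unit_kcal_per_kg": energy_unit(e, n_chicks, mean_weight, calibration),
                "centroid": cent.signal_khz,
                "n_peep": counts["peep"],
                "n_short_call": counts["short_call"],
                "n_alarm_call": counts["alarm_call"],
            }
        )
    return pd.DataFrame(rows)
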