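"""Synthetic chick-call audio and feature tables.

No public recording corpus accompanies the chick-vocalization welfare
workflow, so this module generates the study conditions instead: three call
types (peep, short call, alarm call) with distinct duration / intensity /
repetition signatures, group recordings in which per-bird vocal energy
falls steeply from social isolation (continuous high-intensity alarm
calling) to a calm 15-bird flock, a chamber noise floor roughly 24 dB below
the alarm-call peak, and feature tables drawn from the published per-group
means and standard errors.

Call waveform model: a sinusoid at the fundamental plus two harmonics at
-12 dB and -20 dB, amplitude-shaped with Hann-tapered onset/offset ramps
(a Tukey envelope). This is the simplest model that yields realistic tonal
spectrograms with a well-defined spectral centroid.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal.windows import tukey
from scipy.stats import norm, truncnorm

from . import labels
from .audio_io import DEFAULT_RATE, Waveform


class CallType(str, enum.Enum):
    PEEP = "peep"
    SHORT_CALL = "short_call"
    ALARM_CALL = "alarm_call"


@dataclass(frozen=True)
class CallTemplate:
    """Parametric description of one call type.

    Parameters
    ----------
    f0 : float
        Fundamental frequency, Hz; must lie below the Nyquist frequency of
        whatever rate the call is rendered at.
    duration : float
        Call length, s.
    amplitude : float
        Linear peak in (0, 1]; rendered waveforms hit this peak exactly.
    repetition_period : float
        Characteristic spacing between call onsets within a bout, s; used
        as the refractory floor when scheduling call trains.
    """

    call_type: CallType
    f0: float
    duration: float
    amplitude: float
    repetition_period: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.amplitude <= 1:
            raise ValueError("amplitude must lie in [0, 1]")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.repetition_period <= 0:
            raise ValueError("repetition_period must be positive")


#: amplitude ratios of the two harmonics (-12 dB, -20 dB)
HARMONIC_AMPLITUDES = (10 ** (-12 / 20), 10 ** (-20 / 20))

#: fraction of the call spent in the two Hann-shaped ramps combined
EDGE_FRACTION = 0.4

DEFAULT_TEMPLATES: dict[CallType, CallTemplate] = {
    CallType.PEEP: CallTemplate(CallType.PEEP, f0=3000.0, duration=0.15, amplitude=0.35, repetition_period=2.0),
    CallType.SHORT_CALL: CallTemplate(CallType.SHORT_CALL, f0=3600.0, duration=0.08, amplitude=0.28, repetition_period=1.5),
    CallType.ALARM_CALL: CallTemplate(CallType.ALARM_CALL, f0=2500.0, duration=0.35, amplitude=0.85, repetition_period=0.8),
}

#: chamber noise floor (linear RMS), ~24 dB below the alarm-call peak
DEFAULT_NOISE_FLOOR = DEFAULT_TEMPLATES[CallType.ALARM_CALL].amplitude * 10 ** (-24 / 20)


@dataclass(frozen=True)
class GroupProfile:
    """Published per-group feature statistics (means and standard errors)
    used as the generative defaults for feature tables."""

    n_chicks: int
    weight_mean: float  # kg/bird
    weight_se: float
    energy_mean: float  # kcal/kg
    energy_se: float
    centroid_mean: float  # kHz convention
    reaction: str


GROUP_PROFILES: dict[int, GroupProfile] = {
    1: GroupProfile(1, 0.045, 0.002, 14.87, 12.501, 1.24, labels.DISTRESS),
    3: GroupProfile(3, 0.047, 0.002, 0.16, 0.118, 2.73, labels.INTERMEDIATE),
    5: GroupProfile(5, 0.046, 0.000, 0.14, 0.068, 2.37, labels.INTERMEDIATE),
    7: GroupProfile(7, 0.048, 0.001, 0.14, 0.122, 1.30, labels.INTERMEDIATE),
    10: GroupProfile(10, 0.046, 0.000, 0.12, 0.088, 1.74, labels.INTERMEDIATE),
    15: GroupProfile(15, 0.047, 0.001, 0.05, 0.029, 1.96, labels.NORMAL),
}

#: spread of the synthetic spectral-centroid draws (kHz); the published
#: table prints no SE for the centroid column.
CENTROID_SD_KHZ = 0.15

# per-bird call rate (calls/min) versus group size: isolation elicits
# continuous alarm calling; calling relaxes as the flock grows
_RATE_TABLE = {1: 75.0, 3: 30.0, 5: 24.0, 7: 20.0, 10: 16.0, 15: 10.0}


def per_bird_call_rate(n_chicks: int) -> float:
    """Default per-bird call rate (calls/min), log-interpolated between the
    anchored group sizes and clamped outside 1..15."""
    if n_chicks < 1:
        raise ValueError("n_chicks must be >= 1")
    ns = np.array(sorted(_RATE_TABLE))
    rates = np.array([_RATE_TABLE[n] for n in ns])
    return float(np.interp(np.log(min(n_chicks, 15)), np.log(ns), rates))


def short_call_fraction(n_chicks: int) -> float:
    """Fraction of non-alarm calls that are short calls; short calls occur
    occasionally in groups of 3, 5, 10 and 15 but rarely at 7, and never in
    isolation (where all calling is alarm calling)."""
    if n_chicks == 1:
        return 0.0
    return 0.05 if n_chicks == 7 else 0.25


@dataclass(frozen=True)
class GroupScenario:
    """A group recording condition.

    ``call_rate_per_bird`` and ``noise_floor`` default to the package's
    rate curve and the chamber noise floor; ``mean_weight`` defaults to the
    published per-group mean (0.046 kg for unanchored group sizes).
    """

    n_chicks: int
    duration: float = 30.0
    mean_weight: float | None = None
    call_rate_per_bird: float | None = None
    noise_floor: float = DEFAULT_NOISE_FLOOR
    templates: dict[CallType, CallTemplate] = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))

    def __post_init__(self) -> None:
        if self.n_chicks < 1:
            raise ValueError("n_chicks must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be non-negative")
        if self.mean_weight is not None and self.mean_weight <= 0:
            raise ValueError("mean_weight must be positive")

    @property
    def weight(self) -> float:
        if self.mean_weight is not None:
            return self.mean_weight
        profile = GROUP_PROFILES.get(self.n_chicks)
        return profile.weight_mean if profile else 0.046

    @property
    def rate(self) -> float:
        if self.call_rate_per_bird is not None:
            return self.call_rate_per_bird
        return per_bird_call_rate(self.n_chicks)


@dataclass(frozen=True)
class AnnotatedEvent:
    onset: float
    offset: float
    call_type: CallType
    bird: int


@dataclass(frozen=True)
class SynthAnnotation:
    """Ground-truth call list for a synthetic recording."""

    events: tuple[AnnotatedEvent, ...]

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.onset, e.offset, e.call_type.value, e.bird) for e in self.events],
            columns=["onset_s", "offset_s", "call_type", "bird_idx"],
        )

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {t.value: 0 for t in CallType}
        for e in self.events:
            out[e.call_type.value] += 1
        return out

    def merged_intervals(self, min_gap: float = 0.0) -> list[tuple[float, float]]:
        """Union of annotated intervals, merging overlaps (and gaps below
        ``min_gap``). This is the event count an envelope detector can
        actually observe: simultaneous calls form one acoustic event."""
        if not self.events:
            return []
        spans = sorted((e.onset, e.offset) for e in self.events)
        merged = [list(spans[0])]
        for on, off in spans[1:]:
            if on - merged[-1][1] <= min_gap:
                merged[-1][1] = max(merged[-1][1], off)
            else:
                merged.append([on, off])
        return [tuple(m) for m in merged]


def _render_call(template: CallTemplate, sampling_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Render one call: f0 + harmonics below Nyquist, random phases, Tukey
    amplitude envelope, exact requested peak."""
    nyquist = sampling_rate / 2
    if template.f0 >= nyquist:
        raise ValueError(
            f"f0 {template.f0} Hz is at or above the Nyquist frequency {nyquist} Hz"
        )
    n = int(round(template.duration * sampling_rate))
    if n == 0:
        return np.zeros(0)
    t = np.arange(n) / sampling_rate
    x = np.zeros(n)
    for h, amp in enumerate([1.0, *HARMONIC_AMPLITUDES], start=1):
        f = template.f0 * h
        if f >= nyquist:
            continue  # drop aliasing harmonics
        x += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    x *= tukey(n, alpha=EDGE_FRACTION)
    peak = np.max(np.abs(x))
    if peak > 0 and template.amplitude > 0:
        x *= template.amplitude / peak
    else:
        x[:] = 0.0
    return x


def synth_call(template: CallTemplate, sampling_rate: float = DEFAULT_RATE, seed: int = 0) -> Waveform:
    """Synthesize a single call as a tonal burst.

    The output has ``round(duration * sampling_rate)`` samples and a peak
    absolute sample equal to ``template.amplitude`` (exactly, by
    renormalization); identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    return Waveform(_render_call(template, sampling_rate, rng), sampling_rate)


def _bird_schedule(
    scenario: GroupScenario, rng: np.random.Generator
) -> list[tuple[float, CallTemplate]]:
    """Call train for one bird: refractory interval plus exponential
    waiting time tuned to the scenario's per-bird rate."""
    mean_gap = 60.0 / scenario.rate
    short_frac = short_call_fraction(scenario.n_chicks)
    out: list[tuple[float, CallTemplate]] = []
    t = rng.uniform(0, mean_gap)
    while True:
        if scenario.n_chicks == 1:
            template = scenario.templates[CallType.ALARM_CALL]
        elif rng.uniform() < short_frac:
            template = scenario.templates[CallType.SHORT_CALL]
        else:
            template = scenario.templates[CallType.PEEP]
        if t + template.duration > scenario.duration:
            break
        out.append((t, template))
        refractory = max(template.duration + 0.05, 0.5 * template.repetition_period)
        t += refractory + rng.exponential(max(mean_gap - refractory, 0.01))
    return out


def synth_group_recording(
    scenario: GroupScenario,
    sampling_rate: float = DEFAULT_RATE,
    seed: int = 0,
) -> tuple[Waveform, SynthAnnotation]:
    """Mix per-bird call trains over Gaussian chamber noise.

    Call-type mix follows group size: only alarm calls in isolation
    (n_chicks = 1); peeps and occasional short calls otherwise. One global
    seed fans out to per-bird substreams, so the mix is reproducible
    independently of bird count. Output samples lie in [-1, 1] (rescaled
    only when summed calls would clip).
    """
    n = int(round(scenario.duration * sampling_rate))
    streams = np.random.SeedSequence(seed).spawn(scenario.n_chicks + 1)
    noise_rng = np.random.default_rng(streams[0])
    x = noise_rng.normal(0.0, scenario.noise_floor, n) if scenario.noise_floor > 0 else np.zeros(n)

    events: list[AnnotatedEvent] = []
    for bird in range(scenario.n_chicks):
        rng = np.random.default_rng(streams[bird + 1])
        # individual vocal-tract variation: each bird carries its own
        # fundamental, +/-4 % around the template
        f0_factor = rng.uniform(0.96, 1.04)
        for onset, template in _bird_schedule(scenario, rng):
            call = _render_call(replace(template, f0=template.f0 * f0_factor), sampling_rate, rng)
            i0 = int(round(onset * sampling_rate))
            x[i0 : i0 + len(call)] += call
            if template.amplitude > 0:
                events.append(
                    AnnotatedEvent(onset, onset + template.duration, template.call_type, bird)
                )
    peak = np.max(np.abs(x)) if n else 0.0
    if peak > 1.0:
        x /= peak
    events.sort(key=lambda e: (e.onset, e.bird))
    return Waveform(x, sampling_rate), SynthAnnotation(tuple(events))


def _truncated_normal_mean(mu: float, sd: float) -> float:
    a = -mu / sd
    return mu + sd * norm.pdf(a) / norm.sf(a)


def _matched_mu(target_mean: float, sd: float) -> float:
    """Underlying normal location whose zero-truncated mean equals
    ``target_mean`` (truncation pulls the mean up, so mu <= target)."""
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    lo = target_mean - 12 * sd
    return brentq(lambda mu: _truncated_normal_mean(mu, sd) - target_mean, lo, target_mean)


def _draw_truncated(target_mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(size, target_mean)
    mu = _matched_mu(target_mean, sd)
    return truncnorm.rvs(-mu / sd, np.inf, loc=mu, scale=sd, size=size, random_state=rng)


def synth_feature_table(
    n_instances: int,
    scenario_mix: dict[int, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a labeled feature table from the per-group statistics.

    Each row carries (weight_kg, n_chicks, energy_unit_kcal_per_kg,
    centroid, label). Draws come from zero-truncated normals whose means
    are calibrated to the published group means with the published SEs as
    spread; labels are distress (n=1), intermediate (n in {3,5,7,10}) and
    normal (n=15). Deterministic per seed.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if scenario_mix is None:
        scenario_mix = {n: 1 / len(GROUP_PROFILES) for n in GROUP_PROFILES}
    unknown = set(scenario_mix) - set(GROUP_PROFILES)
    if unknown:
        raise ValueError(f"unknown group size(s) {sorted(unknown)}; known: {sorted(GROUP_PROFILES)}")
    sizes = np.array(sorted(scenario_mix))
    probs = np.array([scenario_mix[n] for n in sizes], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("scenario_mix probabilities must sum to a positive value")
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    chosen = rng.choice(sizes, size=n_instances, p=probs)
    rows = []
    for n in sizes:
        k = int(np.sum(chosen == n))
        if k == 0:
            continue
        p = GROUP_PROFILES[int(n)]
        rows.append(
            pd.DataFrame(
                {
                    "weight_kg": _draw_truncated(p.weight_mean, p.weight_se, k, rng),
                    "n_chicks": int(n),
                    "energy_unit_kcal_per_kg": _draw_truncated(p.energy_mean, p.energy_se, k, rng),
                    "centroid": _draw_truncated(p.centroid_mean, CENTROID_SD_KHZ, k, rng),
                    "label": p.reaction,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return table.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)


def binarize_labels(
    table: pd.DataFrame,
    short_call_counts: np.ndarray | None = None,
    cutoff: int = 1,
) -> pd.DataFrame:
    """Resolve the intermediate class to the two extremes.

    With per-row ``short_call_counts``, intermediate rows with at least
    ``cutoff`` identified short calls become normal, the rest distress
    (short calls are the calm-group vocalization). Without counts, the
    deterministic resolution implied by the decision rules is used:
    intermediate groups larger than 6 birds are normal, smaller ones
    distress.
    """
    out = table.copy()
    inter = out["label"] == labels.INTERMEDIATE
    if short_call_counts is not None:
        counts = np.asarray(short_call_counts)
        if len(counts) != len(out):
            raise ValueError("short_call_counts must have one entry per table row")
        from .call_detection import reassign_intermediate

        out.loc[inter, "label"] = [
            reassign_intermediate(labels.INTERMEDIATE, int(c), cutoff)
            for c in counts[inter.to_numpy()]
        ]
    else:
        out.loc[inter, "label"] = np.where(
            out.loc[inter, "n_chicks"] > 6, labels.NORMAL, labels.DISTRESS
        )
    return out


def default_scenarios(duration: float = 30.0) -> dict[int, GroupScenario]:
    """The six study group sizes as ready-made scenarios."""
    return {n: GroupScenario(n_chicks=n, duration=duration) for n in GROUP_PROFILES}


def make_peep_template(**overrides) -> CallTemplate:
    """Convenience: the default peep template with field overrides."""
    return replace(DEFAULT_TEMPLATES[CallType.PEEP], **overrides)
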