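"""Synthetic call, recording and feature-table generators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peepwatch import signal_energy, synth_call, synth_feature_table, synth_group_recording
from peepwatch.synth import (
    DEFAULT_TEMPLATES,
    GROUP_PROFILES,
    CallTemplate,
    CallType,
    GroupScenario,
    binarize_labels,
    per_bird_call_rate,
)

from conftest import SR


class TestSynthCall:
    def test_duration_and_peak(self, peep_template):
        w = synth_call(peep_template, SR, seed=3)
        assert len(w) == round(peep_template.duration * SR)
        assert np.max(np.abs(w.samples)) == pytest.approx(peep_template.amplitude, rel=0.01)

    def test_zero_amplitude_is_silent(self, peep_template):
        from dataclasses import replace

        w = synth_call(replace(peep_template, amplitude=0.0), SR, seed=3)
        assert np.all(w.samples == 0)

    def test_deterministic_per_seed(self, alarm_template):
        a = synth_call(alarm_template, SR, seed=11)
        b = synth_call(alarm_template, SR, seed=11)
        c = synth_call(alarm_template, SR, seed=12)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_f0_at_nyquist_rejected(self, peep_template):
        from dataclasses import replace

        with pytest.raises(ValueError, match="Nyquist"):
            synth_call(replace(peep_template, f0=SR / 2), SR)

    def test_invalid_template_fields_rejected(self):
        with pytest.raises(ValueError):
            CallTemplate(CallType.PEEP, f0=3000, duration=-1, amplitude=0.3, repetition_period=1)
        with pytest.raises(ValueError):
            CallTemplate(CallType.PEEP, f0=3000, duration=0.1, amplitude=1.5, repetition_period=1)

    def test_alarm_louder_than_peep_by_default(self):
        assert (
            DEFAULT_TEMPLATES[CallType.ALARM_CALL].amplitude
            > DEFAULT_TEMPLATES[CallType.PEEP].amplitude
        )


class TestGroupRecording:
    def test_isolation_produces_only_alarm_calls(self):
        _, ann = synth_group_recording(GroupScenario(n_chicks=1, duration=30.0), SR, seed=5)
        assert len(ann) > 0
        assert {e.call_type for e in ann.events} == {CallType.ALARM_CALL}

    def test_full_flock_produces_no_alarm_calls(self):
        _, ann = synth_group_recording(GroupScenario(n_chicks=15, duration=30.0), SR, seed=5)
        assert len(ann) > 0
        assert CallType.ALARM_CALL not in {e.call_type for e in ann.events}

    def test_silent_scenario(self):
        sc = GroupScenario(n_chicks=3, duration=2.0, call_rate_per_bird=1e-9, noise_floor=0.0)
        w, ann = synth_group_recording(sc, SR, seed=0)
        assert np.all(w.samples == 0)
        assert len(ann) == 0

    @given(seed=st.integers(0, 50), n=st.sampled_from([1, 3, 7, 15]))
    @settings(max_examples=12, deadline=None, derandomize=True)
    def test_samples_bounded_and_reproducible(self, seed, n):
        sc = GroupScenario(n_chicks=n, duration=4.0)
        w1, a1 = synth_group_recording(sc, SR, seed=seed)
        w2, a2 = synth_group_recording(sc, SR, seed=seed)
        assert np.max(np.abs(w1.samples)) <= 1.0
        assert np.array_equal(w1.samples, w2.samples)
        assert a1 == a2

    def test_onsets_strictly_increasing_per_bird(self):
        _, ann = synth_group_recording(GroupScenario(n_chicks=5, duration=20.0), SR, seed=9)
        for bird in range(5):
            onsets = [e.onset for e in ann.events if e.bird == bird]
            assert all(b > a for a, b in zip(onsets, onsets[1:]))
        for e in ann.events:
            assert 0 <= e.onset < e.offset <= 20.0

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            GroupScenario(n_chicks=0)
        with pytest.raises(ValueError):
            GroupScenario(n_chicks=3, duration=0)

    def test_merged_intervals_union(self):
        from peepwatch.synth import AnnotatedEvent, SynthAnnotation

        ann = SynthAnnotation(
            (
                AnnotatedEvent(0.0, 0.2, CallType.PEEP, 0),
                AnnotatedEvent(0.1, 0.3, CallType.PEEP, 1),
                AnnotatedEvent(0.5, 0.6, CallType.PEEP, 0),
            )
        )
        assert ann.merged_intervals() == [(0.0, 0.3), (0.5, 0.6)]


class TestEnergyOrdering:
    def test_per_bird_rate_curve_strictly_decreasing(self):
        rates = [per_bird_call_rate(n) for n in (1, 3, 5, 7, 10, 15)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_mass_normalized_energy_extremes(self):
        # emitted vocal energy per unit flock mass: isolation maximal,
        # 15-bird flock minimal
        units = {}
        for n in (1, 3, 15):
            sc = GroupScenario(n_chicks=n, duration=30.0)
            w, _ = synth_group_recording(sc, SR, seed=21)
            units[n] = signal_energy(w).energy / (n * sc.weight)
        assert units[1] > units[3] > units[15]


class TestFeatureTable:
    @pytest.mark.parametrize("group,mean,se", [(1, 14.87, 12.501), (15, 0.05, 0.029)])
    def test_energy_marginals_recover_group_means(self, group, mean, se):
        t = synth_feature_table(1000, scenario_mix={group: 1.0}, seed=123)
        sample_mean = t["energy_unit_kcal_per_kg"].mean()
        assert abs(sample_mean - mean) < 3 * se / np.sqrt(1000)
        assert (t["energy_unit_kcal_per_kg"] >= 0).all()

    def test_labels_follow_group_size(self):
        t = synth_feature_table(600, seed=4)
        assert set(t.loc[t.n_chicks == 1, "label"]) == {"distress"}
        assert set(t.loc[t.n_chicks == 15, "label"]) == {"normal"}
        assert set(t.loc[t.n_chicks.isin([3, 5, 7, 10]), "label"]) == {"intermediate"}

    def test_deterministic_per_seed(self):
        a = synth_feature_table(50, seed=9)
        b = synth_feature_table(50, seed=9)
        assert a.equals(b)

    def test_degenerate_requests_rejected(self):
        with pytest.raises(ValueError):
            synth_feature_table(0)
        with pytest.raises(ValueError, match="unknown group"):
            synth_feature_table(10, scenario_mix={4: 1.0})

    def test_binarize_by_group_size(self):
        t = synth_feature_table(300, seed=2)
        b = binarize_labels(t)
        assert set(b["label"]) <= {"distress", "normal"}
        assert (b.loc[b.n_chicks.isin([3, 5]), "label"] == "distress").all()
        assert (b.loc[b.n_chicks.isin([7, 10]), "label"] == "normal").all()

    def test_binarize_by_short_call_counts(self):
        t = synth_feature_table(100, seed=2)
        counts = np.where(t["n_chicks"] > 6, 3, 0)
        b = binarize_labels(t, short_call_counts=counts, cutoff=1)
        inter = t["label"] == "intermediate"
        assert (b.loc[inter & (t.n_chicks > 6), "label"] == "normal").all()
        assert (b.loc[inter & (t.n_chicks <= 6), "label"] == "distress").all()

    def test_profiles_cover_study_groups(self):
        assert sorted(GROUP_PROFILES) == [1, 3, 5, 7, 10, 15]
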