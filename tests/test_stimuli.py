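"""Stimulus generator: trapezoid profile, contact mechanics, quantization."""

import numpy as np
import pytest

from neurotactile import stimuli
from neurotactile.stimuli import (
    DEFAULT_OBJECTS,
    GridSpec,
    IndentationProfile,
    StimulusObject,
    contact_footprint,
    generate_dataset,
    generate_trial,
    load_dataset,
    save_dataset,
    trapezoid_depth,
)


class TestTrapezoid:
    def test_endpoints_and_plateau(self):
        p = IndentationProfile()
        d = trapezoid_depth(p)
        assert len(d) == 2501
        assert d[0] == 0.0 and d[-1] == 0.0
        # maximal and constant exactly on [onset, onset+hold]
        assert np.all(d[250:2251] == p.depth_mm)
        assert np.all(d[:250] < p.depth_mm)
        assert np.all(d[2251:] < p.depth_mm)

    @pytest.mark.parametrize("onset,hold,offset", [(250, 2000, 250), (50, 400, 50), (0, 100, 0)])
    def test_ramps_linear(self, onset, hold, offset):
        p = IndentationProfile(onset_ms=onset, hold_ms=hold, offset_ms=offset, depth_mm=2.0)
        d = trapezoid_depth(p)
        assert len(d) == p.total_ms + 1
        if onset > 1:
            assert np.allclose(np.diff(d[:onset]), 2.0 / onset)
        if offset > 1:
            assert np.allclose(np.diff(d[onset + hold :]), -2.0 / offset)


class TestContactFootprint:
    def test_zero_depth_is_zero_pressure(self):
        P = contact_footprint(StimulusObject("cone", 3.0), 0.0)
        assert np.all(P == 0)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            contact_footprint(StimulusObject("cone", 3.0), -0.1)

    def test_off_grid_footprint_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="off-grid"):
            P = contact_footprint(StimulusObject("cone", 1.0), 1.0, center_offset_mm=(60.0, 0.0))
        assert np.all(P == 0)

    def test_total_pressure_grows_with_depth(self):
        obj = StimulusObject("cone", 5.0)
        sums = [contact_footprint(obj, d).sum() for d in (0.0, 0.5, 1.0, 1.4)]
        assert all(a < b for a, b in zip(sums, sums[1:]))

    @pytest.mark.parametrize("shape", ["cone", "cube"])
    def test_total_pressure_independent_of_feature_size(self, shape):
        sums = [
            contact_footprint(StimulusObject(shape, s), 1.0).sum() for s in (1.0, 3.0, 5.0)
        ]
        assert max(sums) / min(sums) < 1.02  # discretization error only

    @pytest.mark.parametrize("shape", ["cone", "cube"])
    def test_sharper_means_fewer_taxels_higher_peak(self, shape):
        """Sharp objects: few taxels at high pressure; blunt: many at low."""
        foot = [contact_footprint(StimulusObject(shape, s), 1.4) for s in (1.0, 3.0, 5.0, 9.0)]
        peaks = [P.max() for P in foot]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))  # strictly decreasing
        active = [(P > 0.5 * P.max()).sum() for P in foot]
        assert all(a <= b for a, b in zip(active, active[1:]))
        assert active[0] < active[-1]

    def test_wide_bar_covers_more_taxels_than_edge(self):
        """Enumerated coverage: 9 mm-wide bar crosses threshold on strictly
        more taxels than the 1 mm edge at equal depth."""
        p1 = contact_footprint(StimulusObject("cube", 1.0), 1.0)
        p9 = contact_footprint(StimulusObject("cube", 9.0), 1.0)
        thr = 50.0
        assert (p9 > thr).sum() > (p1 > thr).sum()

    def test_cone_footprint_is_round_bar_is_stripe(self):
        """Geometry sanity: the cone loads a central blob, the bar a full row."""
        Pc = contact_footprint(StimulusObject("cone", 3.0), 1.4)
        Pb = contact_footprint(StimulusObject("cube", 3.0), 1.4)
        assert np.argmax(Pc) == 12  # center taxel of the 5x5
        row = Pb[2]
        assert row.min() > 0.3 * row.max()  # stripe spans all columns


class TestGenerateTrial:
    def test_hold_phase_constant_without_noise(self, sharp_trial, short_profile):
        f = sharp_trial.frames
        hold = f[short_profile.onset_ms : short_profile.onset_ms + short_profile.hold_ms + 1]
        assert np.all(hold == hold[0])

    def test_default_profile_yields_2501_frames(self):
        tr = generate_trial(StimulusObject("cone", 3.0), seed=1)
        assert tr.frames.shape == (2501, 5, 5)

    def test_quantization_range_and_dtype(self, short_dataset):
        for tr in short_dataset[:8]:
            assert tr.frames.dtype == np.int16
            assert tr.frames.min() >= 0
            assert tr.frames.max() <= 1023

    def test_same_seed_bit_identical(self, short_profile):
        obj = StimulusObject("cube", 3.0)
        a = generate_trial(obj, short_profile, seed=9)
        b = generate_trial(obj, short_profile, seed=9)
        assert np.array_equal(a.frames, b.frames)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_trial(StimulusObject("cone", 1.0), noise_sd=-1.0)


class TestGenerateDataset:
    def test_default_experiment_is_80_trials(self):
        profile = IndentationProfile(onset_ms=10, hold_ms=30, offset_ms=10)
        data = generate_dataset(profile=profile, master_seed=0)
        assert len(data) == 80
        labels = [t.object.label for t in data]
        assert len(set(labels)) == 8

    def test_single_object_single_trial(self):
        data = generate_dataset(
            [StimulusObject("cone", 1.0)], 1,
            profile=IndentationProfile(onset_ms=10, hold_ms=10, offset_ms=10),
        )
        assert len(data) == 1

    def test_master_seed_changes_frames_not_labels(self, short_profile):
        a = generate_dataset(n_trials_per_object=2, profile=short_profile, master_seed=1)
        b = generate_dataset(n_trials_per_object=2, profile=short_profile, master_seed=2)
        assert [t.object.label for t in a] == [t.object.label for t in b]
        assert any(not np.array_equal(x.frames, y.frames) for x, y in zip(a, b))

    def test_empty_object_list_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset([], 1)


def test_dataset_roundtrip(tmp_path, short_profile):
    data = generate_dataset(
        DEFAULT_OBJECTS[:2], 2, profile=short_profile, master_seed=3
    )
    save_dataset(data, tmp_path / "ds")
    back = load_dataset(tmp_path / "ds")
    assert len(back) == len(data)
    for x, y in zip(data, back):
        assert x.object == y.object
        assert x.seed == y.seed
        assert np.array_equal(x.frames, y.frames)


def test_grid_defaults():
    g = GridSpec()
    assert (g.rows, g.cols, g.pitch_mm, g.full_scale) == (5, 5, 2.8, 1023)
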