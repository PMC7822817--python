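"""Izhikevich dynamics, afferent front-ends and population encoding."""

import numpy as np
import pytest

from neurotactile import stimuli
from neurotactile.encoder import (
    IzhikevichParams,
    NeuronState,
    NociceptorSpec,
    encode_dataset,
    encode_trial,
    initial_state,
    izhikevich_run,
    izhikevich_step,
    load_response,
    nociceptor_input,
    ra_front_end,
    save_response,
)


class TestIzhikevichStep:
    def test_single_step_matches_symbolic_update(self):
        """One Euler step equals a hand-evaluated (1/32)v^2+4v+109.375 update."""
        p = IzhikevichParams.regular_spiking()
        v, u, I = -60.0, -12.0, 40.0
        new, spiked = izhikevich_step(NeuronState(v, u), I, p)
        v_expected = v + ((1 / 32) * v * v + 4 * v + 109.375 - u + p.k_scale * I)
        u_expected = u + p.a * (p.b * v - u)
        assert not spiked
        assert new.v == pytest.approx(v_expected, abs=1e-12)
        assert new.u == pytest.approx(u_expected, abs=1e-12)

    @pytest.mark.parametrize(
        "params", [IzhikevichParams.regular_spiking(), IzhikevichParams.fast_spiking()]
    )
    def test_reset_law(self, params):
        """On threshold crossing: v <- c and u <- u_pre + d."""
        state = NeuronState(v=20.0, u=0.0)
        new, spiked = izhikevich_step(state, 500.0, params)
        assert spiked
        assert new.v == params.c
        assert new.u == state.u + params.d

    def test_non_finite_input_rejected(self):
        p = IzhikevichParams.regular_spiking()
        with pytest.raises(ValueError):
            izhikevich_step(NeuronState(np.nan, 0.0), 0.0, p)

    def test_zero_input_settles_at_quadratic_root(self):
        """With u at equilibrium (u = b v) the rest point solves
        (1/32)v^2 + (4-b)v + 109.375 = 0; the stable root is ~ -74.82 mV."""
        p = IzhikevichParams.regular_spiking()
        root = min(np.roots([1 / 32, 4 - p.b, 109.375]))
        state = initial_state(p)
        n_spikes = 0
        for _ in range(2500):
            state, spiked = izhikevich_step(state, 0.0, p)
            n_spikes += spiked
        assert n_spikes == 0
        assert state.v == pytest.approx(root, abs=0.1)

    def test_fast_spiking_outpaces_regular_spiking(self):
        """At the same drive the FS preset fires at a strictly higher rate
        (its recovery decays five times faster)."""
        drive = np.full((1, 2000), 15.0)
        rs = IzhikevichParams.regular_spiking()
        fs = IzhikevichParams.fast_spiking()
        n_rs = izhikevich_run(drive, rs.a, rs.b, rs.c, rs.d).sum()
        n_fs = izhikevich_run(drive, fs.a, fs.b, fs.c, fs.d).sum()
        assert n_fs > n_rs > 0

    def test_vectorized_run_matches_stepwise(self):
        p = IzhikevichParams.fast_spiking()
        drive = np.linspace(0, 30, 400)[None, :]
        raster = izhikevich_run(drive, p.a, p.b, p.c, p.d)[0]
        state = initial_state(p)
        for t in range(drive.shape[1]):
            state, spiked = izhikevich_step(state, drive[0, t] / p.k_scale, p)
            assert spiked == raster[t]


class TestRaFrontEnd:
    def test_constant_drive_silent(self):
        assert np.all(ra_front_end(np.full(100, 42.0)) == 0)

    def test_ramp_gives_constant_rectified_slope(self):
        out = ra_front_end(np.arange(0, 50, 0.5), k3=128.0)
        assert out.shape == (99,)
        assert np.allclose(out, 128.0 * 0.5)

    def test_falling_ramp_also_excites(self):
        """Full-wave rectification: offset transients drive RA-I too."""
        out = ra_front_end(np.arange(50, 0, -0.5))
        assert np.all(out > 0)

    def test_trapezoid_nonzero_only_on_ramps(self):
        prof = stimuli.IndentationProfile(onset_ms=50, hold_ms=100, offset_ms=50)
        drive = 100.0 * stimuli.trapezoid_depth(prof)
        out = ra_front_end(drive)
        assert np.all(out[:50] > 0)
        assert np.all(out[50:150] == 0)
        assert np.all(out[150:] > 0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ra_front_end([1.0])


class TestNociceptorInput:
    def test_silent_below_threshold(self):
        frame = np.full((5, 5), 100)
        assert nociceptor_input(frame, NociceptorSpec(threshold_adc=512)) == 0.0

    def test_sharp_contact_one_hot_taxel(self):
        frame = np.zeros((5, 5), dtype=int)
        frame[2, 2] = 1000
        assert nociceptor_input(frame, NociceptorSpec(threshold_adc=500)) == 1000.0

    def test_distributed_pressure_divides_down(self):
        frame = np.zeros((5, 5), dtype=int)
        frame.ravel()[:10] = 1000
        spec = NociceptorSpec(threshold_adc=500)
        assert nociceptor_input(frame, spec) == pytest.approx(100.0)
        # FPGA mode: shift by ceil(log2(10)) = 4, i.e. divide by 16
        assert nociceptor_input(frame, spec, shift_division=True) == pytest.approx(62.5)

    def test_threshold_bounds_validated(self):
        with pytest.raises(ValueError):
            NociceptorSpec(threshold_adc=0)


class TestEncodeTrial:
    def test_zero_trial_gives_23_empty_trains(self, short_profile, default_imap):
        tr = stimuli.generate_trial(
            stimuli.StimulusObject("cone", 1.0), short_profile, seed=0,
            noise_sd=0.0, jitter_mm=0.0, force_scale_sd=0.0,
        )
        tr.frames = np.zeros_like(tr.frames)
        resp = encode_trial(tr, default_imap)
        assert len(resp.trains) == 23
        assert all(t.n_spikes == 0 for t in resp.trains)

    def test_channel_order_noc_sa_ra(self, sharp_trial, default_imap):
        resp = encode_trial(sharp_trial, default_imap)
        assert resp.kinds == ("NOC",) * 5 + ("SA1",) * 6 + ("RA1",) * 12

    def test_spike_times_strictly_increasing_within_duration(
        self, sharp_trial, default_imap
    ):
        resp = encode_trial(sharp_trial, default_imap)
        for t in resp.trains:
            if t.n_spikes > 1:
                assert np.all(np.diff(t.times_ms) > 0)
            if t.n_spikes:
                assert t.times_ms.min() >= 0 and t.times_ms.max() <= resp.duration_ms

    def test_sharp_drives_nociceptors_blunt_drives_sa(
        self, sharp_trial, blunt_trial, default_imap
    ):
        """Sharpness inverts the NOC/SA balance: the 1 mm cone excites
        nociceptors more and SA-I less than the 9 mm cone."""
        sharp = encode_trial(sharp_trial, default_imap)
        blunt = encode_trial(blunt_trial, default_imap)

        def mean_count(resp, kind):
            counts = [t.n_spikes for t in resp.trains if t.kind == kind]
            return np.mean(counts)

        assert mean_count(sharp, "NOC") > mean_count(blunt, "NOC")
        assert mean_count(sharp, "SA1") < mean_count(blunt, "SA1")

    def test_ra_confined_to_onset_offset(self, blunt_trial, short_profile, default_imap):
        """Rapidly adapting afferents respond to changes only: every RA-I
        spike falls in the onset or offset window (+50 ms relaxation)."""
        resp = encode_trial(blunt_trial, default_imap)
        on_end = short_profile.onset_ms + 50
        off_start = short_profile.onset_ms + short_profile.hold_ms
        for t in resp.trains:
            if t.kind == "RA1" and t.n_spikes:
                ok = (t.times_ms <= on_end) | (t.times_ms >= off_start)
                assert np.all(ok)

    def test_sa_active_through_hold(self, blunt_trial, short_profile, default_imap):
        resp = encode_trial(blunt_trial, default_imap)
        lo = short_profile.onset_ms + 50
        hi = short_profile.onset_ms + short_profile.hold_ms - 50
        sa_hold = sum(
            ((t.times_ms > lo) & (t.times_ms < hi)).sum()
            for t in resp.trains
            if t.kind == "SA1"
        )
        assert sa_hold > 0

    def test_deterministic(self, sharp_trial, default_imap):
        a = encode_trial(sharp_trial, default_imap)
        b = encode_trial(sharp_trial, default_imap)
        for x, y in zip(a.trains, b.trains):
            assert np.array_equal(x.times_ms, y.times_ms)

    def test_grid_mismatch_rejected(self, default_imap, short_profile):
        tr = stimuli.generate_trial(
            stimuli.StimulusObject("cone", 1.0), short_profile,
            grid=stimuli.GridSpec(rows=4, cols=4), seed=0,
        )
        with pytest.raises(ValueError):
            encode_trial(tr, default_imap)

    def test_batched_dataset_equals_per_trial(self, short_dataset, default_imap):
        batched = encode_dataset(short_dataset[:6], default_imap, noc_gain_seed=7)
        from neurotactile.encoder import nociceptor_gains

        gains = nociceptor_gains(5, seed=7)
        for tr, resp in zip(short_dataset[:6], batched):
            single = encode_trial(tr, default_imap, noc_gain=gains)
            for x, y in zip(single.trains, resp.trains):
                assert np.array_equal(x.times_ms, y.times_ms)

    def test_nociceptor_channels_not_identical(self, sharp_trial, default_imap):
        """The five nociceptors share one input but have jittered gains."""
        resp = encode_trial(sharp_trial, default_imap)
        noc = [tuple(t.times_ms) for t in resp.trains if t.kind == "NOC"]
        assert len(set(noc)) > 1


class TestFixedPointEncoding:
    def test_fixed_point_matches_float_spike_counts(self, sharp_trial, default_imap):
        """Q13.18 datapath reproduces the float spike counts within +-1."""
        a = encode_trial(sharp_trial, default_imap)
        b = encode_trial(sharp_trial, default_imap, fixed_point=True)
        for x, y in zip(a.trains, b.trains):
            assert abs(x.n_spikes - y.n_spikes) <= 1


def test_response_roundtrip(tmp_path, sharp_trial, default_imap):
    resp = encode_trial(sharp_trial, default_imap)
    path = save_response(resp, tmp_path / "spikes.csv")
    back = load_response(path, n_channels=23, duration_ms=resp.duration_ms)
    for x, y in zip(resp.trains, back.trains):
        assert np.array_equal(x.times_ms, y.times_ms)
        if x.n_spikes:
            assert x.kind == y.kind
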