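"""Neural feature pipeline: filtering, neurograms, windows, activations,
classification, artefact discrimination, decontamination, DRCs."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from ecapkit import ecaps, synth
from ecapkit.ecaps import EcapsConfig
from ecapkit.errors import BoundsError, ValidationError
from ecapkit.session import ChannelTrace


def _sine_trace(freq_hz, fs=20_000.0, dur=2.0):
    t = np.arange(int(fs * dur)) / fs
    return ChannelTrace("c", "neural", fs, 0.0, np.sin(2 * np.pi * freq_hz * t))


class TestPreprocess:
    def test_slow_component_attenuated_40db(self):
        out = ecaps.preprocess_neural(_sine_trace(1.0))
        mid = slice(20_000 // 2, -20_000 // 2)  # avoid edge transients
        assert np.max(np.abs(out.samples[mid])) < 1e-2  # > 40 dB down

    def test_passband_within_1db(self):
        out = ecaps.preprocess_neural(_sine_trace(1000.0))
        mid = slice(20_000 // 2, -20_000 // 2)
        assert np.max(np.abs(out.samples[mid])) > 10 ** (-1 / 20)

    def test_zeros_stay_zeros(self):
        tr = ChannelTrace("c", "neural", 20_000.0, 0.0, np.zeros(1000))
        assert np.allclose(ecaps.preprocess_neural(tr).samples, 0.0)

    def test_low_sampling_rate_rejected(self):
        tr = ChannelTrace("c", "neural", 400.0, 0.0, np.zeros(1000))
        with pytest.raises(ValidationError, match="sampling rate"):
            ecaps.preprocess_neural(tr)

    def test_wrong_modality_rejected(self):
        tr = ChannelTrace("c", "ecg", 20_000.0, 0.0, np.zeros(1000))
        with pytest.raises(ValidationError):
            ecaps.preprocess_neural(tr)


class TestExtractNeurogram:
    def test_pulse_grouping_monophasic_vs_biphasic(self):
        from dataclasses import replace
        cfg = synth.SessionConfig(currents=(1.0,), frequencies=(10.0,),
                                  durations=(1.0,), inter_event_gap=5.0,
                                  lead_in=8.0, tail=5.0)
        for waveform, expected in [("monophasic", {"cathodic": 10}),
                                   ("biphasic_alternating",
                                    {"cathodic": 5, "anodic": 5})]:
            sess, _ = synth.generate_session(replace(cfg, waveform=waveform),
                                             seed=0)
            ngs = ecaps.extract_neurogram(sess, sess.events[0], "cuffA")
            assert {p: n.n_pulses for p, n in ngs.items()} == expected

    def test_noise_free_percentiles_collapse(self, noisefree_train_session):
        sess, _ = noisefree_train_session
        ngs = ecaps.extract_neurogram(sess, sess.events[1], "cuffA")
        ng = ngs["cathodic"]
        assert np.allclose(ng.p5, ng.mean, atol=1e-9)
        assert np.allclose(ng.p95, ng.mean, atol=1e-9)

    def test_peak_latency_matches_ground_truth(self, default_session,
                                               default_features):
        sess, gt = default_session
        _, neurograms = default_features
        ev = sess.events[-1]  # saturating current
        ng = neurograms[(ev.event_id, "cuffA", "cathodic")]
        for fiber, lo, hi in [("Abeta", 0.75, 1.4), ("Agamma", 1.7, 3.3),
                              ("B", 8.0, 11.0)]:
            lat = ecaps.peak_latency(ng, lo, hi)
            true = gt.event(ev.event_id).latency_ms[(fiber, "cuffA",
                                                     "cathodic")]
            assert lat == pytest.approx(true, abs=0.051)  # 1 sample @ 20 kHz

    def test_epoch_past_trace_end_raises(self, default_session):
        sess, _ = default_session
        short = ChannelTrace("cuffA", "neural", 20_000.0, 0.0,
                             sess.trace("cuffA").samples[:1000])
        with pytest.raises(BoundsError):
            ecaps.extract_neurogram(sess, sess.events[0], short)


class TestFiberWindows:
    # blanking moved below the A-beta window start so the pure d/v bounds
    # are visible
    CFG = EcapsConfig(blank_ms=(0.0, 0.5))

    def test_window_bounds_scale_with_velocity(self):
        geom = synth.default_geometry()
        windows = {w.fiber_type: w for w in ecaps.fiber_windows(
            geom, "cuffA", "C1-C8", "cathodic", 1.0, self.CFG)}
        assert windows["Abeta"].latency_start == pytest.approx(50 / 70)
        assert windows["Abeta"].latency_end == pytest.approx(50 / 30)
        assert windows["B"].latency_start == pytest.approx(50 / 8)
        assert windows["B"].latency_end == pytest.approx(50 / 3)

    def test_bounds_linear_in_distance(self):
        geom = synth.default_geometry()
        wa = {w.fiber_type: w for w in ecaps.fiber_windows(
            geom, "cuffA", "C1-C8", "cathodic", 1.0, self.CFG)}
        wb = {w.fiber_type: w for w in ecaps.fiber_windows(
            geom, "cuffB", "C1-C8", "cathodic", 1.0, self.CFG)}
        for f in ("Abeta", "Agamma", "Adelta", "B"):  # C clips at epoch end
            assert wb[f].latency_end / wa[f].latency_end == \
                pytest.approx(54.5 / 50.0)

    def test_cathodic_has_no_shift_anodic_widens(self):
        geom = synth.default_geometry()
        cfg = EcapsConfig()
        cath = {w.fiber_type: w for w in ecaps.fiber_windows(
            geom, "cuffA", "C1-C8", "cathodic", 2.5, cfg)}
        anod = {w.fiber_type: w for w in ecaps.fiber_windows(
            geom, "cuffA", "C8-C1", "anodic", 2.5, cfg)}
        # same source contact C1; anodic start pulled earlier by the
        # virtual-cathode shift (2 mm/mA x 2.5 mA = 5 mm)
        assert anod["B"].latency_start == pytest.approx((50 - 5) / 8)
        assert cath["B"].latency_start == pytest.approx(50 / 8)

    def test_fast_fiber_hidden_in_blanking_is_unobservable(self):
        cfg = EcapsConfig(velocity_bins={"Aalpha": (70.0, 120.0)})
        w, = ecaps.fiber_windows(synth.default_geometry(), "cuffA",
                                 "C1-C8", "cathodic", 1.0, cfg)
        assert not w.observable  # [0.42, 0.71] ms sits inside the artefact


class TestFiberActivation:
    def _ng(self, mean):
        n = len(mean)
        lat = np.arange(n) / 20.0
        return ecaps.Neurogram("e", "c", "cathodic", lat, mean,
                               mean.copy(), mean.copy(), 1)

    def test_zero_signal_zero_activation(self):
        ng = self._ng(np.zeros(600))
        w = ecaps.FiberWindow("B", 5.0, 15.0)
        rec = ecaps.fiber_activation(ng, [w])
        assert rec.activation["B"] == 0.0

    def test_linear_ramp_removed_by_detrend(self):
        ng = self._ng(np.linspace(0, 10, 600))
        w = ecaps.FiberWindow("B", 5.0, 15.0)
        assert ecaps.fiber_activation(ng, [w]).activation["B"] == \
            pytest.approx(0.0, abs=1e-9)

    def test_saturated_activation_matches_recruitment(self, default_session,
                                                      default_features):
        sess, gt = default_session
        table, _ = default_features
        sel = table[(table["channel_id"] == "cuffA")
                    & (table["frequency_hz"] == 10.0)]
        for fiber in ("Abeta", "Agamma", "B"):
            fg = sel[sel["fiber"] == fiber].set_index("current_mA")
            for cur in (2.2, 2.5):
                ev_id = fg.loc[cur, "event_id"]
                true = gt.event(ev_id).recruitment[(fiber, "cathodic")]
                assert fg.loc[cur, "activation_norm"] == pytest.approx(
                    true, abs=0.05)


class TestClassification:
    @pytest.mark.parametrize("latency,expected", [
        (1.0, "Abeta"),     # 50 m/s
        (5.0, "B"),         # 10 m/s -> wait: 10 m/s is Adelta bin
    ])
    def test_table_examples(self, latency, expected):
        # 50 mm at 1.0 ms -> 50 m/s -> A-beta; at 5.0 ms -> 10 m/s which
        # falls in the (non-overlapping) A-delta bin [8, 15)
        v = 50.0 / latency
        got = ecaps.classify_component(latency, 50.0)
        if v >= 30:
            assert got == "Abeta"
        elif 8 <= v < 15:
            assert got == "Adelta"

    def test_b_fiber_bin(self):
        assert ecaps.classify_component(9.1, 50.0) == "B"  # 5.5 m/s

    def test_below_all_bins_unclassified(self):
        assert ecaps.classify_component(100.0, 50.0) == ecaps.UNCLASSIFIED

    def test_identity_on_generated_fibers(self, noisefree_train_session):
        sess, gt = noisefree_train_session
        ngs = ecaps.extract_neurogram(sess, sess.events[0], "cuffA")
        ng = ngs["cathodic"]
        for fiber, lo, hi in [("Abeta", 0.75, 1.4), ("Agamma", 1.7, 3.3),
                              ("Adelta", 3.4, 6.2), ("B", 8.0, 11.0)]:
            lat = ecaps.peak_latency(ng, lo, hi)
            assert ecaps.classify_component(lat, 50.0) == fiber


class TestArtefactDiscrimination:
    def test_propagating_vs_fixed(self, default_session, default_features):
        sess, _ = default_session
        _, neurograms = default_features
        ev = sess.events[7]  # mid current: A-gamma and muscle both present
        lats, mus = {}, {}
        for chan in ("cuffA", "cuffB"):
            ng = neurograms[(ev.event_id, chan, "cathodic")]
            d = sess.geometry.distance("C1", chan)
            lats[chan] = ecaps.peak_latency(ng, d / 30.0, d / 15.0)
            mus[chan] = ecaps.peak_latency(ng, 4.0, 8.0)
        dist = {"cuffA": 50.0, "cuffB": 54.5}
        assert ecaps.discriminate_artefact(lats, dist) == "propagating"
        assert ecaps.discriminate_artefact(mus, dist) == "artefact"

    def test_single_channel_rejected(self):
        with pytest.raises(ValidationError, match="2 neural channels"):
            ecaps.discriminate_artefact({"cuffA": 2.0}, {"cuffA": 50.0})


class TestTrainInvariance:
    def test_identical_groups_zero(self):
        m = np.sin(np.linspace(0, 3, 400))
        assert ecaps.train_invariance_mape([m, m.copy()]) == 0.0

    def test_scaled_group_one_percent(self):
        m = np.sin(np.linspace(0, 3, 400)) + 2.0
        got = ecaps.train_invariance_mape([m, 1.01 * m])
        assert got == pytest.approx(1.0, abs=0.01)

    def test_symmetry_in_group_order(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1, 0.2, 300)
        b = rng.normal(1, 0.2, 300)
        assert ecaps.train_invariance_mape([a, b]) == \
            ecaps.train_invariance_mape([b, a])

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            ecaps.train_invariance_mape([np.ones(10)])


class TestDecontamination:
    def _b_drc(self, table, neurograms, sess, pw=260.0, decontaminated=False):
        cfg = EcapsConfig()
        responses = {}
        for ev in sess.events:
            if ev.pulse.pulse_width != pw or ev.train.frequency != 10.0:
                continue
            ng = neurograms[(ev.event_id, "cuffA", "cathodic")]
            w = [x for x in ecaps.fiber_windows(
                sess.geometry, "cuffA", "C1-C8", "cathodic",
                ev.pulse.current, cfg) if x.fiber_type == "B"][0]
            sl = ng.window_slice(w.latency_start, w.latency_end)
            nv = ecaps.window_noise_profile(ng, sl.start, sl.stop)
            responses[ev.pulse.current] = (ng.latency_ms[sl], ng.mean[sl], nv)
        sub = table[(table["frequency_hz"] == 10.0)]
        return ecaps.build_drc(sub, "B", "C1-C8", "cathodic", pw,
                               channel_id="cuffA", responses=responses)

    def test_decontaminated_matches_recruitment(self, default_session,
                                                default_features):
        sess, gt = default_session
        table, neurograms = default_features
        # compute_activations already decontaminates the table
        sel = table[(table["channel_id"] == "cuffA")
                    & (table["fiber"] == "B")
                    & (table["frequency_hz"] == 10.0)]
        for _, row in sel.iterrows():
            true = gt.event(row["event_id"]).recruitment[("B", "cathodic")]
            assert row["activation_norm"] == pytest.approx(true, abs=0.10)

    def test_standalone_never_negative_and_preserves_low(self,
                                                         default_session,
                                                         default_features):
        sess, _ = default_session
        table, neurograms = default_features
        raw = table[(table["channel_id"] == "cuffA")]
        drc = self._b_drc(raw, neurograms, sess)
        out = ecaps.decontaminate_b(drc)
        assert np.all(out.activations >= 0.0)
        low = drc.currents <= 0.5
        assert np.array_equal(out.activations[low], drc.activations[low])

    def test_all_below_reference_unchanged(self):
        drc = ecaps.DoseResponseCurve("B", "C1-C8", "cathodic", 260.0,
                                      np.array([0.1, 0.3, 0.5]),
                                      np.array([0.0, 1.0, 2.0]))
        out = ecaps.decontaminate_b(drc)
        assert np.array_equal(out.activations, drc.activations)

    def test_missing_reference_raises(self):
        drc = ecaps.DoseResponseCurve("B", "C1-C8", "cathodic", 260.0,
                                      np.array([1.0, 2.0]),
                                      np.array([1.0, 2.0]))
        with pytest.raises(ValidationError, match="reference"):
            ecaps.decontaminate_b(drc)


class TestBuildDrc:
    def test_point_count_and_normalization(self, recruitment_features):
        table, _ = recruitment_features
        drc = ecaps.build_drc(table, "Abeta", "C1-C8", "cathodic", 260.0,
                              channel_id="cuffA")
        assert drc.currents.size == 14
        assert np.max(drc.normalized) <= 1.0 + 1e-12
        norm = table[(table["channel_id"] == "cuffA")
                     & (table["fiber"] == "Abeta")]["activation_norm"]
        assert norm.max() == pytest.approx(1.0)

    def test_monotone_after_decontamination(self, recruitment_features,
                                            recruitment_session):
        # the measured curve tracks the generator's monotone recruitment:
        # any sag below the running maximum stays within the 5% noise
        # resolution, and every point sits within 0.1 of the true
        # recruitment fraction
        _, gt = recruitment_session
        table, _ = recruitment_features
        for fiber in ("Abeta", "Agamma", "B"):
            fspec = gt.nerve.fiber(fiber)
            for pw in (130.0, 260.0):
                drc = ecaps.build_drc(table, fiber, "C1-C8", "cathodic",
                                      pw, channel_id="cuffA")
                v = drc.activations / drc.norm_ref
                assert np.max(np.maximum.accumulate(v) - v) <= 0.05
                true = [synth.recruitment(fspec, c, pw, "C1")
                        for c in drc.currents]
                assert np.max(np.abs(v - true)) <= 0.1

    def test_mixed_pulse_widths_rejected(self, recruitment_features):
        table, _ = recruitment_features
        with pytest.raises(ValidationError, match="pulse width"):
            ecaps.build_drc(table, "Abeta", "C1-C8", "cathodic", 999.0,
                            channel_id="cuffA")


def test_twitch_amplitude_tracks_recruitment(recruitment_session):
    # EMG twitch L2-norms scale linearly with A-beta recruitment
    from ecapkit import physio as ph
    sess, gt = recruitment_session
    emg = sess.channels("emg")[0]
    amps, recs = [], []
    for ev in sess.events:
        a, _ = ph.laryngeal_twitches(emg, ev)
        amps.append(np.mean(a))
        recs.append(gt.event(ev.event_id).recruitment[("Abeta", "cathodic")])
    r = pearsonr(amps, recs).statistic
    assert r >= 0.95
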