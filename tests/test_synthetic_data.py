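"""Generator properties: chain composition, event statistics, determinism."""

import numpy as np
import pytest
from scipy import stats

import somnispike as sp
from somnispike import sleep_metrics
from somnispike.synthetic_data import (EPOCH_LEN_S, HypnogramModel,
                                       ProfileError, StrainProfile,
                                       SWDWaveformSpec, get_profile,
                                       list_profiles, simulate_ground_truth,
                                       simulate_hypnogram, simulate_recording)
from somnispike.types import ValidationError


class TestHypnogramModel:
    def test_identity_matrices_freeze_initial_state(self):
        eye = np.eye(3)
        model = HypnogramModel(lights_on=eye, lights_off=eye, initial_state="SWS")
        hyp = simulate_hypnogram(model, duration_h=1.0, seed=0)
        assert (hyp.labels == "SWS").all()

    def test_default_composition_near_targets(self):
        fracs = []
        rems = []
        for seed in range(20):
            hyp = simulate_hypnogram(HypnogramModel(), 24.0, seed)
            fracs.append((hyp.labels == "SWS").mean())
            rems.append((hyp.labels == "REM").mean())
        assert abs(np.mean(fracs) - 0.50) < 0.05
        assert abs(np.mean(rems) - 0.05) < 0.02

    def test_wake_to_rem_forbidden(self):
        P = np.array([[0.9, 0.05, 0.05], [0.1, 0.9, 0.0], [0.1, 0.1, 0.8]])
        with pytest.raises(ValidationError):
            HypnogramModel(lights_on=P, lights_off=np.eye(3))

    def test_non_stochastic_matrix_rejected(self):
        P = np.array([[0.5, 0.1, 0.0], [0.1, 0.9, 0.0], [0.1, 0.1, 0.8]])
        with pytest.raises(ValidationError):
            HypnogramModel(lights_on=P, lights_off=np.eye(3))

    def test_sleep_concentrated_in_lights_on(self):
        hyp = simulate_hypnogram(HypnogramModel(), 24.0, 7)
        on = hyp.labels[:4320]
        off = hyp.labels[4320:]
        assert (on == "SWS").mean() > (off == "SWS").mean()


class TestEventGeneration:
    def test_zero_rate_profile_yields_no_events(self):
        prof = get_profile("c57_like")
        hyp, ev = simulate_ground_truth(prof, duration_h=24, seed=0)
        assert len(ev) == 0

    def test_daily_event_count_recovers_calibration(self):
        prof = get_profile("jax_like")
        counts = [len(simulate_ground_truth(prof, duration_h=24, seed=s)[1])
                  for s in range(1, 9)]
        assert abs(np.mean(counts) - 93) / 93 < 0.15

    def test_ola_calibration(self):
        prof = get_profile("ola_like")
        counts = [len(simulate_ground_truth(prof, duration_h=24, seed=s)[1])
                  for s in range(50)]
        assert abs(np.mean(counts) - 1.5) < 0.5

    def test_event_state_shares_match_rate_time_product(self):
        """Ground-truth state shares converge to lambda_s*T_s / sum."""
        prof = get_profile("jax_like")
        counts = {s: 0 for s in sp.STATES}
        hours = {s: 0.0 for s in sp.STATES}
        for seed in range(10):
            hyp, ev = simulate_ground_truth(prof, duration_h=24, seed=seed)
            for s in sp.STATES:
                counts[s] += int((ev["state"] == s).sum())
                hours[s] += hyp.hours_in_state(s)
        total = sum(counts.values())
        expected_tot = sum(prof.state_rates[s] * hours[s] for s in sp.STATES)
        for s in sp.STATES:
            expected = prof.state_rates[s] * hours[s] / expected_tot
            assert abs(counts[s] / total - expected) < 0.03

    def test_circadian_thinning_tracks_gain(self):
        """Hour-binned realized intensity correlates with c(t)."""
        prof = get_profile("jax_like")
        hourly = np.zeros(24)
        sws_hours = np.zeros(24)
        for seed in range(25):
            hyp, ev = simulate_ground_truth(prof, duration_h=24, seed=seed)
            for z in ev.loc[ev["state"] == "SWS", "onset_zt_h"]:
                hourly[int(z)] += 1
            ep_zt = hyp.epoch_zt(np.arange(hyp.n_epochs))
            for h in range(24):
                sws_hours[h] += ((ep_zt >= h) & (ep_zt < h + 1)
                                 & (hyp.labels == "SWS")).sum() / 360.0
        rate = hourly / sws_hours
        c = prof.circadian_gain(np.arange(24) + 0.5)
        r, _ = stats.pearsonr(rate, c)
        assert r > 0.8

    def test_min_duration_satisfies_cycle_criterion(self):
        wf = SWDWaveformSpec()
        rng = np.random.default_rng(0)
        durs = [wf.sample_duration(rng) for _ in range(500)]
        assert min(durs) >= 4.0 / wf.f0_hz
        assert max(durs) <= wf.duration_max_s
        assert abs(np.mean(durs) - 2.0) < 0.15

    def test_coupling_null_when_hazard_disabled(self):
        """With hazard 1 the post-SWD transition distribution matches the
        post-clean distribution (chi-square on pooled simulated counts)."""
        prof = get_profile("jax_like")
        null = StrainProfile(name="null", daily_event_mean=prof.daily_event_mean,
                             state_rates=prof.state_rates, awakening_hazard=1.0)
        swd = np.zeros(2)
        clean = np.zeros(2)
        for seed in range(50):
            hyp, ev = simulate_ground_truth(null, duration_h=24, seed=seed)
            res = sleep_metrics.conditional_transitions(ev, hyp, n_boot=0)
            n_s, n_c = res["n_swd_epochs"], res["n_clean_epochs"]
            swd += [res["p_transition_given_swd"] * n_s,
                    (1 - res["p_transition_given_swd"]) * n_s]
            clean += [res["p_transition_given_clean"] * n_c,
                      (1 - res["p_transition_given_clean"]) * n_c]
        table = np.array([swd, clean])
        _, p, *_ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValidationError):
            simulate_ground_truth(get_profile("jax_like"), duration_h=0.0, seed=0)


class TestSignalSynthesis:
    def test_no_event_profile_lacks_waveform_energy(self):
        prof = get_profile("c57_like")
        rec, hyp, ev = simulate_recording(prof, duration_h=0.5, fs=100, seed=0)
        assert len(ev) == 0
        # the amplitude/cycle detector finds no discharge-like energy
        filt = sp.apply_acquisition_filters(
            rec, sp.FilterSpec(eeg_lp_hz=40, notch_hz=None))
        assert len(sp.detect_candidates(filt, hyp=hyp)) == 0

    def test_events_scaled_above_background(self):
        prof = get_profile("jax_like")
        rec, hyp, ev = simulate_recording(prof, duration_h=2.0, fs=100, seed=5)
        x = rec.eeg().data
        for _, e in ev.iterrows():
            i0, i1 = int(e["onset_s"] * 100), int(e["offset_s"] * 100)
            seg_peak = np.max(np.abs(x[i0:i1]))
            pre = x[max(i0 - 500, 0):i0]
            if len(pre) > 100:
                assert seg_peak > 1.5 * np.sqrt(np.mean(pre**2))

    def test_determinism_same_seed(self):
        prof = get_profile("jax_like")
        r1, h1, e1 = simulate_recording(prof, duration_h=0.5, fs=100, seed=9)
        r2, h2, e2 = simulate_recording(prof, duration_h=0.5, fs=100, seed=9)
        assert np.array_equal(r1.eeg().data, r2.eeg().data)
        assert (h1.labels == h2.labels).all()
        assert e1.equals(e2)

    def test_different_seeds_differ(self):
        prof = get_profile("jax_like")
        r1, _, e1 = simulate_recording(prof, duration_h=1.0, fs=100, seed=1)
        r2, _, e2 = simulate_recording(prof, duration_h=1.0, fs=100, seed=2)
        assert not np.array_equal(r1.eeg().data, r2.eeg().data)

    def test_emg_tone_orders_by_state(self):
        prof = get_profile("c57_like")
        rec, hyp, _ = simulate_recording(prof, duration_h=4.0, fs=100, seed=2)
        emg = rec.emg().data
        ep = int(EPOCH_LEN_S * 100)
        by_state = {}
        for s in sp.STATES:
            idx = np.flatnonzero(hyp.labels == s)
            if len(idx) == 0:
                continue
            segs = np.concatenate([emg[e * ep:(e + 1) * ep] for e in idx])
            by_state[s] = np.sqrt(np.mean(segs**2))
        assert by_state["WAKE"] > by_state["SWS"] > by_state["REM"]


class TestFixtureExport:
    def test_deterministic_csv_bytes(self, tmp_path):
        p1 = sp.export_fixture(3, "ola_like", tmp_path / "a", duration_h=0.25)
        p2 = sp.export_fixture(3, "ola_like", tmp_path / "b", duration_h=0.25)
        assert p1["hypnogram"].read_bytes() == p2["hypnogram"].read_bytes()
        assert p1["events"].read_bytes() == p2["events"].read_bytes()

    def test_unknown_profile_lists_known(self):
        with pytest.raises(ProfileError, match="jax_like"):
            get_profile("nonexistent_strain")

    def test_shipped_profiles_present(self):
        assert {"jax_like", "ola_like", "c57_like"} <= set(list_profiles())
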