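"""Generator contracts: phenotype structure, seeding, noise statistics,
paradigm bookkeeping and the on-disk epoch table."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings, strategies as st

from erpspeller import synthetic as syn
from erpspeller.montage import (CHANNELS, N_CHANNELS, N_ICONS, N_REPETITIONS,
                                N_SAMPLES, SFREQ_HZ)


def _still_profile(group=syn.GROUP_H, seed=1, **over):
    """Profile without single-trial variability, for signal-statistics tests."""
    base = syn.make_profile(group, seed)
    from dataclasses import replace
    return replace(base, latency_jitter_s=0.0, attend_rate=1.0, **over)


class TestProfiles:
    def test_h_profile_has_three_components_at_expected_latencies(self):
        prof = syn.make_profile(syn.GROUP_H, 1)
        lats = sorted(p.latency_s for p in prof.peaks)
        assert len(lats) == 3
        for lat, nominal in zip(lats, (0.30, 0.50, 0.70)):
            assert abs(lat - nominal) <= 0.02 + 1e-12

    def test_l_profile_single_broad_p700(self):
        prof = syn.make_profile(syn.GROUP_L, 1)
        assert len(prof.peaks) == 1
        assert abs(prof.peaks[0].latency_s - 0.70) <= 0.02 + 1e-12
        assert prof.peaks[0].width_s > 0.1  # broad

    def test_seed_determinism(self):
        assert syn.make_profile(syn.GROUP_H, 7) == syn.make_profile(syn.GROUP_H, 7)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group_label"):
            syn.make_profile("M-like", 0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_profile_invariants_for_any_seed(self, seed):
        for group in (syn.GROUP_H, syn.GROUP_L):
            prof = syn.make_profile(group, seed)
            for pk in prof.peaks:
                assert 0 < pk.latency_s < N_SAMPLES / SFREQ_HZ
                assert abs(max(pk.topography) - 1.0) < 1e-9
                assert pk.amplitude_uV > 0
            assert prof.noise_rms_uV > 0
            assert 0 < prof.attend_rate <= 1

    def test_dominant_latency_is_largest_amplitude_peak(self):
        prof = syn.make_profile(syn.GROUP_H, 3)
        biggest = max(prof.peaks, key=lambda p: p.amplitude_uV)
        assert syn.dominant_latency(prof) == biggest.latency_s


class TestEpochs:
    def test_epoch_determinism(self):
        prof = _still_profile()
        a = syn.simulate_epoch(prof, True, 42)
        b = syn.simulate_epoch(prof, True, 42)
        npt.assert_array_equal(a, b)

    def test_nontarget_epoch_zero_mean(self):
        prof = _still_profile()
        data = syn.simulate_epoch(prof, False, 5)
        bound = 4 * prof.noise_rms_uV / np.sqrt(N_SAMPLES)
        assert np.all(np.abs(data.mean(axis=1)) < bound)

    def test_noise_rms_per_channel(self):
        prof = _still_profile()
        data = syn.simulate_epoch(prof, False, 5)
        npt.assert_allclose(np.sqrt((data ** 2).mean(axis=1)),
                            prof.noise_rms_uV, rtol=1e-9)

    def test_target_mean_recovers_injected_amplitude(self):
        # law-of-large-numbers oracle: averaging 1000 target epochs at the
        # P300 latency on Pz approaches amplitude * gain
        prof = _still_profile(seed=2)
        p300 = min(prof.peaks, key=lambda p: p.latency_s)
        ch = CHANNELS.index("Pz")
        sample = int(round(p300.latency_s * SFREQ_HZ))
        n = 1000
        ss = np.random.SeedSequence(99)
        acc = np.zeros(N_SAMPLES)
        for child in ss.spawn(n):
            acc += syn.simulate_epoch(prof, True, np.random.default_rng(child))[ch]
        expected = sum(p.amplitude_uV * p.topography[ch]
                       * np.exp(-0.5 * ((sample / SFREQ_HZ - p.latency_s) / p.width_s) ** 2)
                       for p in prof.peaks)
        assert abs(acc[sample] / n - expected) < 3 * prof.noise_rms_uV / np.sqrt(n)

    def test_snr_scaling_with_average_size(self):
        # residual of the N-epoch average shrinks like 1/sqrt(N)
        prof = _still_profile(seed=4)
        t = np.arange(N_SAMPLES) / SFREQ_HZ
        signal = syn._erp_signal(prof.peaks, t)
        ss = np.random.SeedSequence(123)
        sizes = (25, 100, 400)
        children = iter(ss.spawn(sum(sizes)))
        residuals = []
        for n in sizes:
            acc = np.zeros((N_CHANNELS, N_SAMPLES))
            for _ in range(n):
                acc += syn.simulate_epoch(prof, True, np.random.default_rng(next(children)))
            residuals.append(np.sqrt(((acc / n - signal) ** 2).mean()))
        slope = np.polyfit(np.log(sizes), np.log(residuals), 1)[0]
        assert -0.65 < slope < -0.35


class TestSessions:
    def test_standard_session_counts(self):
        prof = _still_profile()
        eps = syn.simulate_session(prof, 12, 0)
        assert len(eps) == 12 * N_ICONS * N_REPETITIONS
        # each icon targeted exactly twice over 12 trials
        targets = {ep.trial_id: ep.icon_id for ep in eps if ep.is_target}
        assert len(targets) == 12
        counts = np.bincount(list(targets.values()), minlength=N_ICONS)
        assert list(counts) == [2] * N_ICONS

    def test_single_trial_session(self):
        eps = syn.simulate_session(_still_profile(), 1, 0)
        assert len(eps) == N_ICONS * N_REPETITIONS
        assert sum(ep.is_target for ep in eps) == N_REPETITIONS

    def test_oddball_ratio_exact(self):
        eps = syn.simulate_session(_still_profile(), 5, 3)
        assert sum(ep.is_target for ep in eps) / len(eps) == 1 / N_ICONS

    def test_target_schedules_differ_across_seeds(self):
        prof = _still_profile()
        sched = []
        for seed in (0, 1):
            eps = syn.simulate_session(prof, 12, seed)
            sched.append(tuple(sorted((ep.trial_id, ep.icon_id)
                                      for ep in eps if ep.is_target)))
        assert sched[0] != sched[1]

    def test_session_determinism_bit_identical(self):
        prof = syn.make_profile(syn.GROUP_L, 9)
        a = syn.simulate_session(prof, 2, 11)
        b = syn.simulate_session(prof, 2, 11)
        assert len(a) == len(b)
        for ea, eb in zip(a, b):
            assert (ea.trial_id, ea.icon_id, ea.repetition, ea.is_target) == \
                   (eb.trial_id, eb.icon_id, eb.repetition, eb.is_target)
            npt.assert_array_equal(ea.data, eb.data)

    def test_lapsed_trials_carry_no_erp(self):
        # attend_rate ~ 0 -> target epochs are indistinguishable from noise
        from dataclasses import replace
        prof = replace(_still_profile(syn.GROUP_L, 1), attend_rate=1e-9)
        eps = syn.simulate_session(prof, 4, 5)
        tgt = np.stack([ep.data for ep in eps if ep.is_target])
        assert abs(tgt.mean()) < 0.5  # no systematic positive deflection


class TestEpochTable:
    def test_roundtrip(self, tmp_path):
        prof = syn.make_profile(syn.GROUP_H, 5)
        eps = syn.simulate_session(prof, 1, 8, subject_id="S01", session_id=2)
        path = tmp_path / "epochs.tsv"
        syn.write_epoch_table(eps, path)
        assert path.with_suffix(".tsv.meta").exists()
        back = syn.read_epoch_table(path)
        assert len(back) == len(eps)
        orig = {(e.trial_id, e.icon_id, e.repetition): e for e in eps}
        for e in back:
            ref = orig[(e.trial_id, e.icon_id, e.repetition)]
            assert e.is_target == ref.is_target
            assert e.subject_id == "S01" and e.session_id == 2
            npt.assert_allclose(e.data, ref.data, atol=1e-4)

    def test_sidecar_channel_mismatch_rejected(self, tmp_path):
        prof = syn.make_profile(syn.GROUP_H, 5)
        eps = syn.simulate_session(prof, 1, 8)
        path = tmp_path / "epochs.tsv"
        syn.write_epoch_table(eps, path)
        meta = path.with_suffix(".tsv.meta")
        meta.write_text(meta.read_text().replace("F3,Fz", "Fz,F3"))
        with pytest.raises(ValueError, match="channel order"):
            syn.read_epoch_table(path)
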