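"""Synthetic cohort generator: RR model, waveform channels, outcomes."""

import numpy as np
import pandas as pd
import pytest

from physiophen.cohort import (ArchetypeSpec, CohortConfig, DEFAULT_ARCHETYPES,
                               DEFAULT_MIXTURE, PPGMorphology, RRModelParams,
                               generate_cohort, generate_rr_series, load_cohort,
                               rr_from_params, save_cohort, synthesize_ecg,
                               synthesize_ppg, synthesize_resp)
from physiophen.interpreter import compute_hrv, detect_r_peaks, denoise
from physiophen.types import WaveformRecord


class TestRRSeries:
    def test_degenerate_model_is_constant(self):
        """No modulation, no jitter at 60 bpm -> constant 1000 ms tachogram."""
        params = RRModelParams(base_ms=1000.0, jitter_sd=0.0, lf_amp=0.0,
                               hf_amp=0.0, jump_prob=0.0, jump_mag=0.0)
        rr = rr_from_params(params, 120.0, seed=0)
        assert np.allclose(rr, 1000.0)
        hrv = compute_hrv(rr)
        assert hrv["SDNN"] == 0.0 and hrv["pNN50"] == 0.0

    def test_covers_duration_and_floor(self):
        for name, spec in DEFAULT_ARCHETYPES.items():
            rr = generate_rr_series(spec, 300.0, seed=3)
            assert rr.sum() >= 300.0 * 1000.0
            assert (rr > 200.0).all()

    def test_seed_determinism(self):
        spec = DEFAULT_ARCHETYPES["SP3"]
        a = generate_rr_series(spec, 300.0, seed=11)
        b = generate_rr_series(spec, 300.0, seed=11)
        assert np.array_equal(a, b)
        c = generate_rr_series(spec, 300.0, seed=12)
        assert not np.array_equal(a, c)

    def test_duration_precondition(self):
        with pytest.raises(ValueError):
            generate_rr_series(DEFAULT_ARCHETYPES["SP1"], 30.0, seed=0)

    def test_sp1_sdnn_recovered_within_25pct(self):
        """The extractor-computed SDNN of the low-variability archetype
        lands within 25% of its 9.28 ms target (median over 20 seeds)."""
        spec = DEFAULT_ARCHETYPES["SP1"]
        sdnn = [compute_hrv(generate_rr_series(spec, 300.0, s))["SDNN"]
                for s in range(20)]
        med = float(np.median(sdnn))
        assert abs(med - spec.sdnn_target) / spec.sdnn_target < 0.25

    def test_archetype_ordering_round_trip(self):
        """Cohort-median extracted statistics keep the planted ordering:
        SDNN SP3 > SP2 > SP1 and pNN50 highest in SP4 (20-seed majority)."""
        wins_sdnn = 0
        wins_pnn = 0
        for s in range(20):
            med = {}
            for name, spec in DEFAULT_ARCHETYPES.items():
                med[name] = compute_hrv(generate_rr_series(spec, 300.0, s))
            if med["SP3"]["SDNN"] > med["SP2"]["SDNN"] > med["SP1"]["SDNN"]:
                wins_sdnn += 1
            if med["SP4"]["pNN50"] == max(m["pNN50"] for m in med.values()):
                wins_pnn += 1
        assert wins_sdnn > 10
        assert wins_pnn > 10

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            ArchetypeSpec(id="X", hr_mean=80, sdnn_target=np.nan, rmssd_target=10,
                          pnn50_target=5, lfhf_target=1, rr_skew_target=0,
                          rr_irregularity="mid", ppg_ac_skew_target=0,
                          ppg_morphology=PPGMorphology(), resp_rate=16,
                          mortality_28d=0.2, shock_probs=(0.1, 0.2, 0.3),
                          vp_probs=(0.1, 0.2, 0.3), mv_probs=(0.1, 0.2, 0.3),
                          covariate_probs=(0.3, 0.3, 0.3))
        from physiophen.cohort import calibrate_rr_model
        with pytest.raises(ValueError):
            spec = DEFAULT_ARCHETYPES["SP1"]
            bad = ArchetypeSpec(**{**spec.__dict__, "pnn50_target": 150.0})


class TestECG:
    def test_clean_beats_count_and_spacing(self):
        """10 beats at RR=1000 ms -> exactly 10 prominent maxima, 1000 +/- 4 ms."""
        rr = np.full(10, 1000.0)
        ch = synthesize_ecg(rr, 250.0)
        x = ch.samples
        r_amp = x.max()
        # local maxima above half the R amplitude
        mask = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]) & (x[1:-1] > 0.5 * r_amp)
        peaks = np.flatnonzero(mask) + 1
        assert len(peaks) == 10
        spacing = np.diff(peaks) / 250.0 * 1000.0
        assert np.all(np.abs(spacing - 1000.0) <= 4.0)

    def test_zero_modulation_constant_amplitude(self):
        rr = np.full(20, 800.0)
        phase = np.linspace(0, 20 * np.pi, int(250 * 17))
        ch = synthesize_ecg(rr, 250.0, resp_phase=phase, modulation_depth=0.0)
        rp = detect_r_peaks(ch)
        amps = ch.samples[rp]
        assert np.ptp(amps) < 1e-6 * np.abs(amps).max() + 1e-9

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            synthesize_ecg(np.full(10, 1000.0), 80.0)

    def test_r_jitter_grows_as_snr_falls(self):
        """Median absolute R-timing error increases monotonically with noise."""
        rr = np.full(120, 800.0)
        truth = np.cumsum(rr) / 1000.0
        errs = []
        for snr in (30.0, 10.0, 2.0):
            per_seed = []
            for seed in range(5):
                ch = synthesize_ecg(rr, 250.0, seed=seed, snr_db=snr)
                rec = denoise(WaveformRecord(channels={"ecg": ch}))
                rp = detect_r_peaks(rec["ecg"]) / 250.0
                d = np.abs(truth[:, None] - rp[None, :]).min(axis=1)
                per_seed.append(np.median(d))
            errs.append(np.median(per_seed))
        assert errs[0] <= errs[1] <= errs[2]


class TestPPG:
    def test_pulse_count_matches_beats(self, clean_record):
        from physiophen.interpreter import delineate, derive_signals

        der = derive_signals(clean_record, np.array([], dtype=int))
        fid = delineate(clean_record, der)
        # one pulse per beat; the final pulse has no following onset
        assert len(fid.ppg_pulses) in (59, 60)

    def test_notch_prominence_guard(self):
        with pytest.raises(ValueError):
            synthesize_ppg(np.full(10, 1000.0),
                           PPGMorphology(notch_prominence=1.5), 125.0)

    def test_symmetric_amplitudes_near_zero_skew(self):
        """|sample skewness| < 0.2 at n=500 for a symmetric AC distribution
        (median over seeds)."""
        from scipy.stats import skew

        morph = PPGMorphology(ac_skew=0.0)
        sk = []
        for seed in range(7):
            from physiophen.cohort.waveforms import _skewed_amplitudes
            amps = _skewed_amplitudes(np.random.default_rng(seed), 500,
                                      morph.ac_mean, morph.ac_sd, morph.ac_skew)
            sk.append(abs(skew(amps)))
        assert np.median(sk) < 0.2

    def test_skew_target_direction(self):
        from scipy.stats import skew
        from physiophen.cohort.waveforms import _skewed_amplitudes

        rng = np.random.default_rng(0)
        neg = _skewed_amplitudes(rng, 4000, 0.37, 0.05, -1.3)
        pos = _skewed_amplitudes(np.random.default_rng(1), 4000, 0.37, 0.05, 1.3)
        assert skew(neg) < -0.7 and skew(pos) > 0.7


class TestResp:
    def test_exact_cycle_count_without_jitter(self):
        ch = synthesize_resp(15.0, 62.5, 60.0, seed=0, period_jitter=0.0)
        x = ch.samples - ch.samples.mean()
        upcross = np.sum((x[:-1] < 0) & (x[1:] >= 0))
        assert upcross == 15

    def test_spectral_peak_at_rate(self):
        from scipy.signal import periodogram

        ch = synthesize_resp(15.0, 62.5, 120.0, seed=1, period_jitter=0.02)
        f, p = periodogram(ch.samples - ch.samples.mean(), fs=62.5)
        assert abs(f[np.argmax(p)] - 0.25) < 0.02

    def test_zero_jitter_equal_cycles(self):
        ch = synthesize_resp(12.0, 62.5, 60.0, seed=0, period_jitter=0.0)
        x = ch.samples - ch.samples.mean()
        ups = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
        assert np.ptp(np.diff(ups)) <= 1  # sample quantization only

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            synthesize_resp(3.0, 62.5, 60.0)


class TestCohort:
    @pytest.fixture(scope="class")
    def small_bundle(self):
        return generate_cohort(CohortConfig(n_patients=60, seed=1))

    def test_empty_cohort(self):
        bundle = generate_cohort(CohortConfig(n_patients=0, seed=0))
        assert bundle.patients == [] and len(bundle.metadata) == 0

    def test_metadata_determinism(self):
        a = generate_cohort(CohortConfig(n_patients=5, seed=9)).metadata
        b = generate_cohort(CohortConfig(n_patients=5, seed=9)).metadata
        pd.testing.assert_frame_equal(a, b)

    def test_archetype_counts_within_3sd(self):
        """Multinomial membership counts stay within 3 binomial SDs."""
        bundle = generate_cohort(CohortConfig(n_patients=400, seed=2,
                                              duration_s=60.0))
        counts = bundle.metadata["archetype"].value_counts()
        for w, name in zip(DEFAULT_MIXTURE, DEFAULT_ARCHETYPES):
            exp = 400 * w
            sd = np.sqrt(400 * w * (1 - w))
            assert abs(counts.get(name, 0) - exp) <= 3 * sd

    def test_zero_mortality_all_censored(self):
        arch = {k: ArchetypeSpec(**{**v.__dict__, "mortality_28d": 0.0})
                for k, v in DEFAULT_ARCHETYPES.items()}
        bundle = generate_cohort(CohortConfig(n_patients=20, seed=3,
                                              duration_s=60.0, archetypes=arch))
        assert (bundle.metadata["death_event"] == 0).all()
        assert (bundle.metadata["death_time"] == 28.0).all()

    def test_flags_monotone(self, small_bundle):
        m = small_bundle.metadata
        for out in ("ss", "vp", "mv"):
            assert (m[f"{out}2"] <= m[f"{out}7"]).all()
            assert (m[f"{out}7"] <= m[f"{out}28"]).all()

    def test_death_times_in_range(self, small_bundle):
        t = small_bundle.metadata["death_time"]
        assert ((t > 0) & (t <= 28.0)).all()

    def test_channels_finite_with_metadata(self, small_bundle):
        pat = small_bundle.patients[0]
        for name, ch in pat.waveforms.channels.items():
            assert np.isfinite(ch.samples).all()
            assert ch.fs == small_bundle.config.fs[name]

    def test_save_load_roundtrip(self, tmp_path):
        bundle = generate_cohort(CohortConfig(n_patients=3, seed=4,
                                              duration_s=60.0))
        save_cohort(bundle, tmp_path / "cohort")
        records, meta = load_cohort(tmp_path / "cohort")
        pd.testing.assert_frame_equal(meta, bundle.metadata)
        orig = bundle.patients[0].waveforms["ecg"].samples
        assert np.allclose(records[0]["ecg"].samples, orig, atol=1e-4)

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=5, mixture_weights=(0.5, 0.5, 0.2, 0.1))
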