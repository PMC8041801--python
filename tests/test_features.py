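import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyskest.features import (
    FEATURE_NAMES_13,
    FEATURE_NAMES_78,
    N_FEATURES,
    Spectrum,
    axis_features,
    extract_window_features,
    feature_relevance,
    psd,
    spectral_features,
    temporal_features,
)
from dyskest.preprocess import RoundSequence, Window

from oracles import (
    axis_features_oracle,
    entropy_oracle,
    gini_oracle,
    kurtosis_oracle,
    skew_oracle,
    std_oracle,
    welch_oracle,
)


def _win(wrist, ankle, **kw):
    defaults = dict(subject_id="S01", round_index=1, activity="walking",
                    start_s=0.0, medication_state="ON", gold=2.0)
    defaults.update(kw)
    return Window(wrist=wrist, ankle=ankle, **defaults)


def _tone(freq, fs=64.0, n=320, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestPsd:
    def test_pure_tone_peak_within_one_bin(self):
        spec = psd(_tone(3.0))
        df = spec.freqs[1] - spec.freqs[0]
        assert abs(spec.freqs[np.argmax(spec.power)] - 3.0) <= df

    def test_zero_signal_zero_power(self):
        spec = psd(np.zeros(320))
        assert not np.any(spec.power)

    def test_parseval_white_noise(self):
        # integral of the PSD approximates the variance (averaged over seeds)
        ratios = []
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(320)
            spec = psd(x)
            ratios.append(np.trapezoid(spec.power, spec.freqs) / np.var(x))
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_parseval_tone(self):
        x = _tone(5.0)
        spec = psd(x)
        assert abs(np.trapezoid(spec.power, spec.freqs) - np.var(x)) / np.var(x) < 0.05

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="320"):
            psd(np.zeros(100))

    def test_matches_first_principles_welch(self, rng):
        x = rng.normal(0, 30, 320)
        spec = psd(x)
        freqs, power = welch_oracle(x)
        assert np.allclose(spec.freqs, freqs, atol=1e-12)
        assert np.allclose(spec.power, power, rtol=1e-9, atol=1e-12)


class TestTemporal:
    def test_constant_vector_degenerates_to_zero(self):
        assert np.array_equal(temporal_features(np.full(320, 3.3)), np.zeros(6))

    def test_peak_to_peak(self):
        x = np.tile([-3.0, 5.0], 160)
        assert temporal_features(x)[5] == 8.0

    def test_entropy_matches_histogram_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(0, 20, 320)
            assert abs(temporal_features(x)[0] - entropy_oracle(x)) < 1e-9

    def test_gini_matches_mean_difference_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(0, 20, 320)
            assert abs(temporal_features(x)[1] - gini_oracle(x)) < 1e-9

    def test_moments_match_oracles(self, rng):
        x = rng.gamma(2.0, 5.0, 320)
        f = temporal_features(x)
        assert abs(f[2] - std_oracle(x)) < 1e-9
        assert abs(f[3] - skew_oracle(x)) < 1e-9
        assert abs(f[4] - kurtosis_oracle(x)) < 1e-9

    def test_gini_in_unit_interval_and_std_nonneg(self, rng):
        for _ in range(20):
            f = temporal_features(rng.standard_t(3, 320))
            assert 0.0 <= f[1] <= 1.0
            assert f[0] >= 0.0 and f[2] >= 0.0 and f[5] >= 0.0


class TestSpectral:
    def test_tone_in_dyskinesia_band_dominates(self):
        f = spectral_features(psd(_tone(2.0)))
        assert f[1] / f[0] > 0.95

    def test_8hz_tone_dominant_and_concentrated(self):
        spec = psd(_tone(8.0))
        f = spectral_features(spec)
        df = spec.freqs[1] - spec.freqs[0]
        assert abs(f[3] - 8.0) <= df
        assert f[2] < 0.3  # low spectral entropy

    def test_white_noise_entropy_near_one(self):
        ents = [
            spectral_features(psd(np.random.default_rng(s).standard_normal(320)))[2]
            for s in range(100)
        ]
        assert np.mean(ents) > 0.9

    def test_all_zero_spectrum_conventions(self):
        spec = Spectrum(freqs=np.linspace(0, 32, 65), power=np.zeros(65))
        f = spectral_features(spec)
        assert np.array_equal(f, [0.0, 0.0, 0.0, 0.5, 0.0, 0.5, 0.0])

    def test_invariants_on_random_windows(self, rng):
        for _ in range(20):
            f = spectral_features(psd(rng.normal(0, 10, 320)))
            assert 0.0 <= f[1] <= f[0] + 1e-12
            assert 0.0 <= f[2] <= 1.0
            assert 0.5 <= f[3] <= 15.0 and 0.5 <= f[5] <= 15.0
            assert f[4] >= f[6]


class TestWindowDescriptor:
    def test_length_78_and_13_per_axis(self, rng):
        w = _win(rng.normal(0, 10, (3, 320)), rng.normal(0, 10, (3, 320)))
        assert extract_window_features(w).shape == (78,)
        assert len(FEATURE_NAMES_13) == 13
        assert len(FEATURE_NAMES_78) == N_FEATURES == 78

    def test_deterministic(self, rng):
        w = _win(rng.normal(0, 10, (3, 320)), rng.normal(0, 10, (3, 320)))
        assert np.array_equal(extract_window_features(w), extract_window_features(w))

    def test_zero_window_degenerate_conventions(self):
        fv = extract_window_features(_win(np.zeros((3, 320)), np.zeros((3, 320))))
        fv = fv.reshape(6, 13)
        assert np.array_equal(fv[:, :9], np.zeros((6, 9)))
        assert np.array_equal(fv[:, 9], np.full(6, 0.5))   # f_dom at band edge
        assert np.array_equal(fv[:, 11], np.full(6, 0.5))  # f_dom2 at band edge

    def test_ordering_is_sensor_major_axis_major(self, rng):
        wrist = rng.normal(0, 10, (3, 320))
        ankle = rng.normal(0, 10, (3, 320))
        fv = extract_window_features(_win(wrist, ankle))
        assert np.allclose(fv[:13], axis_features(wrist[0]), atol=1e-12)
        assert np.allclose(fv[39:52], axis_features(ankle[0]), atol=1e-12)
        assert FEATURE_NAMES_78[0] == "wrist_x_shannon_entropy"
        assert FEATURE_NAMES_78[39] == "ankle_x_shannon_entropy"

    def test_batch_path_matches_per_window_path(self, tiny_sequences):
        seq = max(tiny_sequences, key=lambda s: s.n_windows)
        per = np.vstack([extract_window_features(w) for w in seq.windows])
        assert np.allclose(seq.features, per, rtol=1e-9, atol=1e-9)

    def test_time_reversal_invariance(self, rng):
        # no feature is direction-sensitive: temporal features are exactly
        # invariant; the Welch PSD uses a periodic taper, so spectral
        # features are invariant only up to the one-sample taper shift
        wrist = rng.normal(0, 10, (3, 320))
        ankle = rng.normal(0, 10, (3, 320))
        a = extract_window_features(_win(wrist, ankle)).reshape(6, 13)
        b = extract_window_features(
            _win(np.ascontiguousarray(wrist[:, ::-1]),
                 np.ascontiguousarray(ankle[:, ::-1]))
        ).reshape(6, 13)
        assert np.allclose(a[:, :6], b[:, :6], rtol=1e-9, atol=1e-9)
        assert np.allclose(a[:, 6:], b[:, 6:], rtol=0.05, atol=1e-9)

    def test_scaling_behaviour(self, rng):
        x = rng.normal(0, 10, 320)
        f1 = axis_features(x)
        f2 = axis_features(2.0 * x)
        assert np.isclose(f2[2], 2 * f1[2])          # std doubles
        assert np.isclose(f2[5], 2 * f1[5])          # peak-to-peak doubles
        assert np.isclose(f2[6], 4 * f1[6])          # band powers quadruple
        assert np.isclose(f2[7], 4 * f1[7])
        assert np.isclose(f2[1], f1[1])              # Gini is scale-free
        assert np.isclose(f2[0], f1[0])              # histogram entropy too


class TestOracleEquivalence:
    def test_all_13_features_match_brute_force(self, rng):
        """Each per-axis feature equals its independent implementation on a
        batch of random windows spanning several signal families."""
        for k in range(60):
            fam = k % 3
            if fam == 0:
                x = rng.normal(0, 25, 320)
            elif fam == 1:
                x = _tone(rng.uniform(0.5, 15), amp=rng.uniform(1, 40)) + rng.normal(0, 2, 320)
            else:
                x = rng.gamma(1.5, 10, 320) - 15
            got = axis_features(x)
            want = axis_features_oracle(x)
            assert np.allclose(got, want, rtol=1e-9, atol=1e-9), FEATURE_NAMES_13[
                int(np.argmax(np.abs(got - want)))
            ]


def _fake_seq(subject, round_index, golds, feature_value=None):
    """A featurized round whose features are constant per window."""
    windows = [
        Window(subject, round_index, "walking", 5.0 * k, "ON", g,
               np.zeros((3, 320)), np.zeros((3, 320)))
        for k, g in enumerate(golds)
    ]
    seq = RoundSequence(subject, round_index, "ON", windows)
    vals = golds if feature_value is None else feature_value
    seq.features = np.tile(np.asarray(vals, dtype=float)[:, None], (1, 78))
    return seq


class TestFeatureRelevance:
    def test_feature_equal_to_gold_gives_r_one(self):
        seqs = [_fake_seq("S1", 1, [1.0, 1.0]), _fake_seq("S1", 2, [5.0, 5.0]),
                _fake_seq("S2", 1, [9.0, 9.0]), _fake_seq("S2", 2, [3.0, 3.0])]
        table = feature_relevance(seqs)
        assert len(table) == 26  # 13 per sensor
        assert np.allclose(table["r"], 1.0)

    def test_feature_equal_to_negative_gold_gives_r_minus_one(self):
        seqs = [
            _fake_seq("S1", r, [g], feature_value=[-g])
            for r, g in enumerate([1.0, 5.0, 9.0, 3.0], start=1)
        ]
        table = feature_relevance(seqs)
        assert np.allclose(table["r"], -1.0)

    def test_zero_variance_feature_flagged_not_nan_crash(self):
        seqs = [_fake_seq("S1", r, [g], feature_value=[2.0]) for r, g in
                enumerate([1.0, 5.0, 9.0], start=1)]
        table = feature_relevance(seqs)
        assert table["r"].isna().all()
        assert (table["note"] == "zero variance").all()

    def test_requires_three_rounds(self):
        with pytest.raises(ValueError, match="3"):
            feature_relevance([_fake_seq("S1", 1, [1.0])])

    def test_synthetic_cohort_wrist_band_power_is_informative(self, tiny_sequences):
        table = feature_relevance(tiny_sequences).set_index(["sensor", "feature"])
        assert table.loc[("wrist", "power_1_4"), "r"] > 0.5


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_temporal_features_finite_on_arbitrary_windows(seed):
    x = np.random.default_rng(seed).standard_t(2, 320) * 10
    assert np.all(np.isfinite(temporal_features(x)))
    assert np.all(np.isfinite(axis_features(x)))
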