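"""Feature extraction: PSD estimation oracles, band averaging, asymmetry,
time-domain statistics, the 344-column layout and the min-max scaler."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegaug.channels import (
    ASYM_BANDS,
    BAND_BY_NAME,
    BANDS,
    CHANNEL_INDEX,
    CHANNELS_32,
    HOMOLOGOUS_PAIRS,
)
from eegaug.features import (
    FeatureScaler,
    ResolutionError,
    WelchParams,
    asymmetry_features,
    band_average_psd,
    compute_psd,
    extract_features,
    feature_names,
    psd_features,
    time_domain_features,
    zero_crossing_count,
)

FS = 128.0


def tone(freq: float, seconds: float = 60.0, amp: float = 1.0) -> np.ndarray:
    t = np.arange(int(seconds * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


class TestComputePsd:
    def test_zero_signal(self):
        est = compute_psd(np.zeros(7680), FS)
        assert np.all(est.psd == 0)

    def test_sinusoid_power_closed_form(self):
        """A unit sinusoid carries power A^2/2 = 0.5; the Welch integral
        recovers it and the spectral peak sits at the tone frequency."""
        est = compute_psd(tone(10.0), FS)
        df = est.freqs[1] - est.freqs[0]
        assert est.psd.sum() * df == pytest.approx(0.5, rel=0.05)
        assert est.freqs[np.argmax(est.psd)] == pytest.approx(10.0, abs=df / 2)

    def test_white_noise_parseval(self):
        x = 1.7 * np.random.default_rng(0).standard_normal(7680)
        est = compute_psd(x, FS)
        df = est.freqs[1] - est.freqs[0]
        assert est.psd.sum() * df == pytest.approx(x.var(), rel=0.10)

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            compute_psd(np.zeros(64), FS)


class TestBandAverage:
    def test_zero_spectrum(self):
        est = compute_psd(np.zeros(7680), FS)
        for band in BANDS:
            assert band_average_psd(est, band) == 0

    def test_band_confinement(self):
        est = compute_psd(tone(6.0), FS)
        theta = band_average_psd(est, BAND_BY_NAME["theta"])
        alpha = band_average_psd(est, BAND_BY_NAME["alpha"])
        assert theta / max(alpha, 1e-300) > 100

    def test_flat_density_constant(self):
        est = compute_psd(np.zeros(7680), FS)
        est.psd = np.full_like(est.psd, 3.25)
        for band in BANDS:
            assert band_average_psd(est, band) == pytest.approx(3.25)

    def test_empty_band_resolution_error(self):
        est = compute_psd(np.zeros(7680), FS)
        from eegaug.channels import BandDef

        with pytest.raises(ResolutionError):
            band_average_psd(est, BandDef("sliver", 8.2, 8.4))


class TestPsdFeatures:
    def test_length_and_zero_trial(self):
        vec = psd_features(np.zeros((32, 7680)), FS)
        assert vec.shape == (160,)
        assert np.all(vec == 0)

    def test_single_channel_tone_is_localised(self):
        trial = np.zeros((32, 7680))
        trial[CHANNEL_INDEX["Fp1"]] = tone(6.0)
        vec = psd_features(trial, FS)
        names = [f"psd_{ch}_{b.name}" for ch in CHANNELS_32 for b in BANDS]
        target = vec[names.index("psd_Fp1_theta")]
        others = np.delete(vec, names.index("psd_Fp1_theta"))
        assert target > 0
        assert np.all(others < 0.01 * target)

    def test_channel_count_checked(self):
        with pytest.raises(Exception):
            psd_features(np.zeros((30, 7680)), FS)


class TestAsymmetry:
    def test_symmetric_trial_is_zero(self):
        rng = np.random.default_rng(1)
        trial = np.zeros((32, 7680))
        base = rng.standard_normal(7680)
        for r, l in HOMOLOGOUS_PAIRS:
            trial[CHANNEL_INDEX[r]] = base
            trial[CHANNEL_INDEX[l]] = base
        vec = asymmetry_features(trial, FS)
        assert vec.shape == (56,)
        np.testing.assert_array_equal(vec, 0.0)

    def test_right_alpha_tone(self):
        trial = np.zeros((32, 7680))
        trial[CHANNEL_INDEX["Fp2"]] = tone(10.0)
        vec = asymmetry_features(trial, FS)
        idx = {(p, b.name): i for i, (p, b) in enumerate(
            [(pair, band) for pair in HOMOLOGOUS_PAIRS for band in ASYM_BANDS]
        )}
        alpha_val = vec[idx[(("Fp2", "Fp1"), "alpha")]]
        assert alpha_val > 0
        for bname in ("theta", "beta", "gamma"):
            assert abs(vec[idx[(("Fp2", "Fp1"), bname)]]) < 0.01 * alpha_val

    def test_pair_swap_negates(self):
        rng = np.random.default_rng(5)
        trial = rng.standard_normal((32, 7680))
        swapped = trial.copy()
        for r, l in HOMOLOGOUS_PAIRS:
            swapped[[CHANNEL_INDEX[r], CHANNEL_INDEX[l]]] = (
                swapped[[CHANNEL_INDEX[l], CHANNEL_INDEX[r]]]
            )
        np.testing.assert_allclose(
            asymmetry_features(swapped, FS), -asymmetry_features(trial, FS),
            atol=1e-12,
        )


def brute_force_zcr(x) -> int:
    signs = [v for v in np.sign(x) if v != 0]
    return sum(1 for a, b in zip(signs, signs[1:]) if a != b)


class TestZeroCrossing:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([3.0, 2.0, 1.0], 0),
            ([1.0, -1.0, 1.0, -1.0], 3),
            ([1.0, 0.0, -1.0], 1),
            ([0.0, 0.0, 0.0], 0),
            ([-1.0, 0.0, -1.0, 2.0], 1),
        ],
    )
    def test_examples(self, x, expected):
        assert zero_crossing_count(np.array(x)) == expected

    def test_length_guard(self):
        with pytest.raises(ValueError):
            zero_crossing_count(np.array([1.0]))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.integers(min_value=-3, max_value=3), min_size=2, max_size=60))
    def test_matches_brute_force(self, values):
        x = np.array(values, dtype=float)
        assert zero_crossing_count(x) == brute_force_zcr(x)


class TestTimeDomain:
    def test_constant_channels(self):
        vec = time_domain_features(np.full((32, 100), 2.5))
        assert vec.shape == (128,)
        np.testing.assert_allclose(vec.reshape(32, 4), [[2.5, 0.0, 0.0, 0.0]] * 32)

    def test_alternating_channel(self):
        trial = np.zeros((32, 7680))
        trial[3] = np.tile([1.0, -1.0], 3840)
        stats = time_domain_features(trial).reshape(32, 4)
        assert stats[3, 0] == pytest.approx(0.0)          # mean
        assert stats[3, 1] == pytest.approx(1.0)          # variance
        assert stats[3, 2] == 7679                        # zero crossings
        assert stats[3, 3] == pytest.approx(2.0)          # mean |diff|

    def test_three_statistic_mode(self):
        vec = time_domain_features(
            np.zeros((32, 100)), statistics=("mean", "variance", "zcr")
        )
        assert vec.shape == (96,)


class TestExtractAll:
    def test_single_trial_layout(self):
        feats = extract_features(np.zeros((32, 7680)), FS, segment_s=None)
        assert feats.shape == (1, 344)
        assert list(feats.columns) == feature_names()
        names = feats.columns
        assert sum(n.startswith("psd_") for n in names) == 160
        assert sum(n.startswith("asym_") for n in names) == 56
        assert sum(n.startswith("td_") for n in names) == 128

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        trials = rng.standard_normal((6, 32, 512))
        perm = rng.permutation(6)
        a = extract_features(trials, FS, segment_s=None)
        b = extract_features(trials[perm], FS, segment_s=None)
        np.testing.assert_allclose(
            a.to_numpy()[perm], b.to_numpy(), rtol=1e-12, atol=1e-12
        )

    def test_segment_trimming_uses_tail(self):
        rng = np.random.default_rng(9)
        tail = rng.standard_normal((1, 32, 512))
        padded = np.concatenate(
            [100.0 * np.ones((1, 32, 128)), tail], axis=-1
        )
        a = extract_features(padded, FS, segment_s=4.0)
        b = extract_features(tail, FS, segment_s=None)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)


class TestScaler:
    def test_affine_map(self):
        train = pd.DataFrame({"a": [2.0, 3.0, 4.0]})
        scaler = FeatureScaler().fit(train)
        np.testing.assert_allclose(
            scaler.transform(train).ravel(), [-1.0, 0.0, 1.0]
        )

    def test_round_trip(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((30, 6)))
        scaler = FeatureScaler().fit(X)
        back = scaler.inverse_transform(scaler.transform(X))
        np.testing.assert_allclose(back, X.to_numpy(), atol=1e-9)

    def test_constant_column(self):
        X = pd.DataFrame({"c": [5.0, 5.0, 5.0], "v": [0.0, 1.0, 2.0]})
        scaler = FeatureScaler().fit(X)
        z = scaler.transform(X)
        np.testing.assert_array_equal(z[:, 0], 0.0)
        back = scaler.inverse_transform(z)
        np.testing.assert_allclose(back[:, 0], 5.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            FeatureScaler().fit(pd.DataFrame({"a": [1.0, np.nan]}))
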