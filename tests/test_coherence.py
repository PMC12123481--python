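import numpy as np
import pytest

from synchrospread.clean import clean_field
from synchrospread.coherence import (
    LONG_BAND,
    SHORT_BAND,
    Band,
    band_test,
    index_band_coherence,
    make_surrogates,
    spatial_coherence,
)
from synchrospread.fields import SpatioTemporalField
from synchrospread.wavelet import ScaleGrid, cwt_many

from conftest import make_field


def cleaned(values):
    f = make_field(values)
    out, _ = clean_field(f)
    return out


class TestBand:
    def test_defaults(self):
        assert SHORT_BAND.lower == 2.0 and SHORT_BAND.upper == 4.0
        assert LONG_BAND.lower == 4.0 and np.isinf(LONG_BAND.upper)

    def test_half_open(self):
        periods = np.array([2.0, 3.9, 4.0, 8.0])
        np.testing.assert_array_equal(
            SHORT_BAND.member_mask(periods), [True, True, False, False]
        )

    def test_invalid(self):
        with pytest.raises(ValueError):
            Band("bad", 5.0, 3.0)


class TestSpatialCoherence:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal((6, 31))
        wf = cwt_many(x, ScaleGrid.for_length(31))
        coh = spatial_coherence(wf, wf)
        valid = np.isfinite(coh)
        np.testing.assert_allclose(np.abs(coh[valid]), 1.0, atol=1e-10)
        np.testing.assert_allclose(np.angle(coh[valid]), 0.0, atol=1e-10)

    def test_antiphase(self, rng):
        x = rng.standard_normal((6, 31))
        g = ScaleGrid.for_length(31)
        coh = spatial_coherence(cwt_many(x, g), cwt_many(-x, g))
        coh = coh[np.isfinite(coh)]
        np.testing.assert_allclose(np.abs(np.angle(coh)), np.pi, atol=1e-10)

    def test_modulus_bounded(self, rng):
        g = ScaleGrid.for_length(31)
        for seed in range(5):
            r = np.random.default_rng(seed)
            coh = spatial_coherence(
                cwt_many(r.standard_normal((5, 31)), g),
                cwt_many(r.standard_normal((5, 31)), g),
            )
            assert np.nanmax(np.abs(coh)) <= 1.0 + 1e-10

    def test_quarter_cycle_phase(self, rng):
        # y delayed 1 year at period 4 => response x leads => arg ~ +pi/2
        t = np.arange(31)
        x = np.tile(np.sin(2 * np.pi * t / 4.0), (8, 1))
        y = np.tile(np.sin(2 * np.pi * (t - 1.0) / 4.0), (8, 1))
        x = x + 0.01 * rng.standard_normal(x.shape)
        y = y + 0.01 * rng.standard_normal(y.shape)
        g = ScaleGrid.for_length(31)
        coh = spatial_coherence(cwt_many(x, g), cwt_many(y, g))
        i4 = np.argmin(np.abs(g.periods - 4.0))
        assert np.angle(coh[i4]) == pytest.approx(np.pi / 2, abs=0.15)


class TestSurrogates:
    def test_periodogram_preserved_exactly(self, rng):
        for T in (30, 31):  # even and odd lengths
            X = rng.standard_normal((4, T))
            ens = make_surrogates(X, n_surrog=5, seed=0)
            pg = np.abs(np.fft.rfft(X, axis=-1)) ** 2
            for s in ens.data:
                np.testing.assert_allclose(
                    np.abs(np.fft.rfft(s, axis=-1)) ** 2, pg, rtol=1e-8, atol=1e-8
                )

    def test_cross_spectra_preserved(self, rng):
        X = rng.standard_normal((5, 31))
        ens = make_surrogates(X, n_surrog=4, sync_preserving=True, seed=1)
        F = np.fft.rfft(X, axis=-1)
        cross = F[0] * np.conj(F[1])
        for s in ens.data:
            Fs = np.fft.rfft(s, axis=-1)
            np.testing.assert_allclose(Fs[0] * np.conj(Fs[1]), cross, atol=1e-8)

    def test_mean_preserved(self, rng):
        X = rng.standard_normal((3, 31)) + 5.0
        ens = make_surrogates(X, n_surrog=50, seed=2)
        np.testing.assert_allclose(
            ens.data.mean(axis=2), np.tile(X.mean(axis=1), (50, 1)), atol=1e-8
        )

    def test_aaft_preserves_amplitude_distribution(self, rng):
        X = rng.exponential(size=(3, 31))
        ens = make_surrogates(X, n_surrog=3, method="aaft", seed=3)
        for s in ens.data:
            np.testing.assert_allclose(np.sort(s, axis=1), np.sort(X, axis=1), atol=1e-10)

    def test_constant_row_error(self):
        with pytest.raises(ValueError, match="constant"):
            make_surrogates(np.ones((2, 31)), n_surrog=1, seed=0)

    def test_reproducible(self, rng):
        X = rng.standard_normal((3, 31))
        a = make_surrogates(X, n_surrog=3, seed=9).data
        b = make_surrogates(X, n_surrog=3, seed=9).data
        np.testing.assert_array_equal(a, b)


class TestBandTest:
    def test_self_test_minimal_p(self, rng):
        x = cleaned(rng.standard_normal((10, 31)))
        res = band_test(x, x, SHORT_BAND, n_surrog=100, seed=0)
        assert res.p_value == pytest.approx(1.0 / 101.0)
        assert res.theta_bar == pytest.approx(0.0, abs=1e-9)

    def test_coupled_fields_detected(self, rng):
        t = np.arange(31)
        common = np.sin(2 * np.pi * t / 3.0)
        x = cleaned(common + 0.3 * rng.standard_normal((10, 31)))
        y = cleaned(common + 0.3 * rng.standard_normal((10, 31)))
        res = band_test(x, y, SHORT_BAND, n_surrog=200, seed=1)
        assert res.p_value < 0.1

    def test_loose_null_calibration(self):
        # cheap version of the full calibration acceptance criterion
        rej = 0
        reps = 60
        for seed in range(reps):
            r = np.random.default_rng(seed)
            x = cleaned(r.standard_normal((8, 31)))
            y = cleaned(r.standard_normal((8, 31)))
            res = band_test(x, y, SHORT_BAND, n_surrog=60, seed=seed)
            rej += res.p_value < 0.1
        assert 0 <= rej / reps < 0.3

    def test_theta_antisymmetry(self, rng):
        x = cleaned(rng.standard_normal((6, 31)))
        y = cleaned(rng.standard_normal((6, 31)))
        a = band_test(x, y, LONG_BAND, n_surrog=0)
        b = band_test(y, x, LONG_BAND, n_surrog=0)
        assert a.theta_bar == pytest.approx(-b.theta_bar, abs=1e-10)

    def test_location_relabeling_invariance(self, rng):
        x = rng.standard_normal((6, 31))
        y = rng.standard_normal((6, 31))
        perm = np.random.default_rng(0).permutation(6)
        a = band_test(cleaned(x), cleaned(y), SHORT_BAND, n_surrog=0)
        b = band_test(cleaned(x[perm]), cleaned(y[perm]), SHORT_BAND, n_surrog=0)
        assert a.stat == pytest.approx(b.stat, abs=1e-10)

    def test_empty_band_error(self, rng):
        x = cleaned(rng.standard_normal((5, 31)))
        with pytest.raises(ValueError, match="band"):
            band_test(x, x, Band("none", 50.0, 60.0), n_surrog=0)

    def test_mod_mean_statistic_flag(self, rng):
        x = cleaned(rng.standard_normal((5, 31)))
        y = cleaned(rng.standard_normal((5, 31)))
        a = band_test(x, y, SHORT_BAND, n_surrog=0, band_stat="mean_mod")
        b = band_test(x, y, SHORT_BAND, n_surrog=0, band_stat="mod_mean")
        assert b.stat <= a.stat + 1e-12  # triangle inequality


class TestIndexBandCoherence:
    def test_identical_index(self, rng):
        idx = np.sin(2 * np.pi * np.arange(31) / 5.0) + 0.1 * rng.standard_normal(31)
        field = cleaned(np.tile(idx, (8, 1)) + 0.01 * rng.standard_normal((8, 31)))
        from synchrospread.clean import clean_series

        idx_c, _ = clean_series(idx)
        res = index_band_coherence(field, idx_c, LONG_BAND, n_surrog=100, seed=0)
        assert res.p_value == pytest.approx(1.0 / 101.0)
        assert abs(res.theta_bar) < 0.1

    def test_delayed_field_negative_phase(self, rng):
        # field = index delayed 1 yr at period 4 => predictor leads => theta ~ -0.5
        t = np.arange(31)
        idx = np.sin(2 * np.pi * t / 4.0)
        field = cleaned(
            np.tile(np.sin(2 * np.pi * (t - 1.0) / 4.0), (8, 1))
            + 0.01 * rng.standard_normal((8, 31))
        )
        from synchrospread.clean import clean_series

        idx_c, _ = clean_series(idx + 0.01 * rng.standard_normal(31))
        res = index_band_coherence(
            field, idx_c, Band("p4", 3.2, 5.0), n_surrog=0, seed=0
        )
        assert res.theta_bar == pytest.approx(-0.5, abs=0.07)

    def test_length_mismatch(self, rng):
        field = cleaned(rng.standard_normal((5, 31)))
        with pytest.raises(ValueError, match="index"):
            index_band_coherence(field, np.zeros(10), SHORT_BAND, n_surrog=0)
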