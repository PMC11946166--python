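import numpy as np
import pytest

from opusnirs.montage import ChannelDef, Montage, Optode
from opusnirs.preprocess import (
    ConcSeries,
    MbllParams,
    ODSeries,
    bandpass,
    block_average,
    default_mbll_params,
    detect_bad_channels,
    intensity_to_od,
    od_to_conc,
)
from opusnirs.recording import Recording


@pytest.fixture
def two_wl_montage():
    return Montage(
        [Optode("S1", "source", (0, 0, 0)), Optode("D1", "detector", (30, 0, 0))],
        [ChannelDef("S1", "D1", 762.0), ChannelDef("S1", "D1", 842.0)],
    )


def _recording(montage, intensity, fs=75.0):
    return Recording(montage, fs, intensity)


class TestIntensityToOd:
    def test_constant_channel_gives_zero(self, two_wl_montage):
        I = np.full((750, 2), 3.7)
        od = intensity_to_od(_recording(two_wl_montage, I))
        assert np.allclose(od.data, 0.0)

    def test_scale_invariance(self, two_wl_montage, rng):
        I = np.exp(rng.normal(0, 0.05, (750, 2)))
        od1 = intensity_to_od(_recording(two_wl_montage, I))
        od2 = intensity_to_od(_recording(two_wl_montage, 10.0 * I))
        assert np.allclose(od1.data, od2.data, atol=1e-12)

    def test_log_attenuation_recovered(self, two_wl_montage, rng):
        """I = I0*exp(-a(t)) with zero-mean a(t) gives dOD = a(t)."""
        n = 1500
        a = rng.normal(0, 0.02, (n, 2))
        a -= a.mean(axis=0, keepdims=True)
        I = 2.5 * np.exp(-a)
        od = intensity_to_od(_recording(two_wl_montage, I))
        # reference is mean intensity, not exp(mean log); correct to 2nd order
        assert np.allclose(od.data, a, atol=1e-3)
        a_exact = a.copy()
        I2 = 2.5 * np.exp(-a_exact)
        od2 = -np.log(I2 / I2.mean(axis=0, keepdims=True))
        assert np.allclose(od.data, od2, atol=1e-12)


class TestDetectBadChannels:
    def test_flat_channel_flagged(self, two_wl_montage):
        I = np.exp(np.random.default_rng(0).normal(0, 0.01, (1500, 2)))
        I[:, 1] = 2.0  # dead channel
        mask = detect_bad_channels(_recording(two_wl_montage, I))
        assert 1 in mask.flagged
        assert mask.criteria.loc[1, "reason"] == "flat"

    def test_clean_channels_not_flagged_at_generator_noise(self, two_wl_montage, rng):
        from opusnirs.synth import GroundTruth

        sd = GroundTruth().noise_od_sd
        I = np.exp(-rng.normal(0, sd, (7500, 2)))
        mask = detect_bad_channels(_recording(two_wl_montage, I))
        assert mask.flagged == set()

    def test_square_wave_dropouts_flagged_by_cv(self, two_wl_montage, rng):
        I = np.exp(rng.normal(0, 0.01, (1500, 2)))
        # 50% amplitude square-wave dropouts on channel 0
        I[::2, 0] *= 0.5
        cv = I[:, 0].std() / I[:, 0].mean()
        assert cv > 0.15  # oracle: direct CV computation
        mask = detect_bad_channels(_recording(two_wl_montage, I))
        assert 0 in mask.flagged
        assert mask.criteria.loc[0, "reason"] == "cv"

    def test_short_data_rejected(self, two_wl_montage):
        I = np.ones((300, 2))
        with pytest.raises(ValueError, match="10 s"):
            detect_bad_channels(_recording(two_wl_montage, I))


class TestBandpass:
    def _sine_od(self, montage, freq, fs=75.0, n=75 * 120):
        t = np.arange(n) / fs
        data = np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, 2))
        return ODSeries(data, fs, montage)

    def test_passband_gain_near_unity(self, two_wl_montage):
        od = self._sine_od(two_wl_montage, 0.1)
        out = bandpass(od)
        core = slice(75 * 20, -75 * 20)  # avoid filter edge transients
        gain = out.data[core, 0].std() / od.data[core, 0].std()
        assert gain == pytest.approx(1.0, abs=0.05)

    def test_cardiac_band_attenuated(self, two_wl_montage):
        od = self._sine_od(two_wl_montage, 1.2)
        out = bandpass(od)
        core = slice(75 * 20, -75 * 20)
        assert out.data[core, 0].std() < od.data[core, 0].std() / 10

    def test_zero_signal_maps_to_zero(self, two_wl_montage):
        od = ODSeries(np.zeros((7500, 2)), 75.0, two_wl_montage)
        assert np.allclose(bandpass(od).data, 0.0)

    def test_zero_phase_at_passband_center(self, two_wl_montage):
        od = self._sine_od(two_wl_montage, 0.1)
        out = bandpass(od)
        core = slice(75 * 30, 75 * 90)
        lag = np.argmax(
            np.correlate(out.data[core, 0], od.data[core, 0], "full")
        ) - (core.stop - core.start - 1)
        assert abs(lag) <= 1  # samples

    def test_invalid_band_rejected(self, two_wl_montage):
        od = ODSeries(np.zeros((750, 2)), 75.0, two_wl_montage)
        with pytest.raises(ValueError, match="invalid band"):
            bandpass(od, 0.5, 0.1)


class TestMbll:
    def test_zero_od_gives_zero_conc(self, two_wl_montage):
        od = ODSeries(np.zeros((100, 2)), 75.0, two_wl_montage)
        conc = od_to_conc(od)
        assert np.allclose(conc.hbo, 0) and np.allclose(conc.hbr, 0)

    def test_forward_inverse_roundtrip(self, two_wl_montage):
        """Known (dHbO, dHbR) = (1, -0.5) uM*mm forward-projected through the
        extinction matrix inverts to the same values."""
        params = default_mbll_params()
        hbo_true, hbr_true = 1.0e-6, -0.5e-6
        n = 100
        data = np.empty((n, 2))
        for j, wl in enumerate(two_wl_montage.wavelengths):
            e_hbo, e_hbr = params.extinction[wl]
            data[:, j] = e_hbo * hbo_true + e_hbr * hbr_true
        conc = od_to_conc(ODSeries(data, 75.0, two_wl_montage), params)
        assert np.allclose(conc.hbo, hbo_true, atol=1e-15)
        assert np.allclose(conc.hbr, hbr_true, atol=1e-15)

    def test_wavelength_roles(self, two_wl_montage):
        """An isolated OD increase at 762 nm moves HbR more than HbO:
        the shorter wavelength is deoxy-dominant."""
        data = np.zeros((10, 2))
        data[:, 0] = 1e-4  # 762 nm channel only
        conc = od_to_conc(ODSeries(data, 75.0, two_wl_montage))
        assert np.abs(conc.hbr[0, 0]) > np.abs(conc.hbo[0, 0])

    def test_linearity(self, two_wl_montage, rng):
        data = rng.normal(0, 1e-4, (50, 2))
        c1 = od_to_conc(ODSeries(data, 75.0, two_wl_montage))
        c2 = od_to_conc(ODSeries(2 * data, 75.0, two_wl_montage))
        assert np.allclose(c2.hbo, 2 * c1.hbo)
        assert np.allclose(c2.hbr, 2 * c1.hbr)

    def test_hbt_conservation(self, two_wl_montage, rng):
        data = rng.normal(0, 1e-4, (50, 2))
        conc = od_to_conc(ODSeries(data, 75.0, two_wl_montage))
        assert np.allclose(conc.hbt, conc.hbo + conc.hbr, atol=1e-12)

    def test_singular_extinction_rejected(self, two_wl_montage):
        params = MbllParams(extinction={762.0: (1.0, 2.0), 842.0: (2.0, 4.0)})
        od = ODSeries(np.zeros((10, 2)), 75.0, two_wl_montage)
        with pytest.raises(ValueError, match="singular"):
            od_to_conc(od, params)

    def test_zero_distance_rejected_when_scaling(self):
        m = Montage(
            [Optode("S1", "source", (0, 0, 0)), Optode("D1", "detector", (0, 0, 0))],
            [ChannelDef("S1", "D1", 762.0), ChannelDef("S1", "D1", 842.0)],
        )
        params = MbllParams(extinction=default_mbll_params().extinction,
                            scale_by_pathlength=True)
        od = ODSeries(np.ones((10, 2)) * 1e-4, 75.0, m)
        with pytest.raises(ValueError, match="distance"):
            od_to_conc(od, params)


class TestBlockAverage:
    def _conc(self, n_t, n_pairs=2, fs=75.0, data=None):
        if data is None:
            data = np.zeros((n_t, n_pairs))
        return ConcSeries(data, 0.5 * data, fs, [("S", f"D{i}") for i in range(n_pairs)])

    def test_single_epoch_unchanged(self, rng):
        data = rng.normal(0, 1, (750, 2))
        conc = self._conc(750, data=data)
        out = block_average(conc, [(0.0, 10.0)])
        assert np.allclose(out["hbo"], data)

    def test_identical_epochs_average_to_one_epoch(self):
        seg = np.sin(np.linspace(0, 2 * np.pi, 150))[:, None] * np.ones((1, 2))
        data = np.tile(seg, (4, 1))
        conc = self._conc(600, data=data)
        out = block_average(conc, [(i * 2.0, (i + 1) * 2.0) for i in range(4)])
        assert np.allclose(out["hbo"], seg)

    def test_noise_shrinks_as_sqrt_n(self, rng):
        """RMS error of the epoch mean vs truth scales ~ sigma/sqrt(n)."""
        fs, sigma, n_rep = 25.0, 1.0, 50
        hrf_len = int(10 * fs)
        truth = np.sin(np.linspace(0, np.pi, hrf_len))
        for n_ep, tol in ((4, 0.3), (16, 0.3)):
            errs = []
            for _ in range(n_rep):
                data = np.tile(truth[:, None], (n_ep, 1)) + rng.normal(
                    0, sigma, (n_ep * hrf_len, 1)
                )
                conc = ConcSeries(data, 0 * data, fs, [("S", "D")])
                out = block_average(
                    conc, [(i * 10.0, (i + 1) * 10.0) for i in range(n_ep)]
                )
                errs.append(np.sqrt(np.mean((out["hbo"][:, 0] - truth) ** 2)))
            expected = sigma / np.sqrt(n_ep)
            assert np.mean(errs) == pytest.approx(expected, rel=tol)

    def test_epoch_out_of_range_names_epoch(self):
        conc = self._conc(750)
        with pytest.raises(ValueError, match=r"\[5.0, 15.0\)"):
            block_average(conc, [(0.0, 10.0), (5.0, 15.0)])

    def test_unequal_epochs_rejected(self):
        conc = self._conc(750)
        with pytest.raises(ValueError, match="equal"):
            block_average(conc, [(0.0, 2.0), (2.0, 5.0)])
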