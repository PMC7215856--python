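"""End-to-end pipeline: masking, standard FT, denoising, T2* separation."""

import numpy as np
import pytest

from fiddec import (
    FID,
    STFTConfig,
    FIDDeconvolver,
    SyntheticLineSpec,
    denoise,
    istft,
    make_fid,
    separate_t2,
    soft_mask,
    standard_ft,
    stft,
    to_log,
)
from fiddec.deconvolution import DeconvolutionConfig, window_for_percent

from conftest import spectral_correlation


def random_fid(n, seed, dwell=1e-4):
    rng = np.random.default_rng(seed)
    return FID(rng.normal(size=n) + 1j * rng.normal(size=n), dwell=dwell)


class TestStandardFT:
    def test_zero_fid_gives_zero_spectrum(self):
        spec = standard_ft(FID(np.zeros(512, complex), 1e-3))
        assert np.all(spec.intensities == 0)
        assert np.all(np.diff(spec.frequency_axis) > 0)

    def test_single_line_peak_position_and_width(self):
        line = SyntheticLineSpec(1.0, 250.0, 0.0, 0.1)
        truth = make_fid([line], 8192, 1e-4, 0.0, 0)
        spec = standard_ft(truth.clean_fid, zero_fill=65536)
        real = np.real(spec.intensities)
        peak_freq = spec.frequency_axis[np.argmax(real)]
        bin_width = spec.frequency_axis[1] - spec.frequency_axis[0]
        assert abs(peak_freq - 250.0) <= bin_width
        half = real.max() / 2
        above = spec.frequency_axis[real >= half]
        expected_fwhm = 1.0 / (np.pi * 0.1)
        assert abs((above.max() - above.min()) - expected_fwhm) <= expected_fwhm * 0.1 + 2 * bin_width

    def test_parseval_energy_identity(self):
        fid = random_fid(1000, 3)
        n = 2048
        spec = standard_ft(fid, zero_fill=n)
        x = fid.samples.copy()
        x[0] *= 0.5  # first-point convention is part of the transform
        assert np.sum(np.abs(spec.intensities) ** 2) == pytest.approx(
            n * np.sum(np.abs(x) ** 2), rel=1e-8
        )

    def test_ppm_axis_attached_when_frequency_known(self):
        fid = FID(np.ones(512, complex), 1e-4, spectrometer_freq=700.0)
        spec = standard_ft(fid)
        np.testing.assert_allclose(spec.ppm_axis, spec.frequency_axis / 700.0)

    def test_zero_fill_below_length_rejected(self):
        with pytest.raises(ValueError, match="zero_fill"):
            standard_ft(random_fid(1000, 0), zero_fill=512)


class TestSoftMask:
    def _spec(self, n=1024, seed=0):
        return stft(random_fid(n, seed), STFTConfig(128, hop=64))

    def test_single_label_returns_original(self):
        spec = self._spec()
        V = to_log(np.abs(spec.values))
        out = soft_mask(spec, {"signal": V})
        np.testing.assert_allclose(out["signal"].values, spec.values, atol=1e-12)

    def test_equal_labels_split_in_half(self):
        spec = self._spec()
        V = to_log(np.abs(spec.values))
        out = soft_mask(spec, {"a": V, "b": V})
        np.testing.assert_allclose(out["a"].values, spec.values / 2, atol=1e-12)
        np.testing.assert_allclose(out["b"].values, spec.values / 2, atol=1e-12)

    def test_components_overlap_add_to_original(self):
        spec = self._spec()
        rng = np.random.default_rng(5)
        Va = np.abs(rng.normal(size=spec.values.shape))
        Vb = np.abs(rng.normal(size=spec.values.shape))
        out = soft_mask(spec, {"a": Va, "b": Vb})
        total = istft(out["a"]).samples + istft(out["b"]).samples
        np.testing.assert_allclose(total, istft(spec).samples, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        spec = self._spec()
        with pytest.raises(ValueError, match="shape"):
            soft_mask(spec, {"a": np.zeros((2, 2))})


class TestDenoise:
    def test_component_fids_conserve_original(self, sucrose_truth, sucrose_result):
        total = sum(f.samples for f in sucrose_result.component_fids.values())
        err = np.max(np.abs(total - sucrose_truth.noisy_fid.samples))
        assert err <= 1e-6 * np.max(np.abs(sucrose_truth.noisy_fid.samples))

    def test_component_spectra_conserve_original(self, sucrose_result):
        total = sum(s.intensities for s in sucrose_result.component_spectra.values())
        ref = sucrose_result.original_spectrum.intensities
        assert np.max(np.abs(total - ref)) <= 1e-6 * np.max(np.abs(ref))

    def test_denoising_improves_snr(self, sucrose_result):
        assert sucrose_result.snr_report.relative_snr >= 3.0

    def test_denoised_spectrum_matches_clean(
        self, sucrose_result, sucrose_clean_spectrum
    ):
        c = spectral_correlation(
            sucrose_result.component_spectra["signal"], sucrose_clean_spectrum
        )
        assert c >= 0.95

    def test_time_equivalent_factor_is_squared_ratio(self, sucrose_result):
        rep = sucrose_result.snr_report
        assert rep.time_equivalent_factor == pytest.approx(rep.relative_snr**2, rel=1e-12)

    def test_noise_free_input_passes_through(self):
        base = make_fid(
            [
                SyntheticLineSpec(1.0, 400.0, 0.0, 0.3),
                SyntheticLineSpec(0.5, -900.0, 0.0, 0.15),
            ],
            16384,
            1e-4,
            0.0,
            seed=2,
        )
        res = denoise(base.noisy_fid, window_size=512, seed=2)
        c = spectral_correlation(
            res.component_spectra["signal"], res.original_spectrum
        )
        assert c > 0.99

    def test_deterministic_given_seed(self, sucrose_truth, sucrose_result):
        again = denoise(
            sucrose_truth.noisy_fid,
            window_size=1024,
            variant="psmf",
            reassign_initial_segments=1,
            seed=0,
        )
        np.testing.assert_array_equal(
            again.component_fids["signal"].samples,
            sucrose_result.component_fids["signal"].samples,
        )

    def test_full_length_window_degenerates_to_plain_ft(self, sucrose_truth):
        # one segment: the transform reduces to a standard FT and there
        # is nothing to separate, so the relative SNR stays at 1
        res = denoise(
            sucrose_truth.noisy_fid,
            window_size=33280,
            hop=16640,
            boundary=False,
            seed=0,
        )
        assert "degenerate" in res.provenance
        assert 0.8 <= res.snr_report.relative_snr <= 1.3

    def test_relative_snr_never_below_one_across_noise_levels(self):
        lines = [
            SyntheticLineSpec(1.0, 700.0, 0.0, 0.4),
            SyntheticLineSpec(0.8, -1500.0, 0.0, 0.2),
            SyntheticLineSpec(1.3, 2100.0, 0.0, 0.6),
        ]
        for sigma in (0.05, 0.5, 5.0):
            truth = make_fid(lines, 16384, 1e-4, sigma, seed=11)
            res = denoise(truth.noisy_fid, window_size=512, seed=11)
            assert res.snr_report.relative_snr >= 1.0

    def test_non_decaying_signal_raises_with_window_guidance(self):
        # a persistent tone never decays within the record: every
        # component is flat and the error should point at the window size
        tone = make_fid(
            [SyntheticLineSpec(1.0, 500.0, 0.0, 1e6)], 8192, 1e-4, 0.0, seed=4
        )
        with pytest.raises(ValueError, match="window"):
            denoise(tone.noisy_fid, window_size=512, seed=4)


class TestSeparateT2:
    def test_components_conserve_original(self, diffusion_truth, diffusion_result):
        total = sum(f.samples for f in diffusion_result.component_fids.values())
        err = np.max(np.abs(total - diffusion_truth.noisy_fid.samples))
        assert err <= 1e-6 * np.max(np.abs(diffusion_truth.noisy_fid.samples))

    def test_long_and_short_match_their_ground_truth(
        self, diffusion_truth, diffusion_result
    ):
        long_ref = standard_ft(diffusion_truth.clean_subset(lambda l: l.t2_star > 0.05))
        short_ref = standard_ft(diffusion_truth.clean_subset(lambda l: l.t2_star <= 0.05))
        assert spectral_correlation(diffusion_result.component_spectra["long_t2"], long_ref) >= 0.9
        assert spectral_correlation(diffusion_result.component_spectra["short_t2"], short_ref) >= 0.9

    def test_provenance_records_paper_time_width(self, diffusion_result):
        assert diffusion_result.provenance["window_percent"] == 6.3
        assert diffusion_result.provenance["rank"] == 3

    def test_all_long_input_leaves_short_component_small(self):
        lines = [
            SyntheticLineSpec(1.0, f, 0.0, t2)
            for f, t2 in [(300.0, 0.4), (-800.0, 0.25), (1500.0, 0.6)]
        ]
        truth = make_fid(lines, 8192, 1.0 / 8000.0, 0.2, seed=9)
        res = separate_t2(truth.noisy_fid, window_size=512, seed=9)
        short_e = np.sum(np.abs(res.component_spectra["short_t2"].intensities) ** 2)
        signal_e = short_e + np.sum(
            np.abs(res.component_spectra["long_t2"].intensities) ** 2
        )
        assert short_e < 0.10 * signal_e


class TestConfigPlumbing:
    @pytest.mark.parametrize(
        "percent,length,expected",
        [(3.1, 33280, 1024), (6.3, 8192, 512), (12.5, 8192, 1024)],
    )
    def test_window_for_percent_matches_paper_choices(self, percent, length, expected):
        assert window_for_percent(percent, length) == expected

    def test_profile_construction(self):
        cfg = DeconvolutionConfig.from_profile("diffusion-edit")
        assert cfg.rank == 3
        assert cfg.percent == 6.3
        with pytest.raises(ValueError, match="profile"):
            DeconvolutionConfig.from_profile("nope")

    def test_estimator_get_params(self):
        est = FIDDeconvolver(window_size=256, variant="nmf")
        params = est.get_params()
        assert params["window_size"] == 256
        clone = FIDDeconvolver().set_params(**params)
        assert clone.get_params() == params

    def test_invalid_mode_and_rank(self):
        fid = random_fid(2048, 0)
        with pytest.raises(ValueError, match="mode"):
            FIDDeconvolver(mode="magic").fit(fid)
        with pytest.raises(ValueError, match="rank"):
            FIDDeconvolver(mode="t2_separation", rank=2).fit(fid)
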