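"""The synthetic-spectra generator: seeded reproducibility, truncated-normal
concentration moments, linear mixing, and the distortion model."""

import numpy as np
import pytest
from scipy import stats

from nirpls import (
    AnalyteParams,
    SyntheticConfig,
    distort_and_replicate,
    generate,
    render_spectrum,
    sample_concentrations,
    snv,
)
from nirpls.synthetic import (
    DEFAULT_ANALYTE_PARAMS,
    background_spectrum,
    pure_spectra,
)


def truncnorm_moments(p: AnalyteParams):
    """Closed-form truncated-normal mean/SD (independent oracle)."""
    a, b = (p.minimum - p.mean) / p.sd, (p.maximum - p.mean) / p.sd
    mean, var = stats.truncnorm.stats(a, b, loc=p.mean, scale=p.sd, moments="mv")
    return float(mean), float(np.sqrt(var))


class TestConfig:
    def test_default_grid_is_176_channels(self):
        wl = SyntheticConfig().wavelengths
        assert wl.size == 176
        assert wl[0] == 950.0 and wl[-1] == 1650.0
        np.testing.assert_allclose(np.diff(wl), 4.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 1},
            {"step_nm": 0.0},
            {"noise_sd": -0.1},
            {"analyte_params": {"total_CBD": AnalyteParams(5, 1, 0, 10)}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)

    def test_band_centres_must_lie_on_grid_range(self):
        from nirpls import GaussianBand

        lib = {k: v for k, v in SyntheticConfig().band_library.items()}
        lib["total_CBD"] = (GaussianBand(2000.0, 30.0, 0.01),)
        with pytest.raises(ValueError, match="outside"):
            SyntheticConfig(band_library=lib)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SyntheticConfig(n_samples=25, seed=9, noise_sd=0.002)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SyntheticConfig.from_yaml(path) == cfg


class TestSampleConcentrations:
    def test_seeded_reproducibility(self):
        cfg = SyntheticConfig(n_samples=100, seed=3)
        a = sample_concentrations(cfg)
        b = sample_concentrations(cfg)
        assert a.equals(b)

    def test_zero_sd_degenerates_to_mean(self):
        params = {
            k: AnalyteParams(p.mean, 0.0, p.minimum, p.maximum)
            for k, p in DEFAULT_ANALYTE_PARAMS.items()
        }
        cfg = SyntheticConfig(n_samples=10, analyte_params=params)
        df = sample_concentrations(cfg)
        for k, p in params.items():
            np.testing.assert_array_equal(df[k], p.mean)

    def test_moments_match_truncated_normal_oracle(self):
        # means/SDs within 10% of the truncation-adjusted targets at n=2000
        cfg = SyntheticConfig(n_samples=2000, seed=5)
        df = sample_concentrations(cfg)
        for name, p in cfg.analyte_params.items():
            mean, sd = truncnorm_moments(p)
            assert df[name].mean() == pytest.approx(mean, rel=0.10)
            assert df[name].std(ddof=1) == pytest.approx(sd, rel=0.10)

    def test_bounds_respected(self):
        cfg = SyntheticConfig(n_samples=500, seed=8)
        df = sample_concentrations(cfg)
        for name, p in cfg.analyte_params.items():
            assert df[name].between(p.minimum, p.maximum).all()

    def test_infeasible_truncation_raises(self):
        # an admissible window a million times narrower than the SD rejects
        # essentially every draw, so the sampler must give up loudly
        params = dict(DEFAULT_ANALYTE_PARAMS)
        params["total_CBD"] = AnalyteParams(0.0, 1000.0, 0.0, 1e-3)
        from nirpls import GaussianBand

        lib = dict(SyntheticConfig().band_library)
        cfg = SyntheticConfig(n_samples=50, analyte_params=params,
                              band_library=lib)
        with pytest.raises(RuntimeError, match="rejection"):
            sample_concentrations(cfg)


class TestRenderSpectrum:
    def test_zero_concentrations_give_background(self):
        cfg = SyntheticConfig()
        conc = {a: 0.0 for a in cfg.analytes}
        np.testing.assert_array_equal(
            render_spectrum(conc, cfg), background_spectrum(cfg)
        )

    def test_linearity_and_additivity(self, rng):
        cfg = SyntheticConfig()
        bg = background_spectrum(cfg)
        c1 = {a: rng.uniform(0, 10) for a in cfg.analytes}
        c2 = {a: rng.uniform(0, 10) for a in cfg.analytes}
        double = {a: 2 * v for a, v in c1.items()}
        np.testing.assert_allclose(
            render_spectrum(double, cfg) - bg,
            2 * (render_spectrum(c1, cfg) - bg),
            atol=1e-12,
        )
        csum = {a: c1[a] + c2[a] for a in cfg.analytes}
        np.testing.assert_allclose(
            render_spectrum(csum, cfg),
            render_spectrum(c1, cfg) + render_spectrum(c2, cfg) - bg,
            atol=1e-12,
        )


class TestDistortAndReplicate:
    def test_no_distortion_reproduces_clean(self):
        cfg = SyntheticConfig(
            baseline_offset_sd=0.0, scatter_log_sd=0.0, noise_sd=0.0
        )
        clean = background_spectrum(cfg)
        scans, offs, scat = distort_and_replicate(clean, cfg)
        assert scans.shape == (10, clean.size)
        np.testing.assert_array_equal(scans, np.tile(clean, (10, 1)))
        np.testing.assert_array_equal(offs, 0.0)
        np.testing.assert_array_equal(scat, 1.0)

    def test_snv_removes_noiseless_distortion(self, rng):
        # SNV of a scatter/offset-distorted scan equals SNV of the clean
        # spectrum (affine invariance of the distortion model)
        cfg = SyntheticConfig(noise_sd=0.0, scatter_log_sd=0.3,
                              baseline_offset_sd=0.1, seed=2)
        conc = {a: rng.uniform(0, 5) for a in cfg.analytes}
        clean = render_spectrum(conc, cfg)
        scans, _, _ = distort_and_replicate(clean, cfg)
        for scan in scans:
            np.testing.assert_allclose(snv(scan), snv(clean), atol=1e-9)

    def test_distortion_log_matches_scans(self):
        cfg = SyntheticConfig(noise_sd=0.0, seed=4)
        clean = background_spectrum(cfg)
        scans, offs, scat = distort_and_replicate(clean, cfg)
        recon = scat[:, None] * clean[None, :] + offs[:, None]
        np.testing.assert_allclose(scans, recon, atol=1e-12)


class TestGenerate:
    def test_shapes_and_id_alignment(self, small_dataset):
        ds = small_dataset
        assert ds.spectra.values.shape == (60, 10, 176)
        assert ds.spectra.samples == ds.reference.samples
        assert len(ds.distortion_log) == 600

    def test_reference_totals_within_bounds(self, small_dataset):
        for name, p in small_dataset.config.analyte_params.items():
            col = small_dataset.reference.column(name)
            assert np.all(col >= p.minimum) and np.all(col <= p.maximum)

    def test_bit_identical_under_same_seed(self):
        cfg = SyntheticConfig(n_samples=12, seed=99)
        a, b = generate(cfg), generate(cfg)
        np.testing.assert_array_equal(a.spectra.values, b.spectra.values)
        assert a.reference.data.equals(b.reference.data)
        assert a.distortion_log.equals(b.distortion_log)

    def test_different_seeds_differ(self):
        a = generate(SyntheticConfig(n_samples=12, seed=1))
        b = generate(SyntheticConfig(n_samples=12, seed=2))
        assert not np.array_equal(a.spectra.values, b.spectra.values)

    def test_minimal_two_sample_dataset(self):
        ds = generate(SyntheticConfig(n_samples=2, n_replicates=1, seed=0))
        assert ds.spectra.values.shape == (2, 1, 176)

    def test_scan_equals_logged_distortion_of_clean_mix(self, small_dataset):
        # reconstruct scan 0 of sample 0 from the logged ground truth
        ds = small_dataset
        cfg = ds.config
        totals = {a: ds.reference.column(a)[0] for a in cfg.analytes}
        clean = render_spectrum(totals, cfg)
        row = ds.distortion_log.iloc[0]
        recon = row.scatter * clean + row.offset
        resid = ds.spectra.values[0, 0] - recon
        # what remains is the white noise term
        assert np.abs(resid).max() < 6 * cfg.noise_sd
        assert np.std(resid) == pytest.approx(cfg.noise_sd, rel=0.3)

    def test_replicate_mean_noise_reduced_sqrt10(self):
        # channel noise SD of the 10-scan average ~ noise_sd / sqrt(10),
        # estimated over 100 samples x 10 scans with distortions off
        cfg = SyntheticConfig(
            n_samples=100, seed=6, baseline_offset_sd=0.0, scatter_log_sd=0.0,
            noise_sd=0.01,
        )
        ds = generate(cfg)
        totals = np.column_stack([ds.reference.column(a) for a in cfg.analytes])
        clean = totals @ pure_spectra(cfg).to_numpy().T + background_spectrum(cfg)
        resid = ds.spectra.values.mean(axis=1) - clean
        assert np.std(resid) == pytest.approx(0.01 / np.sqrt(10), rel=0.05)
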