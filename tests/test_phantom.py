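"""Phantom generator: geometry, signal model, noise, cohort sampling."""

import numpy as np
import pytest

from uspio_t2star import (
    PhantomSpec,
    inject_blooming,
    make_phantom,
    normal_values,
    sample_cohort,
    simulate_multiecho,
)
from uspio_t2star.phantom import Shape, add_rician_noise, decay_signal


@pytest.fixture(scope="module")
def myo_spec():
    return PhantomSpec(tissue_r2star={"panmyocardium": 33.5, "blood": 11.3},
                       image_size=(64, 64), seed=42)


class TestMakePhantom:
    def test_truth_map_carries_assigned_r2star(self, myo_spec):
        truth = make_phantom(myo_spec)
        myo = truth.mask("panmyocardium")
        assert myo.sum() > 0
        assert np.all(truth.r2star[myo] == 33.5)
        assert np.all(truth.r2star[truth.mask("blood")] == 11.3)

    def test_background_has_zero_s0_and_label(self, myo_spec):
        truth = make_phantom(myo_spec)
        bg = truth.labels == 0
        assert bg.any()
        assert np.all(truth.s0[bg] == 0.0)
        assert np.all(truth.r2star[bg] == 0.0)

    def test_overlapping_masks_rejected_naming_tissues(self):
        geom = {"liver": Shape("ellipse", (30, 30), 10, 12),
                "spleen": Shape("ellipse", (32, 34), 8, 10)}
        spec = PhantomSpec(tissue_r2star={"liver": 36.0, "spleen": 22.0},
                           image_size=(64, 64), tissue_geometry=geom)
        with pytest.raises(ValueError, match="liver|spleen"):
            make_phantom(spec)

    def test_default_geometry_masks_disjoint(self):
        spec = PhantomSpec(tissue_r2star={t: p.r2star_pre_mean
                                          for t, p in normal_values(1.5).items()})
        truth = make_phantom(spec)  # would raise on any collision
        n_tissue = sum(truth.mask(t).sum() for t in spec.tissue_r2star)
        assert n_tissue == (truth.labels > 0).sum()


class TestSimulateMultiecho:
    def test_noiseless_closed_form(self):
        # S0=1000, R2*=100 s^-1, TE=10 ms -> 1000/e
        val = decay_signal(1000.0, 100.0, np.array([10.0]))[0]
        assert val == pytest.approx(1000.0 * np.exp(-1.0), rel=1e-12)

    def test_pure_noise_mean_is_rayleigh(self):
        # S=0 magnitude noise has mean sigma*sqrt(pi/2)
        rng = np.random.default_rng(7)
        sigma = 5.0
        draws = add_rician_noise(np.zeros(200_000), sigma, rng)
        expected = sigma * np.sqrt(np.pi / 2.0)
        se = sigma * np.sqrt(2.0 - np.pi / 2.0) / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(expected, abs=4 * se)

    def test_seed_determinism_and_distinctness(self, myo_spec):
        truth = make_phantom(myo_spec)
        a = simulate_multiecho(truth, noise_sigma=10.0, seed=1)
        b = simulate_multiecho(truth, noise_sigma=10.0, seed=1)
        c = simulate_multiecho(truth, noise_sigma=10.0, seed=2)
        assert np.array_equal(a.echo_images, b.echo_images)
        assert not np.array_equal(a.echo_images, c.echo_images)

    def test_noise_preserves_nonnegativity(self, myo_spec):
        truth = make_phantom(myo_spec)
        img = simulate_multiecho(truth, noise_sigma=50.0, seed=0)
        assert np.all(img.echo_images >= 0)

    def test_negative_sigma_rejected(self, myo_spec):
        truth = make_phantom(myo_spec)
        with pytest.raises(ValueError):
            simulate_multiecho(truth, noise_sigma=-1.0)


class TestInjectBlooming:
    @pytest.fixture()
    def clean_image(self, myo_spec):
        return simulate_multiecho(make_phantom(myo_spec), noise_sigma=0.0)

    def test_early_echoes_untouched(self, clean_image, myo_spec):
        region = make_phantom(myo_spec).mask("panmyocardium")
        out = inject_blooming(clean_image, region, severity=150.0, onset_echo=4)
        assert np.array_equal(out.echo_images[:3], clean_image.echo_images[:3])
        assert not np.array_equal(out.echo_images[3:], clean_image.echo_images[3:])

    def test_outside_region_untouched(self, clean_image, myo_spec):
        region = make_phantom(myo_spec).mask("panmyocardium")
        out = inject_blooming(clean_image, region, severity=150.0, onset_echo=4)
        assert np.array_equal(out.echo_images[:, ~region],
                              clean_image.echo_images[:, ~region])

    def test_zero_severity_is_identity(self, clean_image, myo_spec):
        region = make_phantom(myo_spec).mask("panmyocardium")
        out = inject_blooming(clean_image, region, severity=0.0)
        assert np.array_equal(out.echo_images, clean_image.echo_images)

    def test_attenuation_factor_closed_form(self, clean_image, myo_spec):
        region = make_phantom(myo_spec).mask("panmyocardium")
        out = inject_blooming(clean_image, region, severity=1000.0, onset_echo=8)
        te_last = clean_image.echo_times_ms[-1]
        ratio = out.echo_images[-1][region] / clean_image.echo_images[-1][region]
        assert ratio == pytest.approx(np.exp(-te_last), rel=1e-12)

    def test_empty_region_warns_and_returns_unchanged(self, clean_image):
        empty = np.zeros(clean_image.echo_images.shape[1:], bool)
        with pytest.warns(UserWarning, match="empty"):
            out = inject_blooming(clean_image, empty, severity=100.0)
        assert np.array_equal(out.echo_images, clean_image.echo_images)


class TestSampleCohort:
    def test_myocardial_change_mean_matches_generator(self):
        params = {"panmyocardium": normal_values(1.5)["panmyocardium"]}
        cohort = sample_cohort(params, 10_000, seed=11)
        deltas = np.array([s.r2star_post["panmyocardium"] - s.r2star_pre["panmyocardium"]
                           for s in cohort])
        se = 7.3 / np.sqrt(len(deltas))
        assert deltas.mean() == pytest.approx(26.5, abs=3 * se)

    def test_zero_sds_degenerate_to_means(self):
        from uspio_t2star import TissueParams
        params = {"panmyocardium": TissueParams("panmyocardium", 33.5, 0.0, 26.5, 0.0)}
        cohort = sample_cohort(params, 5, seed=0)
        for s in cohort:
            assert s.r2star_pre["panmyocardium"] == pytest.approx(33.5)
            assert s.r2star_post["panmyocardium"] == pytest.approx(60.0)

    def test_bmi_delta_correlation_recovered(self):
        params = {"panmyocardium": normal_values(1.5)["panmyocardium"]}
        cohort = sample_cohort(params, 10_000, bmi_dr2star_corr=0.72, seed=3)
        bmi = np.array([s.bmi for s in cohort])
        delta = np.array([s.r2star_post["panmyocardium"] - s.r2star_pre["panmyocardium"]
                          for s in cohort])
        r = np.corrcoef(bmi, delta)[0, 1]
        assert r == pytest.approx(0.72, abs=0.02)

    def test_seeded_reproducibility(self):
        params = normal_values(1.5)
        a = sample_cohort(params, 6, seed=9)
        b = sample_cohort(params, 6, seed=9)
        c = sample_cohort(params, 6, seed=10)
        assert a == b
        assert a != c

    def test_all_r2star_positive_even_for_wide_tissues(self):
        with pytest.warns(UserWarning, match="bone"):
            cohort = sample_cohort(normal_values(3.0), 500, seed=21,
                                   field_strength=3.0)
        for s in cohort:
            assert all(v > 0 for v in s.r2star_post.values())

    def test_invalid_inputs_rejected(self):
        params = normal_values(1.5)
        with pytest.raises(ValueError):
            sample_cohort(params, 1)
        with pytest.raises(ValueError):
            sample_cohort(params, 5, bmi_dr2star_corr=1.5)
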