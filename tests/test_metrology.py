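"""Recentering, radial profiles, cutoff radii, and dimer separations."""

import math

import numpy as np
import pytest

from dimerlabel import metrology, scene
from dimerlabel.metrology import ClassAverage


def _ca(img, n=1, px=1.0):
    return ClassAverage(image=img, pixel_size=px, n_particles=n)


class TestRecenter:
    def test_centered_image_is_fixed_point(self, centered_monomer_image):
        img, _, _ = centered_monomer_image
        out = metrology.recenter(_ca(img))
        assert np.allclose(out.image, img, atol=1e-6 * img.max())

    def test_offset_disc_recentered_to_hundredth_pixel(self):
        spec = scene.SceneSpec(pixel_size=1.0, shape=(64, 64))
        truth = scene.ParticleTruth(
            id=0, kind="monomer", center=np.array([31.5 + 3.4, 31.5 - 2.1])
        )
        out = metrology.recenter(_ca(scene.render_projection(truth, spec)))
        c = metrology._centroid(metrology._background_subtract(out.image))
        assert np.linalg.norm(c - np.array([31.5, 31.5])) < 0.01

    def test_pure_noise_raises(self, rng):
        with pytest.raises(ValueError):
            metrology.recenter(_ca(rng.normal(0.0, 1.0, (64, 64)) - 10.0))


class TestRadialProfile:
    def test_binary_disc_step_profile(self):
        idx = np.indices((65, 65))
        r = np.hypot(idx[0] - 32, idx[1] - 32)
        disc = (r <= 10.0).astype(float)
        prof = metrology.radial_profile([_ca(disc)])
        assert np.all(prof.mean_intensity[prof.radii <= 9.0] == pytest.approx(1.0))
        assert np.all(prof.mean_intensity[prof.radii >= 12.0] == pytest.approx(0.0))

    def test_projected_sphere_matches_chord_length(self, centered_monomer_image):
        img, spec, _ = centered_monomer_image
        prof = metrology.radial_profile([_ca(img)])
        R = spec.monomer_radius
        mask = prof.radii <= 0.9 * R
        chord = np.sqrt(1 - (prof.radii[mask] / R) ** 2)
        assert np.abs(prof.mean_intensity[mask] - chord).max() < 0.02

    def test_zero_weight_class_ignored(self, centered_monomer_image):
        img, _, _ = centered_monomer_image
        other = np.roll(img, 5, axis=0)
        # n_particles >= 1 enforced, so emulate "weight 1000 vs 1"
        heavy = metrology.radial_profile([_ca(img, n=100000), _ca(other, n=1)])
        alone = metrology.radial_profile([_ca(img)])
        assert np.allclose(heavy.mean_intensity, alone.mean_intensity, atol=5e-3)

    def test_mixed_pixel_sizes_rejected(self, centered_monomer_image):
        img, _, _ = centered_monomer_image
        with pytest.raises(ValueError):
            metrology.radial_profile([_ca(img, px=1.0), _ca(img, px=2.0)])


class TestCutoffRadii:
    def test_step_disc_all_cutoffs_at_edge(self):
        idx = np.indices((65, 65))
        r = np.hypot(idx[0] - 32, idx[1] - 32)
        prof = metrology.radial_profile([_ca((r <= 10.0).astype(float))])
        cut = metrology.cutoff_radii(prof)
        # 1-px annuli average the hard edge over one annulus, so the cutoffs
        # are accurate to one annulus width for a discontinuous profile
        for rf in (cut.r50, cut.r20, cut.r10):
            assert abs(rf - 10.0) <= 1.0

    def test_projected_sphere_matches_analytic_inversion(self, centered_monomer_image):
        img, spec, _ = centered_monomer_image
        prof = metrology.radial_profile([_ca(img)])
        cut = metrology.cutoff_radii(prof)
        R = spec.monomer_radius
        for f, rf in ((0.5, cut.r50), (0.2, cut.r20), (0.1, cut.r10)):
            assert abs(rf - R * math.sqrt(1 - f * f)) <= 0.5 * spec.pixel_size
        assert cut.d50 == 2 * cut.r50

    def test_ordering_invariant_with_gaussian_tail(self):
        radii = np.arange(30.0)
        prof = metrology.RadialProfile(
            radii=radii, mean_intensity=np.exp(-(radii**2) / 50.0), n_particles=1
        )
        cut = metrology.cutoff_radii(prof)
        assert cut.r50 <= cut.r20 <= cut.r10

    def test_profile_never_crossing_raises_with_level_named(self):
        radii = np.arange(10.0)
        prof = metrology.RadialProfile(
            radii=radii, mean_intensity=np.linspace(1.0, 0.4, 10), n_particles=1
        )
        with pytest.raises(ValueError, match="20%"):
            metrology.cutoff_radii(prof)


def template_separation_oracle(img, pixel_size, radius, sep_grid, angle_grid):
    """Exhaustive two-disc template grid search (brute-force oracle)."""
    spec = scene.SceneSpec(pixel_size=pixel_size, shape=img.shape, monomer_radius=radius)
    center = (np.array(img.shape, float) - 1) / 2 * pixel_size
    best = (-np.inf, None)
    for sep in sep_grid:
        for ang in angle_grid:
            axis = np.array([math.sin(ang), math.cos(ang)])
            t = scene.ParticleTruth(
                id=0, kind="dimer", center=center, axis=axis, separation=sep
            )
            tmpl = scene.render_projection(t, spec)
            score = float((tmpl * img).sum() / np.linalg.norm(tmpl))
            if score > best[0]:
                best = (score, sep)
    return best[1]


class TestSplitCentroids:
    def test_symmetric_dumbbell_centroids(self, dumbbell_image):
        img, spec, _ = dumbbell_image
        a, b, score = metrology.split_centroids(_ca(img))
        assert np.linalg.norm(b - a) == pytest.approx(40.0, abs=0.5)
        mid = (a + b) / 2
        assert np.allclose(mid, [47.5, 47.5], atol=0.5)
        assert score >= 0.1

    def test_rotation_invariance(self, dumbbell_image):
        img, spec, truth = dumbbell_image
        th = math.radians(37.0)
        rot = scene.ParticleTruth(
            id=0, kind="dimer", center=truth.center,
            axis=np.array([math.sin(th), math.cos(th)]), separation=40.0,
        )
        img_r = scene.render_projection(rot, spec)
        a, b, _ = metrology.split_centroids(_ca(img_r))
        assert np.linalg.norm(b - a) == pytest.approx(40.0, abs=0.5)

    def test_monomer_rejected(self, centered_monomer_image):
        img, _, _ = centered_monomer_image
        with pytest.raises(metrology.ClassRejected):
            metrology.split_centroids(_ca(img))

    def test_agrees_with_template_oracle(self, dumbbell_image):
        img, spec, _ = dumbbell_image
        a, b, _ = metrology.split_centroids(_ca(img))
        measured = np.linalg.norm(b - a)
        oracle = template_separation_oracle(
            img, 1.0, 13.2, np.arange(36.0, 44.5, 0.5), [0.0]
        )
        assert abs(measured - oracle) <= 0.5


class TestAxisProfile:
    def test_symmetric_dumbbell_profile_even_with_peaks_at_lobes(self, dumbbell_image):
        img, _, _ = dumbbell_image
        ca = _ca(img)
        a, b, _ = metrology.split_centroids(ca)
        t, vals = metrology.axis_profile(ca, a, b)
        assert np.allclose(vals, vals[::-1], atol=0.02 * vals.max())
        assert abs(abs(t[np.argmax(vals * (t < 0))])) == pytest.approx(20.0, abs=2.0)

    def test_constant_image_gives_constant_profile(self):
        ca = _ca(np.ones((64, 64)))
        t, vals = metrology.axis_profile(
            ca, np.array([20.0, 20.0]), np.array([40.0, 40.0])
        )
        assert np.allclose(vals, vals[0])

    def test_coincident_centroids_rejected(self):
        ca = _ca(np.ones((64, 64)))
        with pytest.raises(ValueError):
            metrology.axis_profile(ca, np.array([20.0, 20.0]), np.array([20.0, 20.0]))


def _measurement(sep, n):
    return metrology.SeparationMeasurement(
        class_id=0, centroid_a=np.zeros(2), centroid_b=np.array([0.0, sep]),
        separation=sep, n_particles=n, axis_profile=np.zeros(3),
        axis_offsets=np.zeros(3), dumbbell_score=1.0,
    )


class TestAggregation:
    def test_single_class(self):
        hist = metrology.aggregate_separations([_measurement(34.8, 100)])
        assert hist.mean == pytest.approx(34.8)
        assert hist.sd == 0.0
        assert hist.counts[4] == 100  # bin [34, 36)
        assert hist.counts.sum() == 100

    def test_weighted_mean_of_two_classes(self):
        hist = metrology.aggregate_separations(
            [_measurement(30.0, 100), _measurement(40.0, 300)]
        )
        assert hist.mean == pytest.approx(37.5)
        assert hist.counts.sum() == 400  # conservation

    def test_overflow_goes_to_bucket_with_warning(self):
        with pytest.warns(UserWarning):
            hist = metrology.aggregate_separations(
                [_measurement(50.0, 10), _measurement(34.0, 5)]
            )
        assert hist.n_overflow == 10
        assert hist.counts.sum() == 5

    def test_representative_is_configuration_not_estimator(self):
        hist = metrology.aggregate_separations(
            [_measurement(34.8, 100)], representative=40.0
        )
        assert hist.representative == 40.0
        assert hist.mean == pytest.approx(34.8)


class TestParameterRecovery:
    def test_fig2c_procedure_recovers_generator_truth(self):
        """20 dimer classes at SNR 3 recover the truth mean/SD to 0.5/1.0 A."""
        spec = scene.SceneSpec(
            pixel_size=1.0, shape=(96, 96), monomer_fraction=0.0, dimer_fraction=1.0,
            snr=3.0, seed=11,
        )
        cas, truths = scene.generate_class_averages(spec, 20, 1000)
        measurements = []
        for i, ca in enumerate(cas):
            ca = metrology.recenter(ca)
            measurements.append(metrology.measure_separation(ca, class_id=i))
        hist = metrology.aggregate_separations(measurements)
        w = np.array([m.n_particles for m in measurements], float)
        s = np.array([truths[m.class_id].separation for m in measurements])
        true_mean = np.average(s, weights=w)
        true_sd = math.sqrt(np.average((s - true_mean) ** 2, weights=w))
        assert abs(hist.mean - true_mean) <= 0.5
        assert abs(hist.sd - true_sd) <= 1.0
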