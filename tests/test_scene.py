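"""Synthetic projections, class averages, tomograms, and the missing wedge."""

import numpy as np
import pytest

from dimerlabel import scene
from dimerlabel.metrology import ClassAverage


def brute_force_ball_volume(radius, h=0.25):
    """Oracle: voxel integration of the indicator of a ball."""
    ax = np.arange(-radius - 1, radius + 1 + h, h)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.sum(x**2 + y**2 + z**2 <= radius**2) * h**3


class TestRenderProjection:
    def test_integrated_intensity_equals_ball_volume(self, centered_monomer_image):
        img, spec, _ = centered_monomer_image
        oracle = brute_force_ball_volume(spec.monomer_radius)
        assert img.sum() * spec.pixel_size**2 == pytest.approx(oracle, rel=0.01)

    def test_zero_separation_dimer_is_doubled_monomer(self, centered_monomer_image):
        img, spec, truth = centered_monomer_image
        dimer = scene.ParticleTruth(
            id=0, kind="dimer", center=truth.center, axis=np.array([0.0, 1.0]),
            separation=1e-9,
        )
        assert np.allclose(scene.render_projection(dimer, spec), 2 * img, atol=1e-6)

    def test_dimer_peak_to_peak_distance(self, dumbbell_image):
        img, spec, truth = dumbbell_image
        from scipy.signal import find_peaks

        row = img[47, :] + img[48, :]
        peaks, props = find_peaks(row, height=0.5 * row.max())
        peaks = peaks[np.argsort(props["peak_heights"])[-2:]]
        assert abs(abs(peaks[0] - peaks[1]) * spec.pixel_size - 40.0) <= 1.0

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            scene.SceneSpec(monomer_radius=-1.0)


class TestClassAverages:
    def test_single_noiseless_average_is_the_render(self, rng):
        spec = scene.SceneSpec(shape=(64, 64), monomer_fraction=1.0, dimer_fraction=0.0)
        ca, truth = scene.generate_class_average(spec, 1, rng=rng)
        assert np.allclose(ca.image, scene.render_projection(truth, spec))

    def test_thousand_particle_average_matches_noiseless_profile(self, rng):
        spec = scene.SceneSpec(
            shape=(64, 64), monomer_fraction=1.0, dimer_fraction=0.0, snr=1.0
        )
        ca, truth = scene.generate_class_average(spec, 1000, rng=rng)
        clean = scene.render_projection(truth, spec)
        # the residual is pure noise of SD sigma/sqrt(n); at snr=1 sigma equals
        # the peak, so the normalized RMS should sit at 1/sqrt(1000)
        rms = np.sqrt(np.mean((ca.image - clean) ** 2)) / clean.max()
        assert rms == pytest.approx(1.0 / np.sqrt(1000.0), rel=0.15)

    def test_truth_separations_respect_bounds(self, rng):
        spec = scene.SceneSpec(
            shape=(64, 64), monomer_fraction=0.0, dimer_fraction=1.0, snr=3.0
        )
        _, truths = scene.generate_class_averages(spec, 50, 10)
        seps = [t.separation for t in truths]
        assert all(26.0 <= s <= 46.0 for s in seps)

    def test_nonpositive_snr_rejected(self):
        with pytest.raises(ValueError):
            scene.SceneSpec(snr=0.0)


class TestTomogram:
    def test_empty_scene_is_pure_noise(self):
        spec = scene.SceneSpec(
            pixel_size=10.0, shape=(48, 48, 48), n_particles=0, snr=5.0, seed=1,
            monomer_fraction=1.0, dimer_fraction=0.0,
        )
        vol = scene.generate_tomogram(spec)
        assert abs(vol.density.mean()) < 3 * (1 / 5.0) / np.sqrt(48**3)
        assert vol.truth == []

    def test_min_center_distance_respected(self):
        spec = scene.SceneSpec(
            pixel_size=10.0, shape=(128, 128, 128), n_particles=20,
            monomer_fraction=0.0, dimer_fraction=1.0, min_center_distance=100.0,
            seed=4,
        )
        vol = scene.generate_tomogram(spec)
        centers = np.array([t.center for t in vol.truth])
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 100.0
        assert len(vol.truth) == 20  # truth completeness

    def test_membrane_midplanes_cleft_width_apart(self):
        spec = scene.SceneSpec(
            pixel_size=10.0, shape=(96, 64, 64), n_particles=0,
            membrane_pair=(280.0, 50.0), monomer_fraction=1.0, dimer_fraction=0.0,
        )
        vol = scene.generate_tomogram(spec)
        prof = vol.density.sum(axis=(1, 2))
        z = np.arange(96) * 10.0
        # two slabs: centroids of the two density bands
        half = len(prof) // 2
        z1 = np.average(z[:half], weights=prof[:half])
        z2 = np.average(z[half:], weights=prof[half:])
        assert z2 - z1 == pytest.approx(280.0, abs=2.0)
        assert vol.membranes is not None

    def test_unplaceable_scene_reports_achieved_count(self):
        spec = scene.SceneSpec(
            pixel_size=10.0, shape=(32, 32, 32), n_particles=100,
            min_center_distance=200.0, retry_cap=20, seed=0,
            monomer_fraction=1.0, dimer_fraction=0.0,
        )
        with pytest.raises(scene.PlacementError) as err:
            scene.generate_tomogram(spec)
        assert err.value.placed < 100

    def test_reproducibility_bit_identical(self):
        spec = scene.SceneSpec(
            pixel_size=10.0, shape=(48, 48, 48), n_particles=5, snr=5.0, seed=7,
            monomer_fraction=0.5, dimer_fraction=0.5, min_center_distance=60.0,
        )
        a = scene.generate_tomogram(spec)
        b = scene.generate_tomogram(spec)
        assert np.array_equal(a.density, b.density)
        assert all(
            np.array_equal(x.center, y.center) for x, y in zip(a.truth, b.truth)
        )


class TestMissingWedge:
    def test_full_tilt_range_is_identity(self):
        rng = np.random.default_rng(0)
        vol = scene.TomoVolume(voxel_size=10.0, density=rng.normal(size=(32, 32, 32)))
        out = scene.apply_missing_wedge(vol, -90.0, 90.0)
        assert np.allclose(out.density, vol.density, atol=1e-10)

    def test_degenerate_range_rejected(self):
        vol = scene.TomoVolume(voxel_size=10.0, density=np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            scene.apply_missing_wedge(vol, 30.0, 30.0)

    def test_mask_hermitian_and_output_real(self):
        mask = scene.missing_wedge_mask((16, 16, 16), -68.0, 28.0)
        flipped = mask[
            np.ix_(*[(-np.arange(n)) % n for n in mask.shape])
        ]
        assert np.array_equal(mask, flipped)
        rng = np.random.default_rng(1)
        vol = scene.TomoVolume(voxel_size=10.0, density=rng.normal(size=(16, 16, 16)))
        out = scene.apply_missing_wedge(vol, -68.0, 28.0)
        assert np.all(np.isreal(out.density))
        assert out.wedge_applied and out.tilt_range == (-68.0, 28.0)

    @staticmethod
    def _interp_fwhm(profile):
        profile = profile / profile.max()
        i0 = int(np.argmax(profile))

        def cross(step):
            prev = i0
            i = i0 + step
            while 0 <= i < len(profile):
                if profile[i] < 0.5:
                    # linear interpolation between prev and i
                    frac = (profile[prev] - 0.5) / (profile[prev] - profile[i])
                    return prev + frac * (i - prev)
                prev, i = i, i + step
            return prev

        return abs(cross(+1) - cross(-1))

    def test_point_response_elongated_along_z(self):
        # small Gaussian source so the half-max is resolvable on the grid
        ax = np.arange(64)
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        dens = np.exp(-((zz - 32.0) ** 2 + (yy - 32.0) ** 2 + (xx - 32.0) ** 2) / (2 * 1.5**2))
        vol = scene.TomoVolume(voxel_size=10.0, density=dens)
        out = scene.apply_missing_wedge(vol, -48.0, 48.0)
        fz = self._interp_fwhm(out.density[:, 32, 32])
        fx = self._interp_fwhm(out.density[32, 32, :])
        assert fz > fx

    def test_axial_dimer_dip_shallower_than_in_plane(self):
        spec = scene.SceneSpec(pixel_size=10.0, shape=(64, 64, 64), n_particles=0)
        dips = {}
        for name, axis in (("z", [1.0, 0.0, 0.0]), ("xy", [0.0, 0.0, 1.0])):
            t = scene.ParticleTruth(
                id=0, kind="dimer", center=np.array([320.0] * 3),
                axis=np.array(axis), separation=40.0,
            )
            vol = scene.TomoVolume(
                voxel_size=10.0, density=scene.render_volume(spec, [t]), truth=[t]
            )
            out = scene.apply_missing_wedge(vol, -48.0, 48.0)
            # profile along the dumbbell axis through the center
            if name == "z":
                prof = out.density[:, 32, 32]
            else:
                prof = out.density[32, 32, :]
            lobes = max(prof[30], prof[34])
            dip = (lobes - prof[32]) / lobes
            dips[name] = dip
        assert dips["z"] < dips["xy"]


def test_class_average_reproducibility():
    spec = scene.SceneSpec(shape=(64, 64), snr=2.0, seed=5)
    a, ta = scene.generate_class_average(spec, 100)
    b, tb = scene.generate_class_average(spec, 100)
    assert np.array_equal(a.image, b.image)
    assert ta.kind == tb.kind
    assert isinstance(a, ClassAverage)
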