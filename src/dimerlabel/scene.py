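"""Synthetic 2D/3D scenes of monomeric and dimeric nanoparticle labels.

The generator emulates what the downstream metrology assumes: homogeneous
gold spheres whose 2D projection intensity is the chord length
2 sqrt(R^2 - rho^2), class averages of n aligned noisy copies of one
geometry, and tomogram-like volumes of randomly placed/oriented monomers and
two-sphere dumbbells, optionally confined between two parallel membrane
slabs and degraded by a Fourier missing-wedge mask matching a single-axis
tilt range. No CTF and no atomic gold lattice: the analyses operate on
reconstructed densities, for which a uniform ball is the appropriate model.

SNR convention: (peak noiseless particle intensity) / (noise SD). All
coordinates are in Angstrom, array index i maps to coordinate i * voxel
(0-based); axes of 3D arrays are (z, y, x) with the tilt axis along y and
the beam along z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .metrology import ClassAverage


@dataclass(frozen=True)
class SceneSpec:
    """Generative parameters for synthetic 2D stacks and 3D volumes."""

    pixel_size: float = 1.0  # A per pixel (2D) or per voxel (3D)
    shape: tuple[int, ...] = (64, 64)
    monomer_fraction: float = 0.5
    dimer_fraction: float = 0.5
    monomer_radius: float = 13.2
    dimer_separation_mean: float = 34.8
    dimer_separation_sd: float = 3.6
    separation_bounds: tuple[float, float] = (26.0, 46.0)
    snr: float = math.inf
    contrast: float = 1.0
    n_particles: int = 0
    tilt_range: tuple[float, float] | None = None
    membrane_pair: tuple[float, float] | None = None  # (cleft width A, slab thickness A)
    min_center_distance: float = 0.0
    retry_cap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        fractions = (self.monomer_fraction, self.dimer_fraction)
        if min(fractions) < 0 or abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("mixture fractions must be >= 0 and sum to 1")
        if self.monomer_radius <= 0:
            raise ValueError("monomer radius must be positive")
        if self.dimer_separation_mean <= 0:
            raise ValueError("dimer separation mean must be positive")
        if self.snr <= 0:
            raise ValueError("SNR must be positive (use inf for noiseless)")
        if self.tilt_range is not None and not (
            -90 < self.tilt_range[0] < self.tilt_range[1] < 90
        ):
            raise ValueError("tilt range must satisfy -90 < min < max < 90")
        if self.min_center_distance < 0:
            raise ValueError("min_center_distance must be >= 0")


@dataclass(frozen=True)
class ParticleTruth:
    """Ground-truth placement of one label."""

    id: int
    kind: str  # "monomer" | "dimer"
    center: np.ndarray  # A; (row, col) in 2D, (z, y, x) in 3D
    axis: np.ndarray | None = None  # unit dumbbell axis, dimers only
    separation: float | None = None  # center-to-center A, dimers only

    def __post_init__(self) -> None:
        if self.kind not in ("monomer", "dimer"):
            raise ValueError(f"unknown particle kind {self.kind!r}")
        object.__setattr__(self, "center", np.asarray(self.center, float))
        if self.kind == "dimer":
            if self.separation is None or self.separation <= 0:
                raise ValueError("dimer separation must be positive")
            axis = np.asarray(self.axis, float)
            if abs(np.linalg.norm(axis) - 1.0) > 1e-6:
                raise ValueError("dumbbell axis must have unit norm")
            object.__setattr__(self, "axis", axis)

    @property
    def lobe_centers(self) -> np.ndarray:
        """Sphere centers (k, ndim): one row for monomers, two for dimers."""
        if self.kind == "monomer":
            return self.center[None, :]
        half = 0.5 * self.separation * self.axis
        return np.stack([self.center - half, self.center + half])


@dataclass(frozen=True)
class ImageStack2D:
    pixel_size: float
    images: np.ndarray  # (N, H, W)
    truth: list[ParticleTruth]


@dataclass(frozen=True)
class TomoVolume:
    voxel_size: float
    density: np.ndarray  # (nz, ny, nx)
    truth: list[ParticleTruth] = field(default_factory=list)
    membranes: tuple[dict, dict] | None = None
    wedge_applied: bool = False
    tilt_range: tuple[float, float] | None = None


def uniform_sphere_axis(rng: np.random.Generator, in_plane: bool = False) -> np.ndarray:
    """Uniform random unit vector: on S^2, or in the image plane (z comp 0)."""
    while True:
        v = rng.normal(size=3)
        if in_plane:
            v[0] = 0.0  # (z, y, x) ordering: zero the out-of-plane component
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float]
) -> float:
    """Normal draw rejected until it lands inside closed bounds."""
    lo, hi = bounds
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate truncated normal outside bounds")
        return mean
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated normal sampling failed")


def render_projection(truth: ParticleTruth, spec: SceneSpec) -> np.ndarray:
    """Noiseless 2D projection of a homogeneous ball (or dumbbell).

    Each sphere of radius R centered in-plane at c contributes
    contrast * 2 sqrt(R^2 - rho^2) at in-plane distance rho <= R; a dimer is
    the sum of two such discs, its 3D axis projected into the plane. The
    integrated image intensity times the pixel area equals the ball volume
    times contrast.
    """
    h, w = spec.shape[-2:]
    a = spec.pixel_size
    rr, cc = np.indices((h, w)).astype(float) * a
    img = np.zeros((h, w))
    radius = spec.monomer_radius
    for lobe in truth.lobe_centers:
        y, x = lobe[-2], lobe[-1]  # in-plane projection
        rho2 = (rr - y) ** 2 + (cc - x) ** 2
        chord2 = radius**2 - rho2
        img += 2.0 * np.sqrt(np.clip(chord2, 0.0, None))
    return spec.contrast * img


def projection_peak(spec: SceneSpec) -> float:
    """Peak noiseless intensity of a single projected monomer."""
    return 2.0 * spec.monomer_radius * spec.contrast


def sample_class_truth(spec: SceneSpec, rng: np.random.Generator) -> ParticleTruth:
    """One class geometry: centered particle, in-plane dumbbell axis."""
    h, w = spec.shape[-2:]
    center = (np.array([h, w], float) - 1.0) / 2.0 * spec.pixel_size
    if rng.uniform() < spec.dimer_fraction:
        sep = truncated_normal(
            rng, spec.dimer_separation_mean, spec.dimer_separation_sd, spec.separation_bounds
        )
        axis3 = uniform_sphere_axis(rng, in_plane=True)
        return ParticleTruth(
            id=0, kind="dimer", center=center, axis=axis3[1:], separation=sep
        )
    return ParticleTruth(id=0, kind="monomer", center=center)


def generate_class_average(
    spec: SceneSpec,
    n_particles: int,
    rng: np.random.Generator | None = None,
    truth: ParticleTruth | None = None,
) -> tuple[ClassAverage, ParticleTruth]:
    """Average of n aligned noisy renders sharing one truth geometry.

    Alignment is taken from truth (reference-free classification is out of
    scope), so the average of n iid noisy copies equals the noiseless render
    plus Gaussian noise of SD sigma/sqrt(n); it is sampled in that exact
    form. sigma is set so the per-image SNR matches the spec.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if truth is None:
        truth = sample_class_truth(spec, rng)
    img = render_projection(truth, spec)
    if math.isfinite(spec.snr):
        sd = projection_peak(spec) / spec.snr
        img = img + rng.normal(0.0, sd / math.sqrt(n_particles), size=img.shape)
    return (
        ClassAverage(image=img, pixel_size=spec.pixel_size, n_particles=n_particles),
        truth,
    )


def generate_class_averages(
    spec: SceneSpec, n_classes: int, particles_per_class: int
) -> tuple[list[ClassAverage], list[ParticleTruth]]:
    """A set of class averages drawn from the spec's mixture (one RNG stream)."""
    rng = np.random.default_rng(spec.seed)
    cas, truths = [], []
    for i in range(n_classes):
        ca, truth = generate_class_average(spec, particles_per_class, rng=rng)
        cas.append(ca)
        truths.append(replace(truth, id=i))
    return cas, truths


class PlacementError(RuntimeError):
    """Requested particle count unplaceable under the distance constraint."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed}/{requested} particles under the "
            "min-center-distance constraint"
        )


def _placement_bounds(spec: SceneSpec, margin: float) -> tuple[np.ndarray, np.ndarray]:
    extent = np.array(spec.shape, float) * spec.pixel_size
    lo = np.full(len(spec.shape), margin)
    hi = extent - margin
    if spec.membrane_pair is not None:
        cleft, thickness = spec.membrane_pair
        mid = extent[0] / 2.0
        lo[0] = max(lo[0], mid - cleft / 2.0 + margin)
        hi[0] = min(hi[0], mid + cleft / 2.0 - margin)
    if np.any(hi <= lo):
        raise ValueError("volume too small for the requested margins")
    return lo, hi


def place_particles(spec: SceneSpec, rng: np.random.Generator) -> list[ParticleTruth]:
    """Rejection-sample particle placements respecting min_center_distance.

    Particle centers of distinct particles must be >= min_center_distance
    apart and lobe centers of distinct particles must not overlap (>= 2R).
    """
    truths: list[ParticleTruth] = []
    all_lobes: list[np.ndarray] = []
    all_centers: list[np.ndarray] = []
    radius = spec.monomer_radius
    for pid in range(spec.n_particles):
        is_dimer = rng.uniform() < spec.dimer_fraction
        placed = False
        for _ in range(spec.retry_cap):
            if is_dimer:
                sep = truncated_normal(
                    rng,
                    spec.dimer_separation_mean,
                    spec.dimer_separation_sd,
                    spec.separation_bounds,
                )
                axis = uniform_sphere_axis(rng)
                margin = radius + sep / 2.0
            else:
                sep, axis, margin = None, None, radius
            lo, hi = _placement_bounds(spec, margin)
            center = rng.uniform(lo, hi)
            cand = ParticleTruth(
                id=pid,
                kind="dimer" if is_dimer else "monomer",
                center=center,
                axis=axis,
                separation=sep,
            )
            lobes = cand.lobe_centers
            ok = True
            if all_centers:
                dc = np.linalg.norm(np.asarray(all_centers) - center, axis=1)
                if dc.min() < spec.min_center_distance:
                    ok = False
            if ok and all_lobes:
                prev = np.concatenate(all_lobes)
                dl = np.linalg.norm(prev[:, None, :] - lobes[None, :, :], axis=2)
                if dl.min() < max(2 * radius, spec.min_center_distance):
                    ok = False
            if ok:
                truths.append(cand)
                all_centers.append(center)
                all_lobes.append(lobes)
                placed = True
                break
        if not placed:
            raise PlacementError(len(truths), spec.n_particles)
    return truths


def _rasterize_ball(
    density: np.ndarray, center: np.ndarray, radius: float, voxel: float, amplitude: float
) -> None:
    """Add a homogeneous ball with a one-voxel antialiased edge, in place."""
    idx_c = center / voxel
    r_vox = radius / voxel
    lo = np.maximum(np.floor(idx_c - r_vox - 1).astype(int), 0)
    hi = np.minimum(np.ceil(idx_c + r_vox + 2).astype(int), density.shape)
    if np.any(hi <= lo):
        return
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    dist = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, idx_c)))
    frac = np.clip(r_vox - dist + 0.5, 0.0, 1.0)
    density[tuple(slice(l, h) for l, h in zip(lo, hi))] += amplitude * frac


def render_volume(spec: SceneSpec, truths: list[ParticleTruth]) -> np.ndarray:
    """Noiseless 3D density of the given truths plus optional membranes."""
    density = np.zeros(spec.shape, dtype=float)
    a = spec.pixel_size
    if spec.membrane_pair is not None:
        cleft, thickness = spec.membrane_pair
        z = (np.arange(spec.shape[0], dtype=float) * a)[:, None, None]
        mid = spec.shape[0] * a / 2.0
        for zc in (mid - cleft / 2.0, mid + cleft / 2.0):
            density += spec.contrast * 0.5 * (np.abs(z - zc) <= thickness / 2.0)
    for truth in truths:
        for lobe in truth.lobe_centers:
            _rasterize_ball(density, lobe, spec.monomer_radius, a, spec.contrast)
    return density


def generate_tomogram(
    spec: SceneSpec,
    rng: np.random.Generator | None = None,
    truths: list[ParticleTruth] | None = None,
) -> TomoVolume:
    """Synthetic tomogram-like volume with full ground truth.

    Particles are placed uniformly at random (orientation uniform on the
    sphere) under the min-center-distance constraint; membranes, when
    requested, are two parallel slabs perpendicular to z whose mid-planes
    are cleft-width apart, with particles confined to the cleft. Gaussian
    noise at the spec SNR is added after rendering; truth is recorded before
    degradation. The missing wedge, when spec.tilt_range is set, is applied
    as a separate step so the pristine volume is also accessible.
    """
    if len(spec.shape) != 3:
        raise ValueError("generate_tomogram needs a 3D shape")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if truths is None:
        truths = place_particles(spec, rng)
    density = render_volume(spec, truths)
    if math.isfinite(spec.snr):
        density = density + rng.normal(0.0, spec.contrast / spec.snr, size=density.shape)
    membranes = None
    if spec.membrane_pair is not None:
        cleft, _ = spec.membrane_pair
        mid = spec.shape[0] * spec.pixel_size / 2.0
        membranes = (
            {"point": np.array([mid - cleft / 2.0, 0.0, 0.0]), "normal": np.array([1.0, 0.0, 0.0])},
            {"point": np.array([mid + cleft / 2.0, 0.0, 0.0]), "normal": np.array([1.0, 0.0, 0.0])},
        )
    vol = TomoVolume(
        voxel_size=spec.pixel_size, density=density, truth=truths, membranes=membranes
    )
    if spec.tilt_range is not None:
        vol = apply_missing_wedge(vol, *spec.tilt_range)
    return vol


def missing_wedge_mask(
    shape: tuple[int, int, int], tilt_min: float, tilt_max: float
) -> np.ndarray:
    """Boolean Fourier mask of the sampled double wedge for a tilt range.

    Single-axis tilt about y with the beam along z: a tilt theta measures
    the central plane whose in-(kx, kz) angle from the kx axis is theta, so
    the sampled region is the set of frequencies whose folded angle
    atan(kz/kx) in (-90, 90] lies within [tilt_min, tilt_max]. The mask is
    even under k -> -k (Hermitian), so masked volumes stay real.
    """
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    psi = np.degrees(np.arctan2(kz, kx))

    def in_range(angle):
        return (angle >= tilt_min) & (angle <= tilt_max)

    # a central section at tilt theta equals the one at theta +/- 180
    mask = in_range(psi) | in_range(psi - 180.0) | in_range(psi + 180.0)
    # the DC line kx = kz = 0 (psi = 0) is sampled at every tilt
    mask = mask | ((kz == 0) & (kx == 0))
    mask = np.broadcast_to(mask, shape).copy()
    # enforce Hermitian symmetry exactly: the unpaired Nyquist planes of an
    # even-sized grid map onto themselves under k -> -k with only kx (or kz)
    # negated, which an asymmetric tilt range would otherwise split
    neg = np.ix_(*[(-np.arange(n)) % n for n in shape])
    return mask & mask[neg]


def apply_missing_wedge(vol: TomoVolume, tilt_min: float, tilt_max: float) -> TomoVolume:
    """Zero Fourier coefficients outside the tilt-range double wedge."""
    if not (-90 <= tilt_min < tilt_max <= 90):
        raise ValueError("tilt range must satisfy -90 <= min < max <= 90")
    mask = missing_wedge_mask(vol.density.shape, tilt_min, tilt_max)
    filtered = np.fft.ifftn(np.fft.fftn(vol.density) * mask).real
    return TomoVolume(
        voxel_size=vol.voxel_size,
        density=filtered,
        truth=vol.truth,
        membranes=vol.membranes,
        wedge_applied=True,
        tilt_range=(tilt_min, tilt_max),
    )
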