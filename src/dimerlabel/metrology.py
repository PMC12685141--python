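"""2D class-average metrology: cutoff diameters and dimer separations.

Monomer sizing: class averages are recentered on the intensity-weighted
particle midpoint, pooled into a particle-count-weighted radial intensity
profile (1-px annuli, normalized to maximum 1), and the cutoff radii
r50/r20/r10 are read off as the outermost descending crossings of the
50/20/10% intensity levels; diameters are twice the radii.

Dimer separation: for each two-lobe class average the two intensity-weighted
lobe centroids are located by iterative bisection along the principal axis,
intensity is sampled along the intercentroid axis on [-50, +50] A about the
midpoint, classes without a clear two-lobe dip are rejected, and accepted
per-class separations are aggregated into 2 A bins spanning 26-46 A with
each class's full particle count assigned to its bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

BORDER_PX = 2  # background frame width for median subtraction
HIST_LO, HIST_HI, HIST_STEP = 26.0, 46.0, 2.0
DIP_THRESHOLD = 0.1  # two-lobe acceptance: central dip >= 10% of lobe peak


class ClassRejected(ValueError):
    """A class average failed the two-lobe acceptance criterion."""


@dataclass(frozen=True)
class ClassAverage:
    """Average of n aligned particle images sharing one view."""

    image: np.ndarray
    pixel_size: float
    n_particles: int

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        img = np.asarray(self.image, float)
        if img.ndim != 2 or not np.all(np.isfinite(img)):
            raise ValueError("image must be a finite 2D array")
        object.__setattr__(self, "image", img)


@dataclass(frozen=True)
class RadialProfile:
    radii: np.ndarray
    mean_intensity: np.ndarray
    n_particles: int


@dataclass(frozen=True)
class CutoffDiameters:
    r50: float
    r20: float
    r10: float
    d50: float = field(init=False)
    d20: float = field(init=False)
    d10: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.r50 <= self.r20 <= self.r10):
            raise ValueError("cutoff radii must satisfy 0 < r50 <= r20 <= r10")
        object.__setattr__(self, "d50", 2 * self.r50)
        object.__setattr__(self, "d20", 2 * self.r20)
        object.__setattr__(self, "d10", 2 * self.r10)


@dataclass(frozen=True)
class SeparationMeasurement:
    class_id: int
    centroid_a: np.ndarray  # (row, col) in A
    centroid_b: np.ndarray
    separation: float
    n_particles: int
    axis_profile: np.ndarray
    axis_offsets: np.ndarray
    dumbbell_score: float


@dataclass(frozen=True)
class SeparationHistogram:
    bin_lower_edges: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    representative: float
    n_overflow: int = 0


def _background_subtract(image: np.ndarray) -> np.ndarray:
    """Subtract the median of a 2-px border frame; floor negatives at zero."""
    b = BORDER_PX
    frame = np.concatenate(
        [image[:b].ravel(), image[-b:].ravel(), image[b:-b, :b].ravel(), image[b:-b, -b:].ravel()]
    )
    return np.clip(image - np.median(frame), 0.0, None)


def _centroid(image: np.ndarray) -> np.ndarray:
    total = image.sum()
    if total <= 0:
        raise ValueError("no positive intensity after background subtraction")
    idx = np.indices(image.shape)
    return np.array([(idx[0] * image).sum(), (idx[1] * image).sum()]) / total


def _geometric_center(shape: tuple[int, int]) -> np.ndarray:
    return (np.array(shape, float) - 1.0) / 2.0


def recenter(ca: ClassAverage, tol_px: float = 0.01, max_iter: int = 10) -> ClassAverage:
    """Shift so the intensity-weighted centroid sits at the image center.

    Subpixel shifts are applied in Fourier space; the centroid is computed on
    the background-subtracted, zero-floored image. Raises on images with no
    positive signal (e.g. all-zero or pure zero-mean noise fields).
    """
    img = ca.image
    # reliability: a zero-mean noise field has no centroid worth trusting
    noise = 1.4826 * np.median(np.abs(img - np.median(img)))
    if img.max() - np.median(img) < 5.0 * noise:
        raise ValueError("no reliable centroid: image signal below the noise floor")
    center = _geometric_center(img.shape)
    for _ in range(max_iter):
        offset = _centroid(_background_subtract(img)) - center
        if np.linalg.norm(offset) < tol_px:
            break
        img = np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(img), -offset)).real
    return ClassAverage(image=img, pixel_size=ca.pixel_size, n_particles=ca.n_particles)


def radial_profile(class_averages: list[ClassAverage]) -> RadialProfile:
    """Particle-count-weighted mean intensity vs radius, 1-px annuli.

    All classes must share one pixel size and be recentered. The pooled
    profile is normalized to maximum 1 and reported as measured (no
    monotonicity is imposed).
    """
    if not class_averages:
        raise ValueError("need at least one class average")
    a = class_averages[0].pixel_size
    if any(abs(c.pixel_size - a) > 1e-9 for c in class_averages):
        raise ValueError("mixed pixel sizes")
    shape = class_averages[0].image.shape
    center = _geometric_center(shape)
    idx = np.indices(shape)
    r_px = np.hypot(idx[0] - center[0], idx[1] - center[1])
    annulus = np.round(r_px).astype(int)
    n_bins = annulus.max() + 1

    counts = np.bincount(annulus.ravel(), minlength=n_bins)
    acc = np.zeros(n_bins)
    total_w = 0
    for ca in class_averages:
        img = _background_subtract(ca.image)
        sums = np.bincount(annulus.ravel(), weights=img.ravel(), minlength=n_bins)
        acc += ca.n_particles * sums / np.maximum(counts, 1)
        total_w += ca.n_particles
    prof = acc / total_w
    # an even-sized image has no pixel in the r=0 annulus; fill empty annuli
    # by interpolation so the profile stays defined on the full radius grid
    if np.any(counts == 0):
        filled = counts > 0
        prof = np.interp(np.arange(n_bins), np.flatnonzero(filled), prof[filled])
    prof = prof / prof.max()
    radii = np.arange(n_bins) * a
    return RadialProfile(radii=radii, mean_intensity=prof, n_particles=total_w)


def cutoff_radii(
    profile: RadialProfile, fractions: tuple[float, ...] = (0.5, 0.2, 0.1)
) -> CutoffDiameters:
    """Outermost descending crossings of each intensity fraction.

    For each fraction f the profile is scanned from the outside in for the
    first annulus pair (p[i] >= f > p[i+1]); r_f is located by linear
    interpolation. Raises if the profile never falls below f.
    """
    p = profile.mean_intensity
    r = profile.radii
    out = {}
    for f in fractions:
        crossing = None
        for i in range(len(p) - 2, -1, -1):
            if p[i] >= f > p[i + 1]:
                crossing = r[i] + (p[i] - f) / (p[i] - p[i + 1]) * (r[i + 1] - r[i])
                break
        if crossing is None:
            raise ValueError(f"profile never crosses the {f:.0%} level on a descending branch")
        out[f] = crossing
    return CutoffDiameters(r50=out[0.5], r20=out[0.2], r10=out[0.1])


def axis_profile(
    ca: ClassAverage,
    centroid_a: np.ndarray,
    centroid_b: np.ndarray,
    half_span: float = 50.0,
    step: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity sampled along the intercentroid axis about the midpoint.

    Returns (offsets, values): offsets in A on [-half_span, +half_span],
    bilinear interpolation on the background-subtracted image, origin at the
    centroid midpoint. Centroids are (row, col) in A.
    """
    ca_a = np.asarray(centroid_a, float)
    ca_b = np.asarray(centroid_b, float)
    sep = np.linalg.norm(ca_b - ca_a)
    if sep < 1e-9:
        raise ValueError("centroids coincide")
    unit = (ca_b - ca_a) / sep
    mid = (ca_a + ca_b) / 2.0
    t = np.arange(-half_span, half_span + step / 2, step)
    pts_px = (mid[None, :] + t[:, None] * unit[None, :]) / ca.pixel_size
    img = _background_subtract(ca.image)
    vals = ndimage.map_coordinates(img, pts_px.T, order=1, mode="constant")
    return t, vals


def _dumbbell_score(offsets: np.ndarray, values: np.ndarray) -> float:
    """Dip depth / lobe peak for a two-lobe axis profile; 0 if no two lobes."""
    neg = values[offsets < 0]
    pos = values[offsets > 0]
    if len(neg) == 0 or len(pos) == 0:
        return 0.0
    ia = int(np.argmax(neg))
    ib = int(np.argmax(pos))
    peak = min(neg[ia], pos[ib])
    if peak <= 0:
        return 0.0
    between = values[(offsets >= offsets[offsets < 0][ia]) & (offsets <= offsets[offsets > 0][ib])]
    valley = between.min()
    return float((peak - valley) / peak)


def split_centroids(
    ca: ClassAverage,
    tol_px: float = 0.01,
    max_iter: int = 50,
    support_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Locate the two lobe centroids of a dumbbell class average.

    The principal axis of the intensity second-moment tensor seeds a split
    of the image by the plane through the global centroid perpendicular to
    that axis; each side's intensity-weighted centroid is computed and the
    split plane is re-anchored at the midpoint of the current centroids
    until they move < tol_px or max_iter is reached. Classes whose
    intercentroid axis profile lacks two maxima separated by a central dip
    of at least 10% of the lobe peak are rejected (ClassRejected), as are
    non-converged iterations.

    Returns (centroid_a, centroid_b, dumbbell_score) with centroids in A,
    ordered by projection on the principal axis.
    """
    img = _background_subtract(ca.image)
    total = img.sum()
    if total <= 0:
        raise ClassRejected("no positive intensity")
    # centroid on the particle support only: the zero-floored residual noise
    # pedestal otherwise drags each half-plane centroid outward
    img = np.where(img >= support_frac * img.max(), img, 0.0)
    idx = np.indices(img.shape).astype(float)
    g = _centroid(img)
    d0 = idx[0] - g[0]
    d1 = idx[1] - g[1]
    cov = np.array(
        [
            [(img * d0 * d0).sum(), (img * d0 * d1).sum()],
            [(img * d0 * d1).sum(), (img * d1 * d1).sum()],
        ]
    ) / total
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]

    mid = g.copy()
    prev: np.ndarray | None = None
    for _ in range(max_iter):
        proj = (idx[0] - mid[0]) * axis[0] + (idx[1] - mid[1]) * axis[1]
        wa = img * (proj < 0)
        wb = img * (proj >= 0)
        if wa.sum() <= 0 or wb.sum() <= 0:
            raise ClassRejected("degenerate split: one side empty")
        c_a = _centroid(wa)
        c_b = _centroid(wb)
        cur = np.concatenate([c_a, c_b])
        if prev is not None and np.abs(cur - prev).max() < tol_px:
            break
        prev = cur
        mid = (c_a + c_b) / 2.0
        axis = c_b - c_a
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            raise ClassRejected("centroids collapsed")
        axis = axis / norm
    else:
        raise ClassRejected(f"centroid split did not converge in {max_iter} iterations")

    c_a_ang = c_a * ca.pixel_size
    c_b_ang = c_b * ca.pixel_size
    offsets, values = axis_profile(ca, c_a_ang, c_b_ang)
    score = _dumbbell_score(offsets, values)
    if score < DIP_THRESHOLD:
        raise ClassRejected(
            f"no two-lobe dip: score {score:.3f} < {DIP_THRESHOLD}"
        )
    return c_a_ang, c_b_ang, score


def measure_separation(ca: ClassAverage, class_id: int = 0) -> SeparationMeasurement:
    """Full per-class dimer measurement; raises ClassRejected on monomers."""
    c_a, c_b, score = split_centroids(ca)
    offsets, values = axis_profile(ca, c_a, c_b)
    return SeparationMeasurement(
        class_id=class_id,
        centroid_a=c_a,
        centroid_b=c_b,
        separation=float(np.linalg.norm(c_b - c_a)),
        n_particles=ca.n_particles,
        axis_profile=values,
        axis_offsets=offsets,
        dumbbell_score=score,
    )


def aggregate_separations(
    measurements: list[SeparationMeasurement],
    representative: float | None = None,
) -> SeparationHistogram:
    """Bin per-class separations into 2 A bins on [26, 46).

    Each class contributes its full particle count to the bin holding its
    separation; mean and SD are particle-count weighted. `representative`
    defaults to the weighted mean but is a configuration value: a judgment-
    based choice (e.g. 40 A where counts fall off sharply) may be passed
    instead and is reported verbatim, never silently equated with the mean.
    Separations outside [26, 46) go to an overflow bucket with a warning.
    """
    edges = np.arange(HIST_LO, HIST_HI + HIST_STEP / 2, HIST_STEP)
    counts = np.zeros(len(edges) - 1, dtype=int)
    seps, weights = [], []
    n_overflow = 0
    for m in measurements:
        if not (HIST_LO <= m.separation < HIST_HI):
            n_overflow += m.n_particles
            warnings.warn(
                f"class {m.class_id}: separation {m.separation:.1f} A outside "
                f"[{HIST_LO:.0f}, {HIST_HI:.0f}); counted as overflow",
                stacklevel=2,
            )
            continue
        counts[int((m.separation - HIST_LO) // HIST_STEP)] += m.n_particles
        seps.append(m.separation)
        weights.append(m.n_particles)
    if seps:
        s = np.array(seps)
        w = np.array(weights, float)
        mean = float(np.average(s, weights=w))
        sd = float(np.sqrt(np.average((s - mean) ** 2, weights=w)))
    else:
        mean = sd = float("nan")
    rep = mean if representative is None else float(representative)
    return SeparationHistogram(
        bin_lower_edges=edges[:-1],
        counts=counts,
        mean=mean,
        sd=sd,
        representative=rep,
        n_overflow=n_overflow,
    )
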