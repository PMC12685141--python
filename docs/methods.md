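# Methods

Definitions, conventions and estimator details for the `dimerlabel` package.
All lengths are in ångströms unless marked nm; q in Å⁻¹.

## Coordinate and array conventions

Volumes are numpy arrays with axes ordered (z, y, x); a coordinate in Å is
`index × voxel_size` (0-based). The tilt axis of the simulated single-axis
acquisition is y; the beam direction is z. 2D images use (row, col) = (y, x).

## Geometry model

For monomer diameter *D* and center-to-center separation *d*:
gap = *d − D*, end-to-end = *d + D*, sphere volume (4/3)πr³. The label
footprint is *n* times the single-core volume (spheres in a dimer do not
overlap at *d > D*).

Linker span: a dithiol linker attached at surface points subtending an angle φ
to the interparticle axis spans L(φ) = √(L₉₀² + (L₀² − L₉₀²)cos²φ), with
L₀ = 10.6 Å (S-to-S along the axis) and L₉₀ = 7.5 Å. A single linker can
bridge gaps in [L₉₀, L₀]; chains of *n* ≥ 2 linkers bridge [0, n·L₀].

Reach model: label center to target membrane = epitope height (135 Å)
plus Fab reach (−10 to +40 Å) plus label offset (15 Å) → [110, 190] Å window.

## SAXS models and PDDF inversion

Sphere form amplitude Φ(x) = 3(sin x − x cos x)/x³ (Taylor series below
x = 0.05 to avoid cancellation); optional shell term. Orientation-averaged
dimer intensity: I(q) = 2 I_s(q)[1 + sinc(qd)], sinc(x) = sin(x)/x.

Indirect transform (Moore): p(r) = Σₙ aₙ sin(nπr/D) on [0, D],
I(q) = 4π∫ p(r)·sin(qr)/(qr) dr evaluated by trapezoid quadrature (800 nodes).
For each candidate D the series order is capped at the Shannon channel count
⌊q_max·D/π⌋ + 2; designs with condition number > 10¹² are rejected. Weights
are 1/σ² when uncertainties are supplied, uniform otherwise (1/I weighting
locks onto form-factor minima and is not used).

**D_max selection.** The residual as a function of candidate D is flat above
the true support, so a plain arg-min is unstable. The estimator instead:

1. scans D over `dmax_scan` at `scan_step`, keeping candidates *admissible*
   if min p(r) ≥ −1 % of max p(r) on a fine r grid;
2. finds the contiguous plateau of admissible candidates whose residual is
   within a factor τ of the best admissible residual, starting from the
   smallest admissible D (τ = 10 noise-free, where residual differences
   reflect only series resolution; τ = 1 + 2√(2/N) when σ is given);
3. reports the plateau midpoint and refits there.

Verified against Monte-Carlo p(r) oracles (10⁶ pairs): noiseless dimer
(R = 12.5, d = 40) → D_max = 65.0 exactly; sphere R_g = √(3/5)·R to 0.01 %;
SNR-50 noisy profiles → D_max within 5 %.

Guinier: weighted LSQ of ln I vs q² restricted to q·R_g < 1.3.

## Synthetic scenes

Projections use the chord model: a sphere of radius R projects to
2√(R² − ρ²)·contrast. **SNR convention:** SNR = peak noiseless particle
intensity / noise SD. A class average of *n* noisy single-particle renders
sharing one truth is distributionally the noiseless render plus
N(0, σ²/n) noise, and is sampled in that O(1) form directly.

Volumes rasterize spheres with a one-voxel antialiased edge; membranes are
0.5·contrast slabs. Particle placement enforces a minimum center distance and
a minimum lobe-to-lobe distance across particles, with a retry cap that raises
`PlacementError` when the scene is over-packed.

**Missing wedge.** The Fourier mask keeps coefficients whose in-plane angle
ψ = atan2(k_z, k_x) folds into the tilt range (ψ, ψ ± 180°), plus the DC
line, then is symmetrized exactly on the negated index grid so Hermitian
symmetry holds on Nyquist planes even for asymmetric ranges. The closed range
(−90°, +90°) is accepted and is the exact identity.

## 2D metrology

Background: border-pixel median subtraction, floored at 0. Recentering:
Fourier shift to the intensity centroid, iterated to 0.01 px, with a
reliability guard (peak ≥ 5× MAD above median) that rejects signal-free
images. Radial profiles: 1-px annuli via bincount, particle-count-weighted
across class averages, normalized to max = 1, empty central annuli filled by
interpolation. Cutoff radii r₅₀/r₂₀/r₁₀: outermost descending crossing with
linear interpolation.

Separation: iterative two-centroid split — principal-axis split of the
supported pixels (intensity ≥ 10 % of max; the support mask removes the
zero-floored noise pedestal, which otherwise biases centroids outward by
~0.5 Å), re-split at the centroid midpoint until converged; classes without a
central dip ≥ 0.1 are rejected. Histograms use 2 Å bins on [26, 46) with an
overflow bucket; the representative value is the particle-weighted mean ± SD.

## 3D discrimination

Detector: Laplacian-of-Gaussian at σ = 13.2 Å, local maxima above 0.2× the
max response *and* above 6× the MAD-estimated noise σ of the band-passed
volume (the noise gate makes empty noisy volumes yield zero picks in typical
sizes), merged within σ, centers refined by 3³ center-of-mass.

Pairing: mutual nearest neighbors within [26, 46] Å (upper edge ×1.15 when a
wedge was applied, compensating apparent elongation), greedy by distance with
deterministic index tie-breaks.

Classification: a paired candidate is a dimer if the dumbbell dip score
≥ 0.1, or if the pair axis is near z (|axis_z| ≥ 0.5) under a wedge — axial
dimers legitimately lose their central dip to the wedge. Weak-dip in-plane
pairs are dissolved into monomers. Merged axial dimers are rescued by
integrated cylinder mass (r_xy = 22 Å, half-height 80 Å): the cylinder
integrates the z-projection, which the k_z = 0 Fourier plane preserves under
any wedge, so a leftover pick with ≥ 2× the median leftover mass is a dimer
(separation unresolved, reported as None).

Evaluation: greedy nearest-neighbor truth matching at 20 Å tolerance;
accuracy = correctly classified truths / all truths. The nearest-neighbor
confusion sweep regenerates monomer-pair scenes over a spacing grid and
reports accuracy, its standard error, and the monomer-pair→dimer confusion
fraction. Below ~40 Å spacing the sweep is not monotone: monomer pairs merge
into single picks and read as monomers again.

## Membranes and statistics

Plane distances are |(x − p)·n̂|; mesh distances use exact point-to-triangle
projection (trimesh) over all faces. Cleft widths project paired samples onto
the postsynaptic plane normal; a plane tilted by θ relative to the gap
yields mean width 280·cos θ for a 280 Å parallel gap. Condition comparisons
use Welch's t (unequal variances, Welch–Satterthwaite dof); identical
zero-variance samples return statistic 0, p = 1. Verified type-I error at
α = 0.05 is within [0.030, 0.072] over 1000 null replicates.

## Problem sizes

Test and acceptance scenes (e.g. 144³ voxels at 10 Å, 75 particles, 8 seeds;
20 classes × 1000 particles at SNR 3) are package choices sized to give tight
statistical checks within minutes on one CPU.

## Limitations

The synthetic data are deliberately minimal: no contrast transfer function,
no atomic gold lattice or coating shell, no tilt-series alignment errors or
reconstruction artifacts beyond the ideal Fourier wedge, additive white
Gaussian noise only, and spherical homogeneous particles. The discrimination
accuracy and confusion limits therefore characterize the geometric task under
the wedge, not detector performance on experimental tomograms. The SAXS
module models dilute, monodisperse, orientation-averaged scatterers without
structure factor or polydispersity. MRC support covers read modes 0/1/2 and
write mode 2; STAR parsing covers simple `loop_` blocks only.
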