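"""Geometric models for dimeric gold-nanoparticle labels.

Covers the arithmetic that motivates the dimeric-label design: sphere-volume
footprints of candidate fiducials, the interparticle gap implied by the
measured center-to-center separation and monomer diameter, the
torsion-dependent S-S span of the biphenyl-4,4'-dithiol (BPDT) cross-linker
and whether n linkers in series can bridge the gap, and a one-dimensional
reach model for the expected label-to-membrane distance window.

All lengths are in Angstrom unless a function says otherwise; volumes are
reported in nm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class DimerGeometry:
    """Center-to-center separation vs monomer diameter bookkeeping.

    gap = d - D is the surface-to-surface distance the cross-linkers must
    bridge; end_to_end = d + D is the outer extent of the dumbbell.
    """

    separation_d: float
    monomer_diameter_D: float
    gap: float = field(init=False)
    end_to_end: float = field(init=False)

    def __post_init__(self) -> None:
        if self.separation_d <= 0 or self.monomer_diameter_D <= 0:
            raise ValueError("separation and diameter must be positive")
        object.__setattr__(self, "gap", self.separation_d - self.monomer_diameter_D)
        object.__setattr__(
            self, "end_to_end", self.separation_d + self.monomer_diameter_D
        )


@dataclass(frozen=True)
class LinkerModel:
    """A dithiol cross-linker whose S-S span depends on the biphenyl torsion.

    length_at_phi0 is the span at torsion 0 deg (rings coplanar, maximal),
    length_at_phi90 at 90 deg (rings perpendicular, minimal). n_linkers
    counts rigid segments joined in series by flexible disulfide joints.
    """

    length_at_phi0: float = 10.6
    length_at_phi90: float = 7.5
    n_linkers: int = 1
    joint_flexible: bool = True

    def __post_init__(self) -> None:
        if self.length_at_phi90 > self.length_at_phi0:
            raise ValueError("span at phi=90 must not exceed span at phi=0")
        if self.n_linkers < 1:
            raise ValueError("n_linkers must be >= 1")


@dataclass(frozen=True)
class ReachModel:
    """1-D normal-to-membrane reach of a Fab-tethered dimeric label.

    Defaults are calibrated so the reach window reproduces the 110-190 A
    label-to-postsynaptic-membrane window predicted from single-particle
    structural models; they are package calibrations, not measured lengths.
    fab_reach_min may be negative (Fab folded back toward the membrane).
    """

    epitope_height: float = 135.0
    fab_reach_min: float = -10.0
    fab_reach_max: float = 40.0
    label_offset: float = 15.0

    def __post_init__(self) -> None:
        if self.fab_reach_min > self.fab_reach_max:
            raise ValueError("fab_reach_min must be <= fab_reach_max")
        if self.epitope_height < 0 or self.label_offset < 0:
            raise ValueError("epitope_height and label_offset must be >= 0")


def sphere_volume(radius_nm: float) -> float:
    """Volume (4/3)*pi*r^3 of a sphere, radius in nm, volume in nm^3."""
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    return (4.0 / 3.0) * math.pi * radius_nm**3


def label_footprint(n_particles: int, radius_nm: float) -> float:
    """Combined volume (nm^3) of an n-particle label of equal spheres."""
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    return n_particles * sphere_volume(radius_nm)


def interparticle_gap(geometry: DimerGeometry) -> float:
    """Surface-to-surface gap d - D between the two monomers of a dimer."""
    return geometry.gap


def linker_span(model: LinkerModel, phi_deg: float) -> float:
    """Single-linker S-S span at biphenyl torsion phi (degrees, 0..90).

    Smooth interpolation L(phi) = sqrt(L90^2 + (L0^2 - L90^2) cos^2 phi);
    exact at both endpoints and monotone non-increasing in phi.
    """
    if not 0.0 <= phi_deg <= 90.0:
        raise ValueError("phi must be in [0, 90] degrees")
    l0sq = model.length_at_phi0**2
    l90sq = model.length_at_phi90**2
    c = math.cos(math.radians(phi_deg))
    return math.sqrt(l90sq + (l0sq - l90sq) * c * c)


def bridge_feasible(gap: float, model: LinkerModel) -> tuple[bool, tuple[float, float]]:
    """Can n linkers in series bridge `gap`? Returns (feasible, [lo, hi]).

    Each rigid segment has length in [L90, L0]; with free joints two or more
    segments can fold back to zero net span, so the reachable interval is
    [0, n*L0] for n >= 2 and [L90, L0] for a single linker.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    n = model.n_linkers
    hi = n * model.length_at_phi0
    lo = model.length_at_phi90 if n == 1 else 0.0
    return (lo <= gap <= hi), (lo, hi)


def reach_range(model: ReachModel) -> tuple[float, float]:
    """[min, max] distance (A) from dimer center to the target membrane."""
    lo = model.epitope_height + model.fab_reach_min - model.label_offset
    hi = model.epitope_height + model.fab_reach_max + model.label_offset
    return (max(lo, 0.0), max(hi, 0.0))


def in_reach(distance: float, reach: tuple[float, float]) -> bool:
    """True if distance lies in the closed reach interval."""
    lo, hi = reach
    if lo > hi:
        raise ValueError("invalid reach interval")
    return lo <= distance <= hi
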