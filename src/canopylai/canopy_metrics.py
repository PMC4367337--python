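"""Crown porosity, zenith clumping index and Beer's-law LAI.

From the cover fractions of the gap analysis the method derives

    crown porosity      Φ    = 1 − f_f / f_c
    clumping index      Ω(0) = (1 − Φ) · ln(1 − f_f) / (ln(Φ) · f_f)
    effective LAI       LAI  = −f_c · (ln(Φ) / k) · Ω(0)

with k the light extinction coefficient.  Inverting the LAI expression with
a destructively measured LAI gives the measured extinction coefficient

    k_M = −f_c · (ln(Φ) / LAI_D) · Ω(0)

Ω(0) ≤ 1 quantifies foliage aggregation into crowns (1 = random dispersion);
it corrects the simple Beer's-law inversion for the clumped canopies of
orchard trees.  All logarithms are natural.

Degenerate covers: an empty canopy (f_f = 0) has LAI 0 by definition;
as the canopy closes (Φ → 0 or f_f → 1) the gap-fraction inversion
saturates, handled through an algebraically equivalent Φ-free form with an
ε-guard.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "CanopyStructure",
    "LaiEstimate",
    "InvertedK",
    "SaturationWarning",
    "crown_porosity",
    "clumping_index",
    "lai_from_cover",
    "invert_k",
    "destructive_lai",
]

#: tolerance for validating fractions against [0, 1] (pooled floating-point
#: drift within this bound is clamped; larger violations raise)
FRACTION_TOL = 1e-9

#: porosity below which the Φ-free algebraic form of the LAI equation is used
EPS_POROSITY = 1e-9


class SaturationWarning(UserWarning):
    """Emitted when gap fractions are at the edge of the invertible domain
    (Φ = 0 or f_f → 1): the Beer's-law inversion saturates."""


def _checked_fraction(x: float, name: str) -> float:
    if not -FRACTION_TOL <= x <= 1.0 + FRACTION_TOL:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return min(max(x, 0.0), 1.0)


@dataclass(frozen=True)
class CanopyStructure:
    """Cover fractions with the derived porosity and clumping index."""

    f_f: float
    f_c: float
    phi: float
    omega0: float


@dataclass(frozen=True)
class LaiEstimate:
    """An LAI value together with the extinction coefficient that produced it."""

    lai: float
    k_used: float
    method_tag: str = "constant_k"

    def __post_init__(self) -> None:
        if self.lai < 0:
            raise ValueError("LAI cannot be negative")


@dataclass(frozen=True)
class InvertedK:
    """Extinction coefficient measured by inverting Beer's law against a
    destructively measured LAI."""

    k_M: float
    lai_D: float


def crown_porosity(f_f: float, f_c: float) -> float:
    """Φ = 1 − f_f/f_c: the gap share of the area inside crown envelopes."""
    f_f = _checked_fraction(f_f, "f_f")
    f_c = _checked_fraction(f_c, "f_c")
    if f_c == 0.0:
        raise ValueError("no crown cover: f_c = 0, porosity undefined")
    if f_f > f_c:
        raise ValueError(f"f_f ({f_f}) cannot exceed f_c ({f_c})")
    return 1.0 - f_f / f_c


def clumping_index(f_f: float, phi: float) -> float:
    """Zenith clumping index Ω(0) = (1 − Φ)·ln(1 − f_f) / (ln(Φ)·f_f).

    When the crown fills the frame (f_c = 1, so Φ = 1 − f_f) the numerator
    and denominator coincide and Ω(0) = 1: no between-crown clumping.

    At Φ = 0 the limit is 0 (a :class:`SaturationWarning` flags it); the
    product ln(Φ)·Ω(0) used by the LAI equation stays finite there.
    """
    f_f = _checked_fraction(f_f, "f_f")
    phi = _checked_fraction(phi, "phi")
    if f_f >= 1.0:
        raise ValueError("saturated foliage cover: f_f = 1 makes ln(1 - f_f) undefined")
    if f_f == 0.0:
        raise ValueError("f_f = 0: clumping index undefined (LAI is 0 by definition)")
    if phi == 0.0:
        warnings.warn(
            "phi = 0: clumping index at its saturation limit 0",
            SaturationWarning,
            stacklevel=2,
        )
        return 0.0
    if phi == 1.0:
        raise ValueError("phi = 1 with f_f > 0 is inconsistent (f_f = f_c*(1 - phi))")
    return (1.0 - phi) * math.log(1.0 - f_f) / (math.log(phi) * f_f)


def lai_from_cover(
    f_c: float,
    phi: float,
    omega0: float,
    k: float,
    method_tag: str = "constant_k",
) -> LaiEstimate:
    """Effective leaf area index LAI = −f_c·(ln(Φ)/k)·Ω(0).

    Near Φ = 0 the direct product is 0·∞; there the algebraically
    equivalent Φ-free form

        LAI = −f_c·(1 − Φ)·ln(1 − f_f) / (k·f_f),   f_f = f_c·(1 − Φ)

    is evaluated instead (identical wherever both are defined, because the
    clumping index satisfies ln(Φ)·Ω(0) = (1 − Φ)·ln(1 − f_f)/f_f).
    """
    if k <= 0:
        raise ValueError(f"extinction coefficient must be positive, got {k}")
    f_c = _checked_fraction(f_c, "f_c")
    phi = _checked_fraction(phi, "phi")
    f_f = f_c * (1.0 - phi)
    if f_f == 0.0:
        return LaiEstimate(0.0, k, method_tag)  # empty canopy
    if phi == 1.0:
        raise ValueError("phi = 1 with foliage present is inconsistent input")
    if phi < EPS_POROSITY or f_f >= 1.0 - EPS_POROSITY:
        warnings.warn(
            "cover fractions at the saturation edge; "
            "LAI computed from the gap-free algebraic form",
            SaturationWarning,
            stacklevel=2,
        )
        if f_f >= 1.0:
            raise ValueError("f_f = 1: fully closed canopy, LAI unbounded")
        lai = -f_c * (1.0 - phi) * math.log(1.0 - f_f) / (k * f_f)
    else:
        lai = -f_c * (math.log(phi) / k) * omega0
    return LaiEstimate(lai, k, method_tag)


def invert_k(f_c: float, phi: float, omega0: float, lai_D: float) -> InvertedK:
    """Measured extinction coefficient k_M = −f_c·(ln(Φ)/LAI_D)·Ω(0).

    Exact inverse of :func:`lai_from_cover` in k: feeding k_M back
    reproduces ``lai_D``.
    """
    if lai_D <= 0:
        raise ValueError(f"destructive LAI must be positive, got {lai_D}")
    f_c = _checked_fraction(f_c, "f_c")
    phi = _checked_fraction(phi, "phi")
    if not 0.0 < phi < 1.0:
        raise ValueError(f"inversion requires 0 < phi < 1, got {phi}")
    k_M = -f_c * (math.log(phi) / lai_D) * omega0
    return InvertedK(k_M=k_M, lai_D=lai_D)


def destructive_lai(
    total_leaf_mass: float,
    sla: float,
    row_spacing: float,
    plant_spacing: float,
) -> float:
    """Ground-truth LAI from defoliation data.

    Total leaf area = leaf mass (g) × specific leaf area (cm²/g), divided
    by the ground area assigned per tree (row spacing × plant spacing, m²).
    """
    for name, v in (
        ("total_leaf_mass", total_leaf_mass),
        ("sla", sla),
        ("row_spacing", row_spacing),
        ("plant_spacing", plant_spacing),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    leaf_area_m2 = total_leaf_mass * sla * 1e-4  # cm² → m²
    return leaf_area_m2 / (row_spacing * plant_spacing)
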