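"""Single-section podocyte stereology and Weibel–Gomez glomerular volumetry.

This module implements the numerical core of slide-based podometrics:

* **Weibel–Gomez volumetry** — converts the mean 2-D glomerular profile
  area on a section to a mean 3-D glomerular volume,
  ``V = A^1.5 * beta / size_coef`` with the sphere coefficient
  ``beta = 1.38`` and a near-monodisperse size-distribution coefficient
  ``1.01``.

* **Thick-section caliper correction** — on a section of true thickness
  ``T`` a nucleus of true caliper diameter ``D`` presents an apparent
  diameter ``d`` that mixes equatorial and cap profiles.  ``D`` is
  recovered as the positive root of ``k*D**2 + (T - d)*D - d*T = 0``
  where ``k`` is a dimensionless nuclear shape coefficient
  (``k = pi/4`` for perfect spheres; ``k = 0.72`` for podocyte nuclei).

* **Single-section density** — the number of nuclei seen per slide area
  overcounts the per-volume numerical density because a thick section
  samples a slab of height ``T + D``.  The correction factor
  ``CF = T / (T + D)`` converts detected counts into a density
  ``n * CF / (T * total_tuft_area)``.

* **Nuclear volumetry** — podocyte nuclear volume from the apparent
  diameter, ``V_nuc = 32 / (3 * pi**2) * d**3`` (the volume of a sphere
  whose diameter is ``(4/pi) * d``).

All lengths are micrometres, areas μm², volumes μm³, densities μm⁻³.
Formulas are applied per subject to subject-level summaries (mean
profile area, mean apparent diameter, slide totals); cohort means are
means of per-subject results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING  # noqa: F401 - SlideMorphometry hint

if TYPE_CHECKING:  # pragma: no cover
    from .histology import SlideMorphometry

__all__ = [
    "SectionSpec",
    "PodometricResult",
    "weibel_gomez_volume",
    "caliper_root",
    "true_caliper_diameter",
    "correction_factor",
    "podocyte_density",
    "nuclear_volume_from_apparent_diameter",
    "compose_podometrics",
    "report_scaled",
]

#: Shape coefficient of a perfect sphere: mean caliper projection factor.
SPHERE_SHAPE_K = math.pi / 4.0


@dataclass(frozen=True)
class SectionSpec:
    """Physical parameters of a histological section.

    Parameters
    ----------
    thickness_T:
        True section thickness in μm (Z-distance between the uppermost
        and lowermost in-focus tissue planes); per-subject scalar, with
        the cohort mean 4.54 μm as the fallback default.
    shape_k:
        Dimensionless nuclear shape coefficient in (0, 1]; 0.72 for
        podocyte nuclei, ``pi/4`` for perfect spheres.
    wg_beta:
        Weibel–Gomez shape coefficient (1.38 for spheres).
    wg_size_coef:
        Weibel–Gomez size-distribution coefficient (1.01, assuming a
        near-monodisperse glomerular population).
    """

    thickness_T: float = 4.54
    shape_k: float = 0.72
    wg_beta: float = 1.38
    wg_size_coef: float = 1.01

    def __post_init__(self) -> None:
        if not self.thickness_T > 0:
            raise ValueError(f"thickness_T must be > 0, got {self.thickness_T}")
        if not 0 < self.shape_k <= 1:
            raise ValueError(f"shape_k must be in (0, 1], got {self.shape_k}")
        if self.wg_beta <= 0 or self.wg_size_coef <= 0:
            raise ValueError("Weibel-Gomez coefficients must be positive")


@dataclass(frozen=True)
class PodometricResult:
    """Per-subject derived podometric quantities (all in μm-based units)."""

    subject_id: str
    glomerular_volume: float  # μm³
    apparent_d: float  # μm
    true_D: float  # μm
    correction_factor: float  # dimensionless, in (0, 1]
    podocyte_density: float  # per μm³
    podocyte_count: float  # per glomerulus
    nuclear_volume: float  # μm³
    total_nuclear_volume: float  # μm³ per glomerulus

    def __post_init__(self) -> None:
        if not 0 < self.correction_factor <= 1:
            raise ValueError("correction_factor must be in (0, 1]")
        for name in ("glomerular_volume", "apparent_d", "true_D",
                     "podocyte_density", "podocyte_count",
                     "nuclear_volume", "total_nuclear_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def weibel_gomez_volume(mean_profile_area: float, spec: SectionSpec = SectionSpec()) -> float:
    """Mean glomerular volume (μm³) from the mean tuft profile area (μm²).

    ``V = A^1.5 * beta / size_coef``.  Exact for spheres up to the ~1%
    bias of the A^1.5 transform on the section-area distribution.
    """
    if mean_profile_area < 0:
        raise ValueError(f"mean_profile_area must be >= 0, got {mean_profile_area}")
    return mean_profile_area ** 1.5 * spec.wg_beta / spec.wg_size_coef


def caliper_root(apparent_d: float, thickness_T: float, shape_k: float) -> float:
    """Positive root of ``k*D**2 + (T - d)*D - d*T = 0``.

    Low-level form of :func:`true_caliper_diameter` that also admits the
    ``T = 0`` thin-section limit (``D = d / k``).
    """
    if apparent_d < 0:
        raise ValueError(f"apparent_d must be >= 0, got {apparent_d}")
    if thickness_T < 0:
        raise ValueError(f"thickness_T must be >= 0, got {thickness_T}")
    if not 0 < shape_k <= 1:
        raise ValueError(f"shape_k must be in (0, 1], got {shape_k}")
    b = apparent_d - thickness_T
    return (b + math.sqrt(b * b + 4.0 * shape_k * apparent_d * thickness_T)) / (2.0 * shape_k)


def true_caliper_diameter(apparent_d: float, spec: SectionSpec = SectionSpec()) -> float:
    """True nuclear caliper diameter D (μm) from the apparent diameter d.

    ``D = [(d - T) + sqrt((d - T)**2 + 4*k*d*T)] / (2*k)``; strictly
    increasing and continuous in ``d``, with ``D(0) = 0``.
    """
    return caliper_root(apparent_d, spec.thickness_T, spec.shape_k)


def correction_factor(true_D: float, spec: SectionSpec = SectionSpec()) -> float:
    """Single-section counting correction ``CF = (D/T + 1)^-1 = T/(T + D)``.

    The fraction of the slab of height ``T + D`` (in which a nucleus of
    diameter ``D`` is visible) occupied by the physical section.
    """
    if true_D < 0:
        raise ValueError(f"true_D must be >= 0, got {true_D}")
    return spec.thickness_T / (spec.thickness_T + true_D)


def podocyte_density(
    n_detected: float,
    cf: float,
    total_tuft_area: float,
    spec: SectionSpec = SectionSpec(),
) -> float:
    """Podocyte numerical density (μm⁻³) by the single-section method.

    ``density = n_detected * CF / (T * total_tuft_area)``.
    """
    if n_detected < 0:
        raise ValueError(f"n_detected must be >= 0, got {n_detected}")
    if not total_tuft_area > 0:
        raise ValueError(f"total_tuft_area must be > 0, got {total_tuft_area}")
    if not 0 < cf <= 1:
        raise ValueError(f"cf must be in (0, 1], got {cf}")
    return n_detected * cf / (spec.thickness_T * total_tuft_area)


def nuclear_volume_from_apparent_diameter(apparent_d: float) -> float:
    """Podocyte nuclear volume (μm³): ``32 / (3*pi**2) * d**3``.

    Equivalently the volume of a sphere of true diameter ``(4/pi) * d``,
    i.e. the apparent profile diameter rescaled by the spherical mean
    caliper factor.
    """
    if apparent_d < 0:
        raise ValueError(f"apparent_d must be >= 0, got {apparent_d}")
    return 32.0 / (3.0 * math.pi ** 2) * apparent_d ** 3


def compose_podometrics(summary: "SlideMorphometry", spec: SectionSpec = SectionSpec()) -> PodometricResult:
    """Chain the stereological formulas on a per-subject slide summary.

    Takes the subject-level summary (mean profile area, slide-total tuft
    area, nucleus count, mean apparent diameter) and returns the derived
    podometrics: glomerular volume, D, CF, density, podocyte count per
    glomerulus, nuclear volume and total nuclear volume per glomerulus.
    Density uses the shape-corrected ``D``; nuclear volume uses the
    uncorrected ``(4/pi) * d`` spherical rescaling.
    """
    volume = weibel_gomez_volume(summary.mean_profile_area, spec)
    d = summary.mean_apparent_d
    true_d = true_caliper_diameter(d, spec)
    cf = correction_factor(true_d, spec)
    density = podocyte_density(summary.n_nuclei, cf, summary.total_tuft_area, spec)
    count = density * volume
    nuc_vol = nuclear_volume_from_apparent_diameter(d)
    return PodometricResult(
        subject_id=summary.subject_id,
        glomerular_volume=volume,
        apparent_d=d,
        true_D=true_d,
        correction_factor=cf,
        podocyte_density=density,
        podocyte_count=count,
        nuclear_volume=nuc_vol,
        total_nuclear_volume=count * nuc_vol,
    )


def report_scaled(result: PodometricResult) -> dict:
    """Rescale a result to reporting units with 1-decimal rounding.

    Glomerular volume in ×10⁶ μm³, density per 10⁶ μm³, total nuclear
    volume in ×10⁵ μm³; diameters in μm, CF to 3 decimals.
    """
    return {
        "subject_id": result.subject_id,
        "glomerular_volume_1e6_um3": round(result.glomerular_volume / 1e6, 1),
        "podocyte_density_per_1e6_um3": round(result.podocyte_density * 1e6, 1),
        "podocyte_count": round(result.podocyte_count, 1),
        "apparent_d_um": round(result.apparent_d, 1),
        "true_D_um": round(result.true_D, 1),
        "correction_factor": round(result.correction_factor, 3),
        "nuclear_volume_um3": round(result.nuclear_volume, 1),
        "total_nuclear_volume_1e5_um3": round(result.total_nuclear_volume / 1e5, 1),
    }
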