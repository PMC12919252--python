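"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators:

* **Sphere–slab sections** — nuclei modelled as monodisperse spheres of
  diameter ``D`` intersecting a slab of thickness ``T``.  A sphere is
  visible iff its centre lies within ``D/2`` of the slab; the apparent
  diameter is ``D`` for centres inside the slab and the cap-circle
  diameter otherwise.  The closed-form mean apparent diameter
  ``D*(T + (pi/4)*D)/(T + D)`` and the visible-count law
  ``counts/area = N_v*(T + D)`` make this the independent oracle for
  the single-section stereology.

* **Slide fixtures** — GeoJSON tuft/nucleus annotation files with
  circular tuft profiles drawn from the sphere-section law for
  lognormally sized glomeruli, and nuclei placed at the count implied
  by a target numerical density; ground truth accompanies the file.

* **CT phantoms** — an elliptical soft-tissue body with an abdominal
  cavity and fat patches at −90 HU totalling an exact pixel count, for
  VAT-segmentation recovery tests.

* **Cohorts** — per-subject covariates and morphometrics drawn per VO
  group, with ΔeGFR carrying a configurable standardized effect.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ct import CTSlice
from .histology import (
    CLASS_NUCLEUS,
    CLASS_TUFT,
    CLASS_TUFT_SCLEROTIC,
)

__all__ = [
    "SphereSlabSim",
    "SyntheticCohortSpec",
    "expected_mean_apparent_d",
    "apparent_diameters",
    "simulate_sphere_sections",
    "simulate_density_section",
    "generate_slide_fixture",
    "generate_ct_phantom",
    "save_phantom_nifti",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# Sphere-slab stereology oracle
# ---------------------------------------------------------------------------

@dataclass
class SphereSlabSim:
    """Monodisperse sphere-versus-slab sectioning experiment."""

    true_D: float  # μm, sphere diameter
    slab_T: float  # μm, slab (section) thickness
    n_spheres: int
    seed: int = 0
    visible_apparent_d: Optional[np.ndarray] = None  # filled by the simulator
    n_visible: Optional[int] = None

    def __post_init__(self) -> None:
        if self.true_D <= 0 or self.slab_T <= 0:
            raise ValueError("true_D and slab_T must be positive")
        if self.n_spheres < 1:
            raise ValueError("n_spheres must be >= 1")


def expected_mean_apparent_d(true_D: float, slab_T: float) -> float:
    """Closed-form mean apparent diameter over visible spheres.

    ``E[d] = D*(T + (pi/4)*D)/(T + D)``: equatorial profiles (diameter
    ``D``) for the fraction ``T/(T+D)`` of visible centres, cap circles
    (mean diameter ``(pi/4)*D``) for the rest.
    """
    return true_D * (slab_T + math.pi / 4.0 * true_D) / (slab_T + true_D)


def apparent_diameters(z: np.ndarray, true_D: float, slab_T: float) -> np.ndarray:
    """Apparent diameters for sphere centres ``z``; NaN where invisible.

    Centres in ``[0, T]`` show the full diameter; centres overshooting
    by ``h < D/2`` show the cap circle ``2*sqrt((D/2)**2 - h**2)``.
    """
    z = np.asarray(z, dtype=float)
    r = true_D / 2.0
    overshoot = np.maximum(np.maximum(-z, z - slab_T), 0.0)
    with np.errstate(invalid="ignore"):
        d = 2.0 * np.sqrt(r * r - overshoot * overshoot)
    return np.where(overshoot < r, d, np.nan)


def simulate_sphere_sections(sim: SphereSlabSim) -> SphereSlabSim:
    """Fill a :class:`SphereSlabSim` with visible apparent diameters.

    Centres are uniform on an interval with a ``D/2`` margin around the
    visibility band ``[-D/2, T + D/2]``; deterministic given the seed.
    """
    rng = np.random.default_rng(sim.seed)
    r = sim.true_D / 2.0
    pad = r
    z = rng.uniform(-r - pad, sim.slab_T + r + pad, size=sim.n_spheres)
    d = apparent_diameters(z, sim.true_D, sim.slab_T)
    visible = d[np.isfinite(d)]
    return replace(sim, visible_apparent_d=visible, n_visible=int(visible.size))


def simulate_density_section(
    density_per_um3: float,
    true_D: float,
    slab_T: float,
    area_um2: float,
    seed: int = 0,
) -> dict:
    """Section a Poisson field of spheres of known numerical density.

    Sphere centres fill a box of footprint ``area_um2`` and a height
    covering the visibility band plus a margin, at the given density;
    returns the visible count and apparent diameters together with the
    ground truth, for testing the CF-corrected single-section
    estimator (expected visible count per area is ``N_v * (T + D)``).
    """
    if density_per_um3 <= 0 or area_um2 <= 0:
        raise ValueError("density and area must be positive")
    rng = np.random.default_rng(seed)
    r = true_D / 2.0
    pad = r
    lo, hi = -r - pad, slab_T + r + pad
    n_total = rng.poisson(density_per_um3 * area_um2 * (hi - lo))
    z = rng.uniform(lo, hi, size=n_total)
    d = apparent_diameters(z, true_D, slab_T)
    visible = d[np.isfinite(d)]
    return {
        "density_truth": density_per_um3,
        "true_D": true_D,
        "slab_T": slab_T,
        "area_um2": area_um2,
        "n_visible": int(visible.size),
        "apparent_d": visible,
    }


# ---------------------------------------------------------------------------
# Slide annotation fixtures
# ---------------------------------------------------------------------------

def _circle_polygon(cx: float, cy: float, area: float, n_vertices: int) -> list[list[float]]:
    """Regular n-gon centred at (cx, cy) whose polygon area is exact."""
    # polygon area of a regular n-gon with circumradius R is (n/2) R^2 sin(2pi/n)
    factor = 0.5 * n_vertices * math.sin(2.0 * math.pi / n_vertices)
    radius = math.sqrt(area / factor)
    angles = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return [[cx + radius * math.cos(a), cy + radius * math.sin(a)] for a in angles]


def generate_slide_fixture(
    path: str | Path,
    n_glomeruli: int = 300,
    volume_mean_um3: float = 2.4e6,
    volume_cv: float = 0.3,
    density_per_um3: float = 210e-6,
    nucleus_D: float = 7.0,
    thickness_T: float = 4.54,
    sclerotic_fraction: float = 0.02,
    pixel_size: float = 0.5,
    seed: int = 0,
    truth_path: str | Path | None = None,
) -> dict:
    """Write a GeoJSON slide annotation fixture plus its ground truth.

    Tuft profile areas follow the sphere-section law (uniform chord
    offset) for lognormally distributed glomerular volumes; each
    nonsclerotic tuft receives ``Poisson(N_v * area * (T + D))``
    spherical nuclei whose apparent diameters follow the sphere-slab
    law.  Sclerotic tufts carry no nuclei.  Returns (and optionally
    writes) the truth record.
    """
    if min(volume_mean_um3, density_per_um3, nucleus_D, thickness_T, pixel_size) <= 0:
        raise ValueError("all physical parameters must be positive")
    if not 0 <= sclerotic_fraction <= 1:
        raise ValueError("sclerotic_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    features: list[dict] = []
    tuft_truth: list[dict] = []
    if n_glomeruli > 0:
        sigma2 = math.log(1.0 + volume_cv ** 2)
        mu = math.log(volume_mean_um3) - sigma2 / 2.0
        volumes = rng.lognormal(mu, math.sqrt(sigma2), size=n_glomeruli)
        radii = (3.0 * volumes / (4.0 * math.pi)) ** (1.0 / 3.0)
        # sphere-section profile radius at a uniform chord offset
        offsets = rng.uniform(-radii, radii)
        profile_r = np.sqrt(np.maximum(radii ** 2 - offsets ** 2, 1e-6))
        sclerotic = rng.random(n_glomeruli) < sclerotic_fraction

        n_cols = max(1, int(math.ceil(math.sqrt(n_glomeruli))))
        spacing = 2.0 * float(profile_r.max()) + 4.0 * nucleus_D
        nucleus_r = nucleus_D / 2.0
        for i in range(n_glomeruli):
            cx = (i % n_cols + 0.5) * spacing
            cy = (i // n_cols + 0.5) * spacing
            area = math.pi * profile_r[i] ** 2
            cls = CLASS_TUFT_SCLEROTIC if sclerotic[i] else CLASS_TUFT
            features.append(_feature(_circle_polygon(cx, cy, area, 64), cls, pixel_size))
            n_nuc = 0
            if not sclerotic[i]:
                n_nuc = int(rng.poisson(density_per_um3 * area * (thickness_T + nucleus_D)))
                for _ in range(n_nuc):
                    # nucleus centroid strictly inside the tuft profile
                    rad = (profile_r[i] - nucleus_r) * math.sqrt(rng.random())
                    rad = max(rad, 0.0)
                    theta = rng.uniform(0.0, 2.0 * math.pi)
                    nx, ny = cx + rad * math.cos(theta), cy + rad * math.sin(theta)
                    z = rng.uniform(-nucleus_r, thickness_T + nucleus_r)
                    d_app = float(apparent_diameters(np.array([z]), nucleus_D, thickness_T)[0])
                    if not math.isfinite(d_app) or d_app <= 0:
                        d_app = 1e-3  # grazing section: keep a degenerate detection
                    nuc_area = math.pi * (d_app / 2.0) ** 2
                    features.append(
                        _feature(_circle_polygon(nx, ny, nuc_area, 16), CLASS_NUCLEUS, pixel_size)
                    )
            tuft_truth.append(
                {"area_um2": area, "sclerotic": bool(sclerotic[i]), "n_nuclei": n_nuc}
            )

    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    nonscl = [t for t in tuft_truth if not t["sclerotic"]]
    truth = {
        "n_glomeruli": n_glomeruli,
        "n_sclerotic": sum(t["sclerotic"] for t in tuft_truth),
        "density_per_um3": density_per_um3,
        "nucleus_D": nucleus_D,
        "thickness_T": thickness_T,
        "pixel_size": pixel_size,
        "seed": seed,
        "mean_profile_area_um2": float(np.mean([t["area_um2"] for t in nonscl])) if nonscl else 0.0,
        "total_tuft_area_um2": float(np.sum([t["area_um2"] for t in nonscl])) if nonscl else 0.0,
        "n_nuclei": int(sum(t["n_nuclei"] for t in tuft_truth)),
        "tufts": tuft_truth,
    }
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(truth))
    return truth


def _feature(ring_um: list[list[float]], cls: str, pixel_size: float) -> dict:
    ring_px = [[x / pixel_size, y / pixel_size] for x, y in ring_um]
    return {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [ring_px]},
        "properties": {"classification": cls},
    }


# ---------------------------------------------------------------------------
# CT phantom
# ---------------------------------------------------------------------------

HU_AIR = -1000.0
HU_SOFT_TISSUE = 40.0
HU_FAT = -90.0


def generate_ct_phantom(
    fat_area_cm2: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    pixel_spacing: tuple[float, float] = (2.0, 2.0),
) -> tuple[CTSlice, dict]:
    """Abdominal CT phantom with an exact fat-pixel ground truth.

    An elliptical body at soft-tissue attenuation holds an elliptical
    abdominal cavity; fat is laid down as axis-aligned rectangles at
    −90 HU whose pixel count equals ``round(target / pixel_area)``
    exactly (rectangles are invariant under the radius-2 disk closing,
    so the segmentation truth survives post-processing).  Optional
    i.i.d. Gaussian HU noise.  Returns the slice and a truth record
    with the exact pixel count and seed coordinates.
    """
    if fat_area_cm2 < 0:
        raise ValueError("fat_area_cm2 must be >= 0")
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    cr, ccen = rows / 2.0, cols / 2.0
    body = ((rr - cr) / (0.42 * rows)) ** 2 + ((cc - ccen) / (0.46 * cols)) ** 2 <= 1.0
    cavity = ((rr - cr) / (0.33 * rows)) ** 2 + ((cc - ccen) / (0.37 * cols)) ** 2 <= 1.0

    hu = np.full(shape, HU_AIR)
    hu[body] = HU_SOFT_TISSUE

    pixel_area_cm2 = pixel_spacing[0] * pixel_spacing[1] / 100.0
    n_pixels = int(round(fat_area_cm2 / pixel_area_cm2))
    capacity = int(0.4 * cavity.sum())
    if n_pixels > capacity:
        raise ValueError(
            f"fat target of {n_pixels} px exceeds phantom cavity capacity {capacity} px"
        )

    # stack rectangles (height 10, width <= 100) centred in the cavity;
    # a possible sub-row remainder becomes its own 1-px strip
    rects: list[tuple[int, int, int, int]] = []  # (r0, c0, h, w)
    chunk_h, max_w, gap = 10, 100, 8
    remaining = n_pixels
    plan: list[tuple[int, int]] = []  # (h, w) per rectangle
    while remaining >= chunk_h:
        w = min(max_w, remaining // chunk_h)
        plan.append((chunk_h, w))
        remaining -= chunk_h * w
    if remaining > 0:
        plan.append((1, remaining))
    total_h = sum(h for h, _ in plan) + gap * max(0, len(plan) - 1)
    r0 = int(cr - total_h / 2.0)
    for h, w in plan:
        c0 = int(ccen - w / 2.0)
        rects.append((r0, c0, h, w))
        r0 += h + gap

    fat_mask = np.zeros(shape, dtype=bool)
    seeds: list[tuple[int, int]] = []
    for r0, c0, h, w in rects:
        block = cavity[r0 : r0 + h, c0 : c0 + w]
        if block.shape != (h, w) or not block.all():
            raise ValueError("fat rectangle does not fit inside the cavity")
        fat_mask[r0 : r0 + h, c0 : c0 + w] = True
        seeds.append((r0 + h // 2, c0 + w // 2))
    assert int(fat_mask.sum()) == n_pixels
    hu[fat_mask] = HU_FAT
    if noise_sd > 0:
        hu = hu + np.random.default_rng(seed).normal(0.0, noise_sd, size=shape)

    ct = CTSlice(hu=hu, pixel_spacing=pixel_spacing, cavity_mask=cavity)
    truth = {
        "n_fat_pixels": n_pixels,
        "fat_area_cm2": n_pixels * pixel_area_cm2,
        "pixel_area_cm2": pixel_area_cm2,
        "seeds": seeds,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return ct, truth


def save_phantom_nifti(ct: CTSlice, image_path: str | Path, mask_path: str | Path) -> None:
    """Write a phantom slice and its cavity mask as NIfTI files."""
    import nibabel as nib

    affine = np.diag([ct.pixel_spacing[0], ct.pixel_spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(ct.hu.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(ct.cavity_mask.astype(np.uint8), affine), str(mask_path))


# ---------------------------------------------------------------------------
# Cohort simulator
# ---------------------------------------------------------------------------

_SCORE_MARGINALS = {
    # absent / mild / moderate / severe marginal frequencies (cohort-wide)
    "score_mesangial_expansion": (0.79, 0.19, 0.01, 0.01),
    "score_intimal_fibrosis": (0.02, 0.29, 0.35, 0.34),
    "score_interstitial_fibrosis": (0.61, 0.33, 0.03, 0.03),
    "score_tubular_atrophy": (0.65, 0.29, 0.03, 0.03),
    "score_arteriolar_hyalinosis": (0.75, 0.17, 0.04, 0.04),
}

SCORE_COLUMNS = tuple(_SCORE_MARGINALS)


@dataclass
class SyntheticCohortSpec:
    """Parameters of the two-group (non-VO, VO) synthetic cohort.

    All ``(mean, sd)`` pairs are ordered ``(non-VO, VO)``.  VAT is
    lognormal with the stated group medians and log-scale sigmas,
    truncated to respect the 100 cm² group definition.  The outcome
    (ΔeGFR by default) carries a standardized effect ``effect_beta``
    of ``effect_predictor`` on top of group-specific target means.
    """

    n_nonvo: int = 17
    n_vo: int = 35
    bmi: tuple = ((23.1, 2.4), (25.9, 2.1))  # kg/m²
    age: tuple = ((60.0, 14.0), (69.0, 13.0))  # years
    height: tuple = ((1.65, 0.08), (1.72, 0.08))  # m
    vat_median: tuple = (67.0, 170.0)  # cm²
    vat_sigma: tuple = (0.55, 0.40)  # lognormal sigma
    glomerular_volume: tuple = ((2.0, 0.5), (2.6, 0.7))  # ×10⁶ μm³
    podocyte_density: tuple = ((243.0, 59.0), (194.0, 50.0))  # per 10⁶ μm³
    apparent_d: tuple = ((5.6, 0.2), (5.9, 0.2))  # μm
    nuclear_volume: tuple = ((195.0, 22.0), (226.0, 27.0))  # μm³
    egfr_baseline: tuple = ((74.0, 18.0), (78.0, 15.0))  # ml/min per 1.73 m²
    kidney_volume: tuple = ((181.0, 69.0), (196.0, 52.0))  # cm³
    female_frac: tuple = (0.88, 0.23)
    hypertension_frac: tuple = (0.47, 0.74)
    diabetes_frac: tuple = (0.0, 0.29)
    delta_egfr_mean: tuple = (-12.0, -24.0)  # ml/min per 1.73 m²
    delta_egfr_sd: float = 15.0
    effect_predictor: str = "glomerular_volume"
    effect_beta: float = -0.41
    n_missing_followup: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nonvo < 2 or self.n_vo < 2:
            raise ValueError("group sizes must be >= 2")
        for name in ("bmi", "age", "height", "glomerular_volume", "podocyte_density",
                     "apparent_d", "nuclear_volume", "egfr_baseline", "kidney_volume"):
            for _, sd in getattr(self, name):
                if sd < 0:
                    raise ValueError(f"{name}: SD must be >= 0")
        if self.delta_egfr_sd < 0:
            raise ValueError("delta_egfr_sd must be >= 0")
        if not -1.0 < self.effect_beta < 1.0:
            raise ValueError("effect_beta must lie in (-1, 1)")

    @classmethod
    def homogeneous(
        cls,
        n: int,
        effect_beta: float,
        effect_predictor: str = "glomerular_volume",
        seed: int = 0,
    ) -> "SyntheticCohortSpec":
        """Single-population spec (equal group parameters) for clean
        parameter-recovery experiments: cohort-pooled morphometric
        means, no group outcome offset, complete follow-up."""
        pooled = {
            "glomerular_volume": ((2.4, 0.7), (2.4, 0.7)),
            "podocyte_density": ((210.0, 57.0), (210.0, 57.0)),
            "apparent_d": ((5.8, 0.25), (5.8, 0.25)),
            "nuclear_volume": ((216.0, 29.0), (216.0, 29.0)),
        }
        return cls(
            n_nonvo=n // 2,
            n_vo=n - n // 2,
            delta_egfr_mean=(-20.0, -20.0),
            effect_beta=effect_beta,
            effect_predictor=effect_predictor,
            n_missing_followup=0,
            seed=seed,
            **pooled,
        )


def _truncated_lognormal(
    rng: np.random.Generator, median: float, sigma: float, n: int,
    lo: float = 0.0, hi: float = np.inf,
) -> np.ndarray:
    out = rng.lognormal(math.log(median), sigma, size=n)
    for _ in range(200):
        bad = (out < lo) | (out >= hi)
        if not bad.any():
            break
        out[bad] = rng.lognormal(math.log(median), sigma, size=int(bad.sum()))
    return np.clip(out, lo, np.nextafter(hi, lo) if np.isfinite(hi) else np.inf)


def simulate_cohort(spec: SyntheticCohortSpec = SyntheticCohortSpec()) -> pd.DataFrame:
    """Draw a per-subject cohort table with the configured group structure.

    Morphometrics are drawn marginally per group; the outcome is
    ``delta_egfr = base_g + beta * z(predictor) * sd + noise`` with the
    per-group base chosen so group means hit their targets, and noise
    variance ``sd² * (1 - beta²)`` so the standardized slope of the
    predictor equals ``effect_beta``.  12-month eGFR is baseline plus
    ΔeGFR (floored at 0); a configurable number of subjects lack
    follow-up.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nonvo + spec.n_vo
    group = np.array([0] * spec.n_nonvo + [1] * spec.n_vo)

    def draw(pairs: tuple, lo: float = -np.inf) -> np.ndarray:
        out = np.empty(n)
        for g in (0, 1):
            mean, sd = pairs[g]
            out[group == g] = rng.normal(mean, sd, size=int((group == g).sum()))
        return np.maximum(out, lo)

    df = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "vo": group,
        "bmi": draw(spec.bmi, lo=15.0),
        "age": np.round(draw(spec.age, lo=18.0)),
        "height_m": draw(spec.height, lo=1.2),
        "egfr_baseline": draw(spec.egfr_baseline, lo=5.0),
        "kidney_volume_cm3": draw(spec.kidney_volume, lo=30.0),
        "glomerular_volume": draw(spec.glomerular_volume, lo=0.2),
        "podocyte_density": draw(spec.podocyte_density, lo=20.0),
        "apparent_d": draw(spec.apparent_d, lo=3.0),
        "nuclear_volume": draw(spec.nuclear_volume, lo=50.0),
    })
    vat = np.empty(n)
    vat[group == 0] = _truncated_lognormal(
        rng, spec.vat_median[0], spec.vat_sigma[0], spec.n_nonvo, lo=5.0, hi=100.0)
    vat[group == 1] = _truncated_lognormal(
        rng, spec.vat_median[1], spec.vat_sigma[1], spec.n_vo, lo=100.0)
    df["vat_cm2"] = vat
    df["sex_female"] = (rng.random(n) < np.asarray(spec.female_frac)[group]).astype(int)
    df["hypertension"] = (rng.random(n) < np.asarray(spec.hypertension_frac)[group]).astype(int)
    df["diabetes"] = (rng.random(n) < np.asarray(spec.diabetes_frac)[group]).astype(int)
    for col, probs in _SCORE_MARGINALS.items():
        df[col] = rng.choice(4, size=n, p=probs)

    # derived morphometrics: count = density (per 1e6 μm³) × volume (×1e6 μm³)
    df["podocyte_count"] = df["podocyte_density"] * df["glomerular_volume"]
    df["total_nuclear_volume"] = df["podocyte_count"] * df["nuclear_volume"] / 1e5
    df["height_adj_kidney_volume"] = df["kidney_volume_cm3"] / df["height_m"]

    # outcome with a standardized effect of the chosen predictor
    x = df[spec.effect_predictor].to_numpy()
    z = (x - x.mean()) / x.std(ddof=1)
    beta, sd_out = spec.effect_beta, spec.delta_egfr_sd
    effect = beta * z * sd_out
    noise = rng.normal(0.0, sd_out * math.sqrt(1.0 - beta ** 2), size=n)
    delta = np.empty(n)
    for g in (0, 1):
        m = group == g
        delta[m] = spec.delta_egfr_mean[g] - effect[m].mean() + effect[m] + noise[m]
    df["egfr_12m"] = np.maximum(df["egfr_baseline"] + delta, 0.0)
    if spec.n_missing_followup > 0:
        missing = rng.choice(n, size=min(spec.n_missing_followup, n), replace=False)
        df.loc[missing, "egfr_12m"] = np.nan
    return df
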