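"""Synthetic phantom cohorts with the statistical structure the pipeline assumes.

No patient images ship with the package, so every pipeline stage is
exercised on ellipsoidal phantoms: a low-grade tumor is homogeneous
Gaussian signal, while a high-grade tumor carries three concentric
intensity compartments — a faint core, an intermediate middle shell and a
bright outer rim (high-grade tumors show their high-signal habitat at the
tumor edge).  The habitat contrast Δ, expressed in units of the noise
standard deviation, is the effect size the end-to-end power analysis
sweeps: Δ = 0 collapses a high-grade phantom onto the low-grade null.

Default study conditions: 48³ voxel grids, ellipsoid semi-axes (10, 12, 14)
jittered ±20% per case, baseline intensity 100, noise sd 10, rim occupying
the outer 25% of the normalized radius, cohorts of 60 + 60 cases.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import GeometryError, ParameterError
from .io import CaseRecord, TumorROI, roi_from_arrays, save_volume

__all__ = [
    "PhantomSpec",
    "SyntheticCohortSpec",
    "generate_phantom",
    "generate_cohort",
    "cohort_rois",
    "write_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal model of one phantom case."""

    grade: int = 0
    grid_size: int = 48
    tumor_radii: tuple[float, float, float] = (10.0, 12.0, 14.0)
    habitat_contrast: float = 3.0  # Δ, in units of noise_sd
    rim_fraction: float = 0.25
    noise_sd: float = 10.0
    base_intensity: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        half = (self.grid_size - 1) / 2.0
        if max(self.tumor_radii) > half:
            raise GeometryError(
                f"radii {self.tumor_radii} exceed grid half-extent {half}"
            )
        if min(self.tumor_radii) <= 0:
            raise GeometryError("radii must be positive")
        if self.habitat_contrast < 0:
            raise ParameterError("habitat_contrast must be >= 0")
        if not 0.0 < self.rim_fraction < 1.0:
            raise ParameterError("rim_fraction must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if self.grade not in (0, 1):
            raise ParameterError("grade must be 0 or 1")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """A two-arm cohort of phantom cases (grade 0 vs grade 1)."""

    n_low: int = 60
    n_high: int = 60
    phantom: PhantomSpec = PhantomSpec()
    radius_jitter: float = 0.2
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_low < 2 or self.n_high < 2:
            raise ParameterError("need >= 2 cases per arm")
        if not 0.0 <= self.radius_jitter < 1.0:
            raise ParameterError("radius_jitter must lie in [0, 1)")


def _ellipsoid_rho(grid_size: int, radii: tuple[float, float, float]) -> np.ndarray:
    """Normalized ellipsoidal radius of every voxel from the grid center."""
    c = (grid_size - 1) / 2.0
    ax = np.arange(grid_size) - c
    return np.sqrt(
        (ax[:, None, None] / radii[0]) ** 2
        + (ax[None, :, None] / radii[1]) ** 2
        + (ax[None, None, :] / radii[2]) ** 2
    )


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """One phantom: (image volume, binary mask volume), background 0.

    Grade 0: N(μ0, σ²) throughout the tumor.  Grade 1: three concentric
    compartments with means μ0 − Δσ/2 (core, ρ < (1−rim)/2), μ0 (middle)
    and μ0 + Δσ (rim, ρ >= 1 − rim_fraction), plus N(0, σ²) noise.
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rho = _ellipsoid_rho(spec.grid_size, spec.tumor_radii)
    mask = (rho <= 1.0).astype(np.uint8)
    image = np.zeros(rho.shape)
    mu0, sd, delta = spec.base_intensity, spec.noise_sd, spec.habitat_contrast
    inside = mask.astype(bool)
    means = np.full(rho.shape, mu0)
    if spec.grade == 1:
        rim_inner = 1.0 - spec.rim_fraction
        core_outer = rim_inner / 2.0
        means[rho < core_outer] = mu0 - delta * sd / 2.0
        means[rho >= rim_inner] = mu0 + delta * sd
    image[inside] = means[inside] + rng.normal(0.0, sd, size=int(inside.sum()))
    return image, mask


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> list[tuple[CaseRecord, np.ndarray, np.ndarray]]:
    """Generate n_low + n_high phantom cases with per-case derived seeds.

    Radii are jittered uniformly within ±``radius_jitter`` per case; labels
    are set by construction; the whole cohort is bit-reproducible from
    ``master_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.master_seed)
    n_total = spec.n_low + spec.n_high
    case_seeds = rng.integers(0, 2**31 - 1, size=n_total)
    jitters = rng.uniform(
        1.0 - spec.radius_jitter, 1.0 + spec.radius_jitter, size=(n_total, 3)
    )
    grades = np.concatenate(
        [np.zeros(spec.n_low, dtype=int), np.ones(spec.n_high, dtype=int)]
    )
    cases = []
    for idx in range(n_total):
        radii = tuple(np.asarray(spec.phantom.tumor_radii) * jitters[idx])
        pspec = replace(
            spec.phantom,
            grade=int(grades[idx]),
            tumor_radii=radii,
            seed=int(case_seeds[idx]),
        )
        image, mask = generate_phantom(pspec)
        record = CaseRecord(case_id=f"case_{idx:04d}", grade=int(grades[idx]))
        cases.append((record, image, mask))
    return cases


def cohort_rois(
    cases: list[tuple[CaseRecord, np.ndarray, np.ndarray]]
) -> tuple[list[TumorROI], np.ndarray, list[str]]:
    """Extract (rois, labels, case_ids) from an in-memory cohort."""
    rois, labels, ids = [], [], []
    for record, image, mask in cases:
        rois.append(roi_from_arrays(image, mask, case_id=record.case_id))
        labels.append(record.grade)
        ids.append(record.case_id)
    return rois, np.asarray(labels), ids


def write_cohort(
    cases: list[tuple[CaseRecord, np.ndarray, np.ndarray]],
    out_dir: str | Path,
) -> Path:
    """Write NIfTI image/mask pairs plus the case-table CSV; returns the CSV path.

    Output is byte-compatible with the pipeline's directory input mode:
    ``<case_id>_image.nii.gz``, ``<case_id>_mask.nii.gz``, ``cases.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_path = out_dir / "cases.csv"
    with open(table_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "grade"])
        for record, image, mask in cases:
            save_volume(image, out_dir / f"{record.case_id}_image.nii.gz")
            save_volume(mask, out_dir / f"{record.case_id}_mask.nii.gz")
            writer.writerow([record.case_id, record.grade])
    return table_path
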