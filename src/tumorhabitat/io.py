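"""Reading image/mask pairs and case tables; extraction of tumor voxel vectors.

The pipeline's unit of input is one case: a 3-D scalar volume (enhanced-T1
MRI in the intended application), a binary tumor mask on the same grid, and
a row in a case table carrying the pathological grade label.  This module
performs no resampling, rescaling or other processing — it only validates
and extracts, so that every numerical step downstream is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataError, EmptyROIError, FormatError, ShapeMismatchError

__all__ = [
    "CaseRecord",
    "TumorROI",
    "load_case",
    "load_case_table",
    "roi_from_arrays",
    "save_volume",
]

#: accepted spellings for the grade column, mapped to the binary label
#: (WHO grade I = low grade = 0; WHO grades II and III = high grade = 1)
_GRADE_MAP = {
    "I": 0, "II": 1, "III": 1,
    "0": 0, "1": 1,
    "LOW": 0, "HIGH": 1,
}

_COVARIATE_COLUMNS = ("age", "sex", "pr", "ki67")


@dataclass(frozen=True)
class CaseRecord:
    """One row of the cohort table: identifier, binary grade, optional covariates."""

    case_id: str
    grade: int
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grade not in (0, 1):
            raise DataError(f"grade must be 0 or 1, got {self.grade!r}")


@dataclass(frozen=True)
class TumorROI:
    """The voxel sample of one tumor.

    Attributes
    ----------
    intensities : (N,) float array
        Scalar voxel values inside the mask, in the image's native units.
    voxel_coords : (N, 3) int array
        Index-space coordinates (i, j, k) of those voxels, in fixed
        lexicographic order, so repeated loads yield identical vectors.
    case_id, image_path, mask_path
        Provenance of the sample.
    """

    intensities: np.ndarray
    voxel_coords: np.ndarray
    case_id: str = ""
    image_path: str = ""
    mask_path: str = ""

    @property
    def n_voxels(self) -> int:
        return int(self.intensities.shape[0])


def roi_from_arrays(
    image: np.ndarray,
    mask: np.ndarray,
    case_id: str = "",
    image_path: str = "",
    mask_path: str = "",
) -> TumorROI:
    """Extract the ROI voxel vector from in-memory arrays.

    Any nonzero mask voxel counts as ROI (masks exported as 0/1 or 0/255
    are treated identically).  Voxels are returned in lexicographic
    (i, j, k) order.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.ndim != 3 or mask.ndim != 3:
        raise ShapeMismatchError(
            f"expected 3-D volumes, got image.ndim={image.ndim}, mask.ndim={mask.ndim}"
        )
    if image.shape != mask.shape:
        raise ShapeMismatchError(
            f"image grid {image.shape} != mask grid {mask.shape}"
        )
    sel = mask != 0
    n = int(sel.sum())
    if n == 0:
        raise EmptyROIError(f"mask selects no voxels (case {case_id or '<unnamed>'})")
    coords = np.argwhere(sel)  # C-order traversal == lexicographic (i, j, k)
    intensities = np.asarray(image[sel], dtype=float)
    if not np.all(np.isfinite(intensities)):
        raise DataError(
            f"non-finite intensities inside ROI (case {case_id or '<unnamed>'})"
        )
    return TumorROI(
        intensities=intensities,
        voxel_coords=coords,
        case_id=case_id,
        image_path=image_path,
        mask_path=mask_path,
    )


def load_case(image_path: str | Path, mask_path: str | Path, case_id: str = "") -> TumorROI:
    """Load a NIfTI image/mask pair and extract the tumor voxel vector.

    No resampling is performed; the two files must share grid dimensions.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    img = np.asarray(nib.load(image_path).get_fdata())
    msk = np.asarray(nib.load(mask_path).get_fdata())
    return roi_from_arrays(
        img,
        msk,
        case_id=case_id or image_path.stem.replace(".nii", ""),
        image_path=str(image_path),
        mask_path=str(mask_path),
    )


def _parse_grade(value: object) -> int:
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return int(value)
    if isinstance(value, (float, np.floating)) and value in (0.0, 1.0):
        return int(value)
    token = str(value).strip().upper()
    if token in _GRADE_MAP:
        return _GRADE_MAP[token]
    raise DataError(f"unparseable grade value {value!r}")


def load_case_table(table_path: str | Path) -> list[CaseRecord]:
    """Read the cohort CSV (columns: case_id, grade, optional age/sex/pr/ki67).

    WHO grades I → 0 and II/III → 1; literal 0/1 labels pass through.
    """
    df = pd.read_csv(table_path, dtype={"case_id": str})
    missing = {"case_id", "grade"} - set(df.columns)
    if missing:
        raise FormatError(f"case table missing required column(s): {sorted(missing)}")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise DataError(f"duplicate case_id values: {dupes}")
    records = []
    for _, row in df.iterrows():
        covs = {
            c: row[c]
            for c in _COVARIATE_COLUMNS
            if c in df.columns and pd.notna(row[c])
        }
        records.append(
            CaseRecord(case_id=row["case_id"], grade=_parse_grade(row["grade"]), covariates=covs)
        )
    return records


def save_volume(array: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    """Write a 3-D array as NIfTI (identity affine by default)."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))
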