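"""Slice extraction from 3D volumes and per-subject asymmetry profiles.

Volumes are Talairach-aligned, skull-stripped T1 images of nominal shape
(176, 208, 176) (a trailing singleton channel is dropped).  The profile
consists of eleven per-slice asymmetry indices: five axial slices
(68, 78, 88, 98, 108), five coronal slices (84, 94, 104, 114, 124) —
central slices spaced 10 voxels apart — and one oblique "diagonal"
slice running from the frontal lobe to the cerebellum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .gmsd import as_gray_image
from .symmetry import AxisSearchConfig, DegenerateImageError, SymmetryAxisResult, find_symmetry_axis

logger = logging.getLogger(__name__)

__all__ = [
    "EXPECTED_SHAPE",
    "SliceSpec",
    "AsymmetryProfile",
    "default_slice_set",
    "load_volume",
    "extract_slice",
    "profile_subject",
    "profile_cohort",
]

EXPECTED_SHAPE = (176, 208, 176)

#: Default axial/coronal slice indices (0-based, used verbatim).
DEFAULT_AXIAL = (68, 78, 88, 98, 108)
DEFAULT_CORONAL = (84, 94, 104, 114, 124)


@dataclass(frozen=True)
class SliceSpec:
    """One 2D slice of a volume.

    ``axial`` fixes the third coordinate, ``coronal`` the second.  The
    ``diagonal`` plane passes through the volume center, tilted from the
    axial plane about the left-right axis by ``pitch_deg`` (the exact
    oblique plane of the original study is not recoverable; 45 degrees
    is this package's documented convention).
    """

    plane: str
    index: int = 0
    pitch_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.plane not in ("axial", "coronal", "diagonal"):
            raise ValueError(f"unknown plane {self.plane!r}")

    @property
    def name(self) -> str:
        return {"axial": f"a{self.index}", "coronal": f"c{self.index}", "diagonal": "dg"}[
            self.plane
        ]


def default_slice_set() -> list[SliceSpec]:
    """Diagonal first, then the five axial and five coronal slices."""
    specs = [SliceSpec("diagonal")]
    specs += [SliceSpec("axial", r) for r in DEFAULT_AXIAL]
    specs += [SliceSpec("coronal", l) for l in DEFAULT_CORONAL]
    return specs


def load_volume(path) -> np.ndarray:
    """Read a NIfTI-1 or Analyze 7.5 volume as a 3D float array.

    Singleton dimensions (the channel axis) are squeezed; negative
    intensities are clipped to zero.  A shape other than (176, 208, 176)
    is allowed with a warning.
    """
    import nibabel as nib

    vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    vol = np.squeeze(vol)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume after channel squeeze, got shape {vol.shape}")
    if vol.shape != EXPECTED_SHAPE:
        logger.warning("volume shape %s differs from expected %s", vol.shape, EXPECTED_SHAPE)
    return np.clip(vol, 0.0, None)


def _diagonal_slice(vol: np.ndarray, pitch_deg: float) -> np.ndarray:
    """Oblique resample: axial plane pitched about the left-right axis.

    The output grid keeps the axial extent (d0 x d1); sampling is
    trilinear with zero fill outside the volume.
    """
    d0, d1, d2 = vol.shape
    c = (np.array(vol.shape) - 1) / 2.0
    phi = np.deg2rad(pitch_deg)
    uu = np.arange(d0, dtype=float)[:, None] - c[0]
    vv = np.arange(d1, dtype=float)[None, :] - c[1]
    coords = np.stack(
        [
            np.broadcast_to(uu + c[0], (d0, d1)),
            c[1] + vv * np.cos(phi) + np.zeros_like(uu),
            c[2] + vv * np.sin(phi) + np.zeros_like(uu),
        ]
    )
    return ndimage.map_coordinates(vol, coords, order=1, mode="constant", cval=0.0)


def extract_slice(vol: np.ndarray, spec: SliceSpec) -> np.ndarray:
    """Extract a named 2D slice, plainly indexed.

    Axial r gives ``vol[:, :, r]``; coronal l gives ``vol[:, l, :]``.
    The left-right anatomical axis (first volume dimension) therefore
    runs along the ROWS of the returned array; the axis search mirrors
    columns, so callers profiling hemispheric asymmetry should
    transpose first (``profile_subject`` does).
    """
    vol = np.asarray(vol, dtype=float)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {vol.shape}")
    if spec.plane == "axial":
        if not 0 <= spec.index < vol.shape[2]:
            raise IndexError(f"axial index {spec.index} out of range [0, {vol.shape[2]})")
        img = vol[:, :, spec.index]
    elif spec.plane == "coronal":
        if not 0 <= spec.index < vol.shape[1]:
            raise IndexError(f"coronal index {spec.index} out of range [0, {vol.shape[1]})")
        img = vol[:, spec.index, :]
    else:
        img = _diagonal_slice(vol, spec.pitch_deg)
    return np.ascontiguousarray(img)


@dataclass(frozen=True)
class AsymmetryProfile:
    """Eleven per-slice asymmetry indices for one subject."""

    subject_id: str
    indices: dict[str, float]
    diagnostics: dict[str, SymmetryAxisResult] = field(repr=False, default_factory=dict)

    def as_row(self) -> dict[str, float]:
        return {"subject_id": self.subject_id, **self.indices}


def profile_subject(
    vol: np.ndarray,
    axis_config: AxisSearchConfig | None = None,
    slices: list[SliceSpec] | None = None,
    subject_id: str = "subject",
) -> AsymmetryProfile:
    """Run the symmetry-axis search on every named slice of a volume.

    Each slice is transposed so the left-right axis lies along image
    columns (mirroring then flips hemispheres).  Deterministic given the
    configuration.  A degenerate (all-zero) slice raises
    ``DegenerateImageError``: the subject should be flagged, not
    silently profiled.
    """
    axis_config = axis_config or AxisSearchConfig()
    slices = slices if slices is not None else default_slice_set()
    indices: dict[str, float] = {}
    diagnostics: dict[str, SymmetryAxisResult] = {}
    for spec in slices:
        img = extract_slice(vol, spec).T
        try:
            img = as_gray_image(img, name=f"slice {spec.name}")
            result = find_symmetry_axis(img, axis_config)
        except (DegenerateImageError, ValueError) as exc:
            raise DegenerateImageError(
                f"subject {subject_id}: slice {spec.name} unusable ({exc})"
            ) from exc
        indices[spec.name] = result.asymmetry_index
        diagnostics[spec.name] = result
    return AsymmetryProfile(subject_id=subject_id, indices=indices, diagnostics=diagnostics)


def profile_cohort(
    volumes: dict[str, "np.ndarray | str"],
    covariates: pd.DataFrame,
    axis_config: AxisSearchConfig | None = None,
    slices: list[SliceSpec] | None = None,
) -> pd.DataFrame:
    """Indicator table for a cohort, merged with covariates.

    ``volumes`` maps subject_id to a 3D array or a volume path.
    ``covariates`` must provide subject_id, age, sex and ses columns;
    subjects with missing covariates, SES outside 1-5, unreadable
    volumes or degenerate slices are dropped with a logged reason.
    Column order is fixed: subject_id, the slice indicators, age, sex,
    ses.
    """
    required = {"subject_id", "age", "sex", "ses"}
    missing_cols = required - set(covariates.columns)
    if missing_cols:
        raise ValueError(f"covariate table missing columns: {sorted(missing_cols)}")
    if covariates["subject_id"].duplicated().any():
        dups = covariates.loc[covariates["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicate subject_id in covariates: {sorted(set(dups))}")
    cov = covariates.set_index("subject_id")

    rows = []
    slice_names: list[str] | None = None
    for subject_id, vol in volumes.items():
        if subject_id not in cov.index:
            logger.warning("subject %s: no covariate row; dropped", subject_id)
            continue
        row = cov.loc[subject_id]
        if row[["age", "sex", "ses"]].isna().any():
            logger.warning("subject %s: missing covariate value; dropped", subject_id)
            continue
        if not 1 <= float(row["ses"]) <= 5:
            logger.warning("subject %s: SES %r outside 1-5; dropped", subject_id, row["ses"])
            continue
        try:
            arr = vol if isinstance(vol, np.ndarray) else load_volume(vol)
            profile = profile_subject(arr, axis_config, slices, subject_id=subject_id)
        except (DegenerateImageError, OSError, ValueError) as exc:
            logger.warning("subject %s: %s; dropped", subject_id, exc)
            continue
        slice_names = list(profile.indices)
        rows.append({**profile.as_row(),
                     "age": float(row["age"]), "sex": float(row["sex"]),
                     "ses": float(row["ses"])})

    if not rows:
        logger.warning("cohort profiling produced no usable subjects")
        names = slice_names or [s.name for s in (slices or default_slice_set())]
        return pd.DataFrame(columns=["subject_id", *names, "age", "sex", "ses"])
    out = pd.DataFrame(rows)
    return out[["subject_id", *slice_names, "age", "sex", "ses"]]
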