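"""NIfTI label volumes and per-lesion sidecar tables.

Every volume entering the pipeline is converted to the closest-canonical
(RAS+) voxel ordering on read, so all downstream modules operate in one
coordinate convention and can compare masks voxel-by-voxel.  Ground-truth and
predicted masks must already share a grid: resampling mismatched geometries is
rejected rather than silently performed.

Conventions
-----------
* voxel indices are 0-based; box extents half-open
* volumes in mL are ``voxel_count * voxel_volume_mm3 / 1000``
* instance masks use positive integers per instance; predicted masks may be
  binary (instances recovered later by connected components)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

CATEGORIES = ("T", "N", "M")
ETIOLOGY_CLASSES = ("physiologic", "benign", "pathologic")

SIDECAR_COLUMNS = [
    "lesion_id",
    "category",
    "station_or_organ",
    "invasion_flags",
    "etiology_class",
    "etiology",
    "diameter_mm",
]


class FormatError(ValueError):
    """Raised when an input file violates the supported format."""


@dataclass
class LabelVolume:
    """A 3D integer voxel grid with physical spacing.

    Parameters
    ----------
    voxels : ndarray of int, shape (nx, ny, nz)
        Non-negative label values; 0 is background.
    spacing : tuple of float
        Voxel edge lengths in mm per axis, strictly positive.
    origin : tuple of float
        World-space offset of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(
                f"expected a 3D volume, got ndim={self.voxels.ndim}"
            )
        if not np.issubdtype(self.voxels.dtype, np.integer):
            if np.issubdtype(self.voxels.dtype, np.floating) and np.allclose(
                self.voxels, np.rint(self.voxels)
            ):
                self.voxels = np.rint(self.voxels).astype(np.int32)
            else:
                raise FormatError("voxels: non-integer label data")
        if self.voxels.min() < 0:
            raise FormatError("voxels: negative label values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing: must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_ml(self, voxel_count: int) -> float:
        """Physical volume of ``voxel_count`` voxels in mL."""
        return voxel_count * self.voxel_volume_mm3 / 1000.0

    def binarized(self) -> np.ndarray:
        return self.voxels > 0

    def same_grid(self, other: "LabelVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def require_same_grid(a: LabelVolume, b: LabelVolume) -> None:
    if not a.same_grid(b):
        raise FormatError(
            f"grid mismatch: shape/spacing {a.shape}/{a.spacing} vs {b.shape}/{b.spacing}"
        )


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a 3D single-channel NIfTI and canonicalize its orientation.

    The image is reoriented to the closest-canonical (RAS+) axis ordering so
    that two files saved in different orientations of the same world-space
    content read back identically.  Spacing is taken from the header.
    """
    path = Path(path)
    img = nib.load(str(path))
    if img.ndim == 4 and img.shape[3] == 1:
        img = nib.funcs.squeeze_image(img)
    if img.ndim != 3:
        raise FormatError(f"{path.name}: expected 3D data, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path.name}: missing or invalid spacing {zooms}")
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.rint(data)):
            raise FormatError(f"{path.name}: non-integer voxel data")
        data = np.rint(data).astype(np.int32)
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return LabelVolume(np.ascontiguousarray(data), tuple(float(z) for z in zooms), origin)


def write_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    """Write a LabelVolume as NIfTI with a diagonal RAS+ affine."""
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    dtype = np.uint16 if vol.voxels.max() < 2**16 else np.int32
    img = nib.Nifti1Image(vol.voxels.astype(dtype), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# lesion sidecar tables


def _normalize_sidecar(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in SIDECAR_COLUMNS:
        if col not in df.columns:
            df[col] = None
    df = df[SIDECAR_COLUMNS]
    if len(df) == 0:
        return df
    if df["lesion_id"].duplicated().any():
        dupes = df.loc[df["lesion_id"].duplicated(), "lesion_id"].tolist()
        raise FormatError(f"sidecar: duplicate lesion_id {dupes}")
    if df["category"].isna().any():
        raise FormatError("sidecar: category missing for some rows")
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise FormatError(f"sidecar: unknown category values {sorted(bad)}")
    # etiology present iff the row describes non-tumour uptake
    nontumour = df["etiology_class"].isin(ETIOLOGY_CLASSES)
    is_tumour = df["etiology_class"].isna() | (df["etiology_class"] == "tumour")
    if not (nontumour | is_tumour).all():
        bad = sorted(set(df.loc[~(nontumour | is_tumour), "etiology_class"]))
        raise FormatError(f"sidecar: unknown etiology_class values {bad}")
    missing_label = nontumour & (df["etiology"].isna() | (df["etiology"] == ""))
    if missing_label.any():
        raise FormatError(
            "sidecar: etiology label required for non-tumour rows "
            f"{df.loc[missing_label, 'lesion_id'].tolist()}"
        )
    return df


def read_sidecar(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-lesion metadata table (CSV or JSON)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        df = pd.DataFrame(rows, columns=SIDECAR_COLUMNS if not rows else None)
    else:
        df = pd.read_csv(path)
    return _normalize_sidecar(df)


def write_sidecar(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df = _normalize_sidecar(pd.DataFrame(df))
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.where(df.notna(), None).to_dict("records"), indent=1))
    else:
        df.to_csv(path, index=False)
    return path


def parse_invasion_flags(value) -> tuple[str, ...]:
    """Invasion flags are serialized as a ';'-joined string in sidecars."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return ()
    if isinstance(value, (list, tuple)):
        return tuple(value)
    return tuple(p for p in str(value).split(";") if p)


def format_invasion_flags(flags) -> str:
    return ";".join(flags) if flags else ""
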