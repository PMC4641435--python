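"""Readers and writers for streamlines (TCK/TRK), volumes (NIfTI-1) and tables.

All geometry handed to the rest of the package is in world millimetres,
RAS orientation. TRK files store points in a voxel-scaled space; nibabel
applies the header transform on load, so both dialects arrive in the
same frame. Voxel indices are 0-based and map to world space through the
volume affine; sampling positions map back through its inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import TckFile, Tractogram, TrkFile
from nibabel.streamlines.header import Field as TrkField

from .errors import DimensionalityError, EmptyInputError, FormatError

__all__ = [
    "ScalarVolume",
    "StreamlineFile",
    "read_volume",
    "write_volume",
    "read_streamlines",
    "write_streamlines",
    "read_behavior_table",
    "write_behavior_table",
]

VOLUME_KINDS = ("FA", "MD", "mask", "dwi")
BEHAVIOR_COLUMNS = ["participant", "contrast", "true_interval", "response", "fixation_deg"]


@dataclass
class ScalarVolume:
    """A scalar grid plus its voxel-index -> world-mm affine.

    ``kind`` is one of ``FA`` (unitless, in [0, 1] within brain),
    ``MD`` (mm^2/s), ``mask`` (binary) or ``dwi`` (4-D channel stack).
    """

    data: np.ndarray
    affine: np.ndarray
    kind: str = "FA"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.kind not in VOLUME_KINDS:
            raise FormatError(f"unknown volume kind {self.kind!r}; expected one of {VOLUME_KINDS}")
        expected_ndim = 4 if self.kind == "dwi" else 3
        if self.data.ndim != expected_ndim:
            raise DimensionalityError(
                f"{self.kind} volume must be {expected_ndim}-D, got {self.data.ndim}-D"
            )
        if self.affine.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular; voxel size cannot be recovered")
        if self.kind == "mask":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise FormatError("mask volume must be binary (0/1)")

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates to continuous 0-based voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class StreamlineFile:
    """A set of streamlines in world mm with the ROI pair that seeded them."""

    streamlines: list[np.ndarray]
    source_rois: tuple[str, str] = ("start", "end")
    outlier_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        clean = []
        for i, s in enumerate(self.streamlines):
            s = np.asarray(s, dtype=float)
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise FormatError(f"streamline {i} must be an (n>=2, 3) point array")
            if not np.all(np.isfinite(s)):
                raise FormatError(f"streamline {i} contains non-finite coordinates")
            clean.append(s)
        if not clean:
            raise EmptyInputError("streamline file contains zero streamlines")
        self.streamlines = clean

    def __len__(self) -> int:
        return len(self.streamlines)


def read_volume(path: str | Path, kind: str | None = None) -> ScalarVolume:
    """Load a NIfTI volume; ``kind`` overrides the header description."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    if kind is None:
        descrip = ""
        if hasattr(img.header, "get"):
            try:
                descrip = np.asarray(img.header["descrip"]).tobytes().decode(errors="ignore")
            except Exception:
                descrip = ""
        kind = next((k for k in VOLUME_KINDS if k in descrip), None)
        if kind is None:
            kind = "dwi" if len(img.shape) == 4 else "FA"
    data = np.asarray(img.dataobj, dtype=np.float64)
    if kind == "mask":
        data = (data > 0.5).astype(np.float64)
    return ScalarVolume(data=data, affine=np.asarray(img.affine), kind=kind)


def write_volume(volume: ScalarVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    img.header["descrip"] = volume.kind.encode()
    nib.save(img, str(path))
    return path


def _dialect_for(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    dialect = dialect.lower()
    if dialect not in ("tck", "trk"):
        raise FormatError(f"unknown streamline dialect {dialect!r}; expected 'tck' or 'trk'")
    return dialect


def read_streamlines(
    path: str | Path,
    dialect: str | None = None,
    source_rois: tuple[str, str] = ("start", "end"),
) -> StreamlineFile:
    """Read a TCK or TRK file into world-mm (RAS) streamlines.

    For TRK the on-disk coordinates are in the header's voxel-scaled
    space; they are transformed to RAS mm through the header affine.
    """
    path = Path(path)
    cls = TckFile if _dialect_for(path, dialect) == "tck" else TrkFile
    try:
        tf = cls.load(str(path), lazy_load=False)
    except EOFError as exc:
        raise FormatError(f"{path}: truncated streamline file ({exc})") from exc
    except Exception as exc:
        raise FormatError(f"{path}: malformed {cls.__name__[:3].lower()} header or body ({exc})") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
    if not streamlines:
        raise EmptyInputError(f"{path}: file contains zero streamlines")
    return StreamlineFile(streamlines=streamlines, source_rois=source_rois)


def write_streamlines(
    sf: StreamlineFile,
    path: str | Path,
    dialect: str | None = None,
    reference: ScalarVolume | None = None,
) -> Path:
    """Write streamlines to TCK or TRK.

    TRK requires a voxel grid in its header; ``reference`` supplies it,
    otherwise a synthetic 1 mm isotropic grid covering the data is used.
    """
    path = Path(path)
    dialect = _dialect_for(path, dialect)
    tractogram = Tractogram(
        [np.asarray(s, dtype=np.float32) for s in sf.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if dialect == "tck":
        TckFile(tractogram).save(str(path))
        return path
    if reference is not None:
        affine, dims = reference.affine, reference.data.shape[:3]
    else:
        lo = np.floor(np.min([s.min(axis=0) for s in sf.streamlines], axis=0)) - 2
        hi = np.ceil(np.max([s.max(axis=0) for s in sf.streamlines], axis=0)) + 2
        affine = np.eye(4)
        affine[:3, 3] = lo
        dims = tuple(int(v) for v in (hi - lo))
    header = {
        TrkField.VOXEL_TO_RASMM: affine.astype(np.float32),
        TrkField.VOXEL_SIZES: np.sqrt((affine[:3, :3] ** 2).sum(axis=0)).astype(np.float32),
        TrkField.DIMENSIONS: np.asarray(dims, dtype=np.int16),
        TrkField.VOXEL_ORDER: b"RAS",
    }
    TrkFile(tractogram, header=header).save(str(path))
    return path


def read_behavior_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: behavior table missing columns {missing}")
    if df.empty:
        raise EmptyInputError(f"{path}: behavior table has no trials")
    return df


def write_behavior_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
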