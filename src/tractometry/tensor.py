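"""Per-voxel diffusion tensor fitting and FA/MD map derivation.

The tensor D (mm^2/s) is fitted by log-linear least squares:
log(S/S0) = -b g^T D g, one equation per diffusion-weighted channel.
S0 is the mean of the b=0 channels. Non-positive signals are clamped to
the smallest positive measured signal in that voxel before the log;
negative eigenvalues are clamped to zero before computing FA and MD.

Fractional anisotropy and mean diffusivity follow the standard
eigenvalue formulas:

    FA = sqrt(3/2) * sqrt(sum((l_i - l_mean)^2)) / sqrt(sum(l_i^2))
    MD = (l_1 + l_2 + l_3) / 3
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError, InsufficientDataError
from .io import ScalarVolume

__all__ = [
    "BTable",
    "TensorField",
    "fit_tensor",
    "fa_from_eigenvalues",
    "md_from_eigenvalues",
    "axially_symmetric_eigenvalues",
    "fa_map",
    "md_map",
    "white_matter_mask",
]

logger = logging.getLogger(__name__)


@dataclass
class BTable:
    """Acquisition b-values (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (len(self.bvals), 3):
            raise FormatError(
                f"bvecs shape {self.bvecs.shape} does not match {len(self.bvals)} bvals"
            )
        if not np.any(self.bvals == 0):
            raise FormatError("b-table must contain at least one b=0 channel")
        norms = np.linalg.norm(self.bvecs[self.bvals > 0], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise FormatError("nonzero-b gradient directions must have unit norm (tol 1e-3)")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @classmethod
    def from_fsl(cls, bval_path: str | Path, bvec_path: str | Path) -> "BTable":
        """Read FSL-style bval (1 x M) and bvec (3 x M) text files."""
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
            bvecs = bvecs.T
        elif bvecs.shape == (3, 3) and len(bvals) == 3:
            pass  # ambiguous 3x3; assume rows are channels
        return cls(bvals=bvals, bvecs=bvecs)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors and fit residuals."""

    tensors: np.ndarray      # (X, Y, Z, 3, 3), zeros outside mask
    mask: np.ndarray         # (X, Y, Z) bool
    residual: np.ndarray     # (X, Y, Z) RMS log-signal residual
    affine: np.ndarray

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues per voxel, descending order, shape (X, Y, Z, 3)."""
        vals = np.linalg.eigvalsh(self.tensors)
        return vals[..., ::-1]


# Design matrix row for direction g, b-value b:
#   -b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz]
_IJ = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def _design_matrix(btable: BTable) -> np.ndarray:
    g = btable.bvecs
    cols = [g[:, i] * g[:, j] * (1 if i == j else 2) for i, j in _IJ]
    return -btable.bvals[:, None] * np.column_stack(cols)


def _unpack(d6: np.ndarray) -> np.ndarray:
    """(..., 6) tensor components -> (..., 3, 3) symmetric matrices."""
    out = np.zeros((*d6.shape[:-1], 3, 3))
    for k, (i, j) in enumerate(_IJ):
        out[..., i, j] = d6[..., k]
        out[..., j, i] = d6[..., k]
    return out


def fit_tensor(
    dwi: np.ndarray,
    btable: BTable,
    mask: ScalarVolume | np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> TensorField:
    """Log-linear least-squares tensor fit per masked voxel.

    ``dwi`` is a 4-D grid whose last axis matches the b-table. Requires
    at least six nonzero-b directions plus one b=0 channel.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise InsufficientDataError(f"dwi must be 4-D, got {dwi.ndim}-D")
    if dwi.shape[-1] != len(btable.bvals):
        raise InsufficientDataError(
            f"dwi has {dwi.shape[-1]} channels but b-table lists {len(btable.bvals)}"
        )
    n_dw = int((~btable.b0_mask).sum())
    n_b0 = int(btable.b0_mask.sum())
    if n_dw < 6 or n_b0 < 1:
        raise InsufficientDataError(
            f"need >= 6 diffusion-weighted + >= 1 b=0 channels, got {n_dw} + {n_b0}"
        )
    shape = dwi.shape[:3]
    if mask is None:
        mask_arr = np.ones(shape, dtype=bool)
    else:
        mask_arr = (mask.data if isinstance(mask, ScalarVolume) else np.asarray(mask)) > 0.5
        if mask_arr.shape != shape:
            raise InsufficientDataError("mask shape does not match dwi grid")
    if affine is None:
        affine = mask.affine if isinstance(mask, ScalarVolume) else np.eye(4)

    dw_mask = ~btable.b0_mask
    X = _design_matrix(btable)[dw_mask]            # (M, 6)
    signals = dwi[mask_arr]                        # (V, C)
    s0 = signals[:, btable.b0_mask].mean(axis=1)   # (V,)

    # Clamp non-positive signals to the smallest positive signal per voxel.
    dw = signals[:, dw_mask]
    pos_min = np.where(dw > 0, dw, np.inf).min(axis=1)
    pos_min = np.where(np.isfinite(pos_min), pos_min, 1e-12)
    dw = np.where(dw > 0, dw, pos_min[:, None])
    s0 = np.where(s0 > 0, s0, pos_min)

    y = np.log(dw / s0[:, None])                   # (V, M)
    coef, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # (6, V)
    resid = y - (X @ coef).T
    rms = np.sqrt((resid ** 2).mean(axis=1))

    tensors = np.zeros((*shape, 3, 3))
    tensors[mask_arr] = _unpack(coef.T)
    residual = np.zeros(shape)
    residual[mask_arr] = rms
    return TensorField(tensors=tensors, mask=mask_arr, residual=residual,
                       affine=np.asarray(affine, dtype=float))


def fa_from_eigenvalues(eigenvalues: np.ndarray) -> np.ndarray:
    """FA from (..., 3) eigenvalues; negative values clamped to 0."""
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def md_from_eigenvalues(eigenvalues: np.ndarray) -> np.ndarray:
    """MD (mm^2/s) from (..., 3) eigenvalues; negative values clamped to 0."""
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    return lam.mean(axis=-1)


def axially_symmetric_eigenvalues(fa: float, md: float) -> np.ndarray:
    """Eigenvalues (l1 >= l2 = l3) of a prolate tensor with given FA and MD.

    With l1 = m + 2d and l2 = l3 = m - d (m = MD), the FA formula gives
    d = m * sqrt(3) * FA / sqrt(9 - 6 FA^2).
    """
    if not 0 <= fa < 1:
        raise ValueError(f"fa must lie in [0, 1), got {fa}")
    d = md * np.sqrt(3.0) * fa / np.sqrt(9.0 - 6.0 * fa ** 2)
    return np.array([md + 2 * d, md - d, md - d])


def fa_map(field: TensorField) -> ScalarVolume:
    """Fractional anisotropy map from a fitted tensor field."""
    lam = field.eigenvalues()
    all_zero = np.all(lam == 0, axis=-1) & field.mask
    if np.any(all_zero):
        warnings.warn(
            f"{int(all_zero.sum())} masked voxel(s) have an all-zero tensor; FA set to 0",
            stacklevel=2,
        )
    fa = fa_from_eigenvalues(lam)
    fa[~field.mask] = 0.0
    return ScalarVolume(data=fa, affine=field.affine, kind="FA")


def md_map(field: TensorField) -> ScalarVolume:
    """Mean diffusivity map (mm^2/s) from a fitted tensor field."""
    md = md_from_eigenvalues(field.eigenvalues())
    md[~field.mask] = 0.0
    return ScalarVolume(data=md, affine=field.affine, kind="MD")


def white_matter_mask(fa: ScalarVolume, threshold: float = 0.15) -> ScalarVolume:
    """Binary mask of voxels with FA strictly greater than ``threshold``.

    The default 0.15 excludes grey matter and ventricles; voxels at
    exactly the threshold are excluded (strict inequality).
    """
    mask = (np.asarray(fa.data) > threshold).astype(float)
    return ScalarVolume(data=mask, affine=fa.affine, kind="mask")
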