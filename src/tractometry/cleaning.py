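"""Streamline resampling, core-tract estimation and outlier rejection.

A bundle is reduced to node correspondence by resampling every
streamline to ``n_nodes`` equidistant arc-length positions after
orienting all streamlines the same way. The core tract is the per-node
mean and covariance across streamlines. Fascicles whose node-wise
Mahalanobis distance from the core (aggregated over nodes) exceeds
``dist_sd`` standard deviations, or whose polyline length exceeds the
bundle mean by more than ``len_sd`` length-SDs (one-sided: only
too-long fascicles are suspect), are removed iteratively until the
bundle is stable. A bundle retaining fewer than ``min_fascicles``
streamlines is reported as a tracking failure, not an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig
from .errors import GeometryError, InsufficientBundleError

__all__ = [
    "streamline_length",
    "resample_streamline",
    "orient_bundle",
    "ResampledBundle",
    "CoreTract",
    "core_tract",
    "fascicle_distance",
    "CleaningResult",
    "clean_bundle",
    "retention_fraction",
]

logger = logging.getLogger(__name__)

# Floor added to every node covariance (mm^2); keeps degenerate bundles finite.
COV_EPSILON = 1e-6
# Condition number above which the covariance is shrunk toward its diagonal.
COV_MAX_CONDITION = 1e10


def streamline_length(points: np.ndarray) -> float:
    """Polyline arc length in mm."""
    points = np.asarray(points, dtype=float)
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def resample_streamline(points: np.ndarray, n_nodes: int) -> np.ndarray:
    """Resample a polyline to ``n_nodes`` equal-arc-length nodes.

    Nodes are linearly interpolated along the polyline; the first and
    last input points are preserved exactly.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
        raise GeometryError("streamline must be an (n>=2, 3) array")
    if not np.all(np.isfinite(points)):
        raise GeometryError("streamline has non-finite coordinates")
    if n_nodes < 2:
        raise GeometryError(f"n_nodes must be >= 2, got {n_nodes}")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise GeometryError("degenerate zero-length streamline")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n_nodes)
    out = np.column_stack([np.interp(targets, s, points[:, c]) for c in range(3)])
    out[0], out[-1] = points[0], points[-1]
    return out


@dataclass
class ResampledBundle:
    """Node-corresponding representation of a bundle.

    ``nodes`` has shape (n_streamlines, n_nodes, 3); ``lengths`` are the
    original polyline arc lengths (resampling would alias the length of
    high-curvature fascicles). ``oriented`` records that node 0 of every
    streamline is the end nearest the designated start anchor.
    """

    nodes: np.ndarray
    lengths: np.ndarray
    orientation_flipped: np.ndarray
    oriented: bool = True
    start_anchor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.nodes.ndim != 3 or self.nodes.shape[2] != 3:
            raise GeometryError("nodes must have shape (n_streamlines, n_nodes, 3)")

    @property
    def n_streamlines(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[1]

    def subset(self, indices) -> "ResampledBundle":
        idx = np.asarray(indices, dtype=int)
        return ResampledBundle(
            nodes=self.nodes[idx],
            lengths=self.lengths[idx],
            orientation_flipped=np.asarray(self.orientation_flipped)[idx],
            oriented=self.oriented,
            start_anchor=self.start_anchor,
        )


def orient_bundle(
    streamlines: list[np.ndarray],
    start_anchor: np.ndarray,
    n_nodes: int = 100,
) -> ResampledBundle:
    """Flip streamlines so node 0 is nearest ``start_anchor``, then resample.

    A streamline is flipped when its stored last point is strictly
    nearer the anchor than its first point; exact ties keep the stored
    order.
    """
    if not streamlines:
        raise InsufficientBundleError("cannot orient an empty bundle")
    anchor = np.asarray(start_anchor, dtype=float)
    nodes, lengths, flipped = [], [], []
    for s in streamlines:
        s = np.asarray(s, dtype=float)
        flip = np.linalg.norm(s[-1] - anchor) < np.linalg.norm(s[0] - anchor)
        if flip:
            s = s[::-1]
        nodes.append(resample_streamline(s, n_nodes))
        lengths.append(streamline_length(s))
        flipped.append(flip)
    return ResampledBundle(
        nodes=np.stack(nodes),
        lengths=np.asarray(lengths),
        orientation_flipped=np.asarray(flipped, dtype=bool),
        oriented=True,
        start_anchor=anchor,
    )


@dataclass
class CoreTract:
    """Per-node mean and covariance of a bundle plus length statistics."""

    mean_position: np.ndarray       # (n_nodes, 3)
    node_covariance: np.ndarray     # (n_nodes, 3, 3), regularized SPD
    mean_length: float
    length_sd: float

    @property
    def n_nodes(self) -> int:
        return self.mean_position.shape[0]


def _regularize_covariance(cov: np.ndarray) -> np.ndarray:
    """Make per-node covariances safely invertible.

    Adds a small isotropic floor, and shrinks toward the diagonal when a
    node is still ill-conditioned (tiny bundles yield rank-deficient
    sample covariances).
    """
    cov = cov + COV_EPSILON * np.eye(3)
    eigvals = np.linalg.eigvalsh(cov)
    cond = eigvals[:, -1] / np.maximum(eigvals[:, 0], 1e-300)
    bad = cond > COV_MAX_CONDITION
    if np.any(bad):
        diag = np.zeros_like(cov[bad])
        d = np.einsum("nii->ni", cov[bad])
        diag[:, np.arange(3), np.arange(3)] = d
        cov[bad] = 0.5 * cov[bad] + 0.5 * diag + COV_EPSILON * np.eye(3)
    return cov


def core_tract(bundle: ResampledBundle) -> CoreTract:
    """Mean position and covariance per node; length mean and SD.

    Covariances use the unbiased (n-1) normalisation and are regularized
    so that Mahalanobis distances are always finite.
    """
    if bundle.n_streamlines < 2:
        raise InsufficientBundleError(
            f"core tract needs >= 2 streamlines, got {bundle.n_streamlines}"
        )
    mean = bundle.nodes.mean(axis=0)
    centred = bundle.nodes - mean  # (S, N, 3)
    cov = np.einsum("sni,snj->nij", centred, centred) / (bundle.n_streamlines - 1)
    return CoreTract(
        mean_position=mean,
        node_covariance=_regularize_covariance(cov),
        mean_length=float(bundle.lengths.mean()),
        length_sd=float(bundle.lengths.std(ddof=1)),
    )


def node_mahalanobis(bundle: ResampledBundle, core: CoreTract) -> np.ndarray:
    """Node-wise Mahalanobis distance of every streamline from the core.

    Returns an (n_streamlines, n_nodes) array in SD units.
    """
    if bundle.n_nodes != core.n_nodes:
        raise GeometryError(
            f"bundle has {bundle.n_nodes} nodes but core has {core.n_nodes}"
        )
    diff = bundle.nodes - core.mean_position          # (S, N, 3)
    chol = np.linalg.cholesky(core.node_covariance)   # (N, 3, 3)
    # Solve L y = diff per node; |y| is the Mahalanobis distance.
    y = np.linalg.solve(chol[None, :, :, :], diff[..., None])[..., 0]
    return np.linalg.norm(y, axis=-1)


def fascicle_distance(
    bundle: ResampledBundle, core: CoreTract, stat: str = "mean"
) -> np.ndarray:
    """Per-streamline distance score from the core, in SD units.

    Node-wise Mahalanobis distances are aggregated with ``stat``
    ("mean", the convention of the tract-profile lineage, or "max").
    """
    d = node_mahalanobis(bundle, core)
    if stat == "mean":
        return d.mean(axis=1)
    if stat == "max":
        return d.max(axis=1)
    raise ValueError(f"unknown distance statistic {stat!r}")


@dataclass
class CleaningResult:
    """Outcome of iterative outlier rejection on one bundle."""

    kept: list[int]
    removed_distance: list[int]
    removed_length: list[int]
    iterations: int
    failed: bool
    converged: bool = True
    original_count: int = 0
    log: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kept": list(map(int, self.kept)),
            "removed_distance": list(map(int, self.removed_distance)),
            "removed_length": list(map(int, self.removed_length)),
            "iterations": self.iterations,
            "failed": self.failed,
            "converged": self.converged,
            "original_count": self.original_count,
            "log": self.log,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def clean_bundle(bundle: ResampledBundle, config: RunConfig | None = None) -> CleaningResult:
    """Iteratively remove positional and length outliers from a bundle.

    Each iteration recomputes the core from the surviving streamlines,
    then removes (as one union) every fascicle whose distance score
    exceeds ``dist_sd`` or whose length exceeds
    ``mean_length + len_sd * length_sd``. Iteration stops when a pass
    removes nothing or after ``max_clean_iterations``. Failure to retain
    ``min_fascicles`` streamlines is reported in the result, never
    raised.
    """
    config = config or RunConfig()
    n = bundle.n_streamlines
    kept = np.arange(n)
    removed_distance: list[int] = []
    removed_length: list[int] = []
    iterations = 0
    converged = True
    log: list[dict] = []

    while iterations < config.max_clean_iterations:
        iterations += 1
        if len(kept) < 2:
            break
        sub = bundle.subset(kept)
        core = core_tract(sub)
        scores = fascicle_distance(sub, core, config.distance_stat)
        far = scores > config.dist_sd
        length_limit = core.mean_length + config.len_sd * core.length_sd
        too_long = sub.lengths > length_limit
        drop = far | too_long
        n_drop = int(drop.sum())
        log.append(
            {
                "iteration": iterations,
                "n_in": int(len(kept)),
                "removed_distance": int(far.sum()),
                "removed_length": int((too_long & ~far).sum()),
            }
        )
        logger.info(
            "cleaning iteration %d: %d in, %d distance outliers, %d length outliers",
            iterations, len(kept), int(far.sum()), int((too_long & ~far).sum()),
        )
        if n_drop == 0:
            break
        removed_distance.extend(kept[far].tolist())
        removed_length.extend(kept[too_long & ~far].tolist())
        kept = kept[~drop]
    else:
        converged = False
        logger.warning("cleaning did not converge in %d iterations", config.max_clean_iterations)

    failed = len(kept) < config.min_fascicles
    if failed:
        logger.info("bundle flagged as tracking failure: %d < %d fascicles survive",
                    len(kept), config.min_fascicles)
    return CleaningResult(
        kept=sorted(int(i) for i in kept),
        removed_distance=sorted(removed_distance),
        removed_length=sorted(removed_length),
        iterations=iterations,
        failed=failed,
        converged=converged,
        original_count=n,
        log=log,
    )


def retention_fraction(result: CleaningResult, original_count: int | None = None) -> float:
    """Fraction of the original fascicles surviving the cleaning."""
    count = original_count if original_count is not None else result.original_count
    if count <= 0:
        raise ValueError("original_count must be positive")
    return len(result.kept) / count
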