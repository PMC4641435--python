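"""Synthetic bundles, scalar volumes, diffusion signals and 2AFC behaviour.

These generators provide inputs with the statistical structure the
analysis assumes — coherent fascicle bundles with planted outliers,
FA/MD fields with a focal lesion, diffusion-weighted signals from a
known tensor, and psychometric trial tables — together with the ground
truth needed to test every downstream stage.

Conventions
-----------
* Inlier fascicles are the core curve plus a smooth band-limited
  perturbation: randomized-phase sinusoids whose per-coordinate SD is
  exactly ``jitter_sd`` at every point. Smoothness keeps arc-length
  correspondence between fascicles, which per-point white noise would
  destroy. Each fascicle's derivative energy is normalised to the
  ensemble mean so that inlier arc lengths vary only through the
  Gaussian first-order term, not the skewed quadratic one — planted
  length outliers are then cleanly separable from inlier length
  scatter. Fascicle endpoints scatter around the ROI centroids (the
  core curve's endpoints), as real fascicles terminate across the ROI
  volume rather than at its centroid.
* Positional outliers are displaced by ``outlier_offset`` mm along a
  plateau covering the midsection of the tract.
* Length outliers carry a small-amplitude high-frequency wiggle sized
  to extend their arc length well past the bundle's length spread
  without moving them far from the core.
* DWI noise is Rician (magnitude-signal convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .errors import SpecError
from .io import ScalarVolume, StreamlineFile
from .tensor import BTable, axially_symmetric_eigenvalues

__all__ = [
    "BundleSpec",
    "LesionSpec",
    "PsychoSpec",
    "curved_core",
    "gen_bundle",
    "gen_scalar_volumes",
    "gen_dwi",
    "gen_behavior",
]

DEFAULT_CONTRASTS = (0.01, 0.05, 0.10, 0.50, 1.00)


def curved_core(
    start: Sequence[float], end: Sequence[float], bow_mm: float = 8.0,
    bow_direction: Sequence[float] = (0.0, 0.0, 1.0),
) -> Callable[[np.ndarray], np.ndarray]:
    """A gently bowed parametric curve between two ROI centroids.

    Returns ``f(t) -> (len(t), 3)`` for t in [0, 1], a straight segment
    plus a half-sine bow of amplitude ``bow_mm``.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    direction = np.asarray(bow_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    def f(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        line = start[None, :] + t[:, None] * (end - start)[None, :]
        return line + bow_mm * np.sin(np.pi * t)[:, None] * direction[None, :]

    return f


@dataclass
class BundleSpec:
    """Recipe for one synthetic fascicle bundle.

    ``core_curve`` maps t in [0, 1] to world mm; its endpoints are the
    two ROI centroids. ``jitter_sd`` is the per-coordinate SD (mm) of
    the smooth positional jitter at mid-tract. Positional outliers are
    displaced by ``outlier_offset`` mm (must clearly exceed the jitter);
    length outliers are extended by ``length_outlier_scale`` times the
    inlier length SD.
    """

    core_curve: Callable[[np.ndarray], np.ndarray]
    n_fascicles: int = 100
    jitter_sd: float = 1.0
    outlier_fraction: float = 0.0
    outlier_offset: float = 10.0
    length_outlier_fraction: float = 0.0
    length_outlier_scale: float = 8.0
    n_points: int = 200
    n_harmonics: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fascicles < 2:
            raise SpecError(f"n_fascicles must be >= 2, got {self.n_fascicles}")
        for name in ("outlier_fraction", "length_outlier_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise SpecError(f"{name} must lie in [0, 1), got {v}")
        if self.jitter_sd <= 0:
            raise SpecError("jitter_sd must be positive")
        if self.outlier_fraction > 0 and self.outlier_offset <= self.jitter_sd:
            raise SpecError("outlier_offset must exceed jitter_sd")


def _smooth_jitter(rng: np.random.Generator, t: np.ndarray, sd: float, n_harmonics: int) -> np.ndarray:
    """Stationary smooth perturbation with per-coordinate SD = sd everywhere.

    Sum of the first ``n_harmonics`` sine/cosine pairs with Gaussian
    coefficients; sin^2 + cos^2 = 1 makes the per-point variance exactly
    sd^2 per coordinate at every t. The derivative-weighted coefficient
    energy sum(h^2 |c_h|^2) is normalised to its ensemble mean so the
    (chi-square distributed, skewed) quadratic arc-length contribution
    is common to all fascicles and inlier lengths stay Gaussian.
    """
    H = n_harmonics
    h = np.arange(1, H + 1)
    a = rng.normal(0.0, sd / np.sqrt(H), size=(3, H))
    b = rng.normal(0.0, sd / np.sqrt(H), size=(3, H))
    energy = np.sum(h ** 2 * (a ** 2 + b ** 2))
    target = 6.0 * sd ** 2 / H * np.sum(h ** 2)
    scale = np.sqrt(target / energy)
    a *= scale
    b *= scale
    phase = np.pi * np.outer(t, h)               # (T, H)
    return np.sin(phase) @ a.T + np.cos(phase) @ b.T


def _midsection_plateau(t: np.ndarray, ramp: float = 0.2) -> np.ndarray:
    """Displacement profile: 0 at endpoints, cosine ramps, 1 on the midsection."""
    w = np.ones_like(t)
    lo = t < ramp
    hi = t > 1 - ramp
    w[lo] = 0.5 * (1 - np.cos(np.pi * t[lo] / ramp))
    w[hi] = 0.5 * (1 - np.cos(np.pi * (1 - t[hi]) / ramp))
    return w


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def gen_bundle(spec: BundleSpec) -> StreamlineFile:
    """Generate a coherent bundle with planted, ground-truthed outliers.

    Returns a :class:`StreamlineFile` whose ``outlier_indices`` lists
    the planted positional and length outliers (positional first).
    """
    rng = np.random.default_rng(spec.rng_seed)
    t = np.linspace(0.0, 1.0, spec.n_points)
    core = spec.core_curve(t)
    if core.shape != (spec.n_points, 3):
        raise SpecError("core_curve must return a (len(t), 3) array")

    streamlines = [core + _smooth_jitter(rng, t, spec.jitter_sd, spec.n_harmonics)
                   for _ in range(spec.n_fascicles)]

    n_pos = int(round(spec.outlier_fraction * spec.n_fascicles))
    n_len = int(round(spec.length_outlier_fraction * spec.n_fascicles))
    outliers = rng.choice(spec.n_fascicles, size=n_pos + n_len, replace=False)
    pos_outliers, len_outliers = outliers[:n_pos], outliers[n_pos:]

    plateau = _midsection_plateau(t)
    for i in pos_outliers:
        streamlines[i] = streamlines[i] + spec.outlier_offset * plateau[:, None] * _random_unit(rng)

    if n_len:
        inlier_idx = np.setdiff1d(np.arange(spec.n_fascicles), outliers)
        inlier_lengths = [_polyline_length(streamlines[i]) for i in inlier_idx]
        target_extra = max(spec.length_outlier_scale * float(np.std(inlier_lengths, ddof=1)),
                           0.02 * float(np.mean(inlier_lengths)))
        for i in len_outliers:
            streamlines[i] = _extend_length(rng, streamlines[i], t, plateau,
                                            target_extra, spec.jitter_sd)

    return StreamlineFile(
        streamlines=streamlines,
        outlier_indices=sorted(int(i) for i in outliers),
    )


def _extend_length(
    rng: np.random.Generator,
    points: np.ndarray,
    t: np.ndarray,
    plateau: np.ndarray,
    target_extra_mm: float,
    jitter_sd: float,
    cycles: int = 18,
) -> np.ndarray:
    """Add a transverse high-frequency wiggle extending arc length by ~target.

    The wiggle amplitude is solved by bisection and capped so the
    fascicle stays positionally close to the core (it should trip the
    length criterion, not the distance criterion). If the cap cannot
    reach the target the wiggle frequency is raised instead.
    """
    base_len = _polyline_length(points)
    direction = _random_unit(rng)
    wave = np.sin(2 * np.pi * cycles * t) * plateau

    def extended(amp: float, ncyc: int) -> np.ndarray:
        w = np.sin(2 * np.pi * ncyc * t) * plateau
        return points + amp * w[:, None] * direction[None, :]

    amp_cap = 1.5 * jitter_sd
    ncyc = cycles
    while _polyline_length(extended(amp_cap, ncyc)) - base_len < target_extra_mm:
        ncyc *= 2
        if ncyc > len(t) // 4:  # resolution limit of the polyline
            break
    lo, hi = 0.0, amp_cap
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _polyline_length(extended(mid, ncyc)) - base_len < target_extra_mm:
            lo = mid
        else:
            hi = mid
    return extended(hi, ncyc)


@dataclass
class LesionSpec:
    """A spherical focal lesion: reduced FA, elevated MD inside."""

    center: Sequence[float] = (0.0, 0.0, 0.0)
    radius: float = 10.0
    fa_inside: float = 0.15
    md_inside: float = 1.5e-3
    fa_background: float = 0.5
    md_background: float = 0.75e-3

    def __post_init__(self) -> None:
        if not self.fa_inside < self.fa_background:
            raise SpecError("lesion must reduce FA: fa_inside < fa_background")
        if not self.md_inside > self.md_background:
            raise SpecError("lesion must elevate MD: md_inside > md_background")
        if self.radius <= 0:
            raise SpecError("radius must be positive")


def gen_scalar_volumes(
    lesion: LesionSpec,
    shape: tuple[int, int, int] = (40, 40, 40),
    voxel_mm: float | Sequence[float] = 2.0,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    transition_voxels: float = 1.0,
) -> tuple[ScalarVolume, ScalarVolume]:
    """FA and MD volumes with a spherical lesion, on a shared affine.

    The lesion edge uses a smooth linear ramp one voxel wide.
    """
    voxel = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    affine = np.diag([*voxel, 1.0])
    affine[:3, 3] = origin
    center_vox = (np.asarray(lesion.center, dtype=float) - np.asarray(origin)) / voxel
    if np.any(center_vox - lesion.radius / voxel < 0) or np.any(
        center_vox + lesion.radius / voxel > np.asarray(shape) - 1
    ):
        raise SpecError("lesion sphere does not fit inside the grid")

    idx = np.indices(shape, dtype=float)
    world = idx * voxel.reshape(3, 1, 1, 1) + np.asarray(origin).reshape(3, 1, 1, 1)
    r = np.sqrt(((world - np.asarray(lesion.center).reshape(3, 1, 1, 1)) ** 2).sum(axis=0))

    band = transition_voxels * float(voxel.mean())
    # inside weight: 1 within the sphere, linear ramp to 0 over `band`
    inside = np.clip((lesion.radius + 0.5 * band - r) / max(band, 1e-9), 0.0, 1.0)
    fa = lesion.fa_background + (lesion.fa_inside - lesion.fa_background) * inside
    md = lesion.md_background + (lesion.md_inside - lesion.md_background) * inside
    return (
        ScalarVolume(data=fa, affine=affine, kind="FA"),
        ScalarVolume(data=md, affine=affine, kind="MD"),
    )


def gen_dwi(
    fa_target: float,
    md_target: float,
    btable: BTable,
    snr: float = np.inf,
    rng_seed: int = 0,
    shape: tuple[int, int, int] = (8, 8, 8),
    s0: float = 1.0,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
) -> np.ndarray:
    """4-D diffusion-weighted signal from an axially symmetric tensor.

    The tensor's analytic FA and MD equal the targets exactly; the
    signal is S = S0 * exp(-b g^T D g) with Rician noise at the stated
    SNR (sigma = S0 / snr) added to the magnitude.
    """
    if not 0 <= fa_target < 1:
        raise SpecError(f"fa_target must lie in [0, 1), got {fa_target}")
    if md_target <= 0:
        raise SpecError("md_target must be positive")
    lams = axially_symmetric_eigenvalues(fa_target, md_target)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # Build D with principal eigenvector along `axis`
    any_v = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(axis, any_v)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(axis, e2)
    R = np.column_stack([axis, e2, e3])
    D = R @ np.diag(lams) @ R.T

    g = np.asarray(btable.bvecs, dtype=float)
    b = np.asarray(btable.bvals, dtype=float)
    atten = np.exp(-b * np.einsum("mi,ij,mj->m", g, D, g))
    signal = np.broadcast_to(s0 * atten, (*shape, len(b))).copy()

    if np.isfinite(snr):
        rng = np.random.default_rng(rng_seed)
        sigma = s0 / snr
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)
    return signal


@dataclass
class PsychoSpec:
    """Psychometric recipe for one participant group.

    Accuracy follows a 2AFC psychometric function
    ``P(correct) = guess + (1 - guess - lapse) * logistic(slope * (log c - log c50))``
    with ``guess`` fixed at 0.5. Fixation deviations are half-normal
    with scale set so the probability of exceeding 1 degree equals
    ``fixation_break_rate``.
    """

    contrasts: tuple[float, ...] = DEFAULT_CONTRASTS
    n_trials_per_contrast: int = 20
    guess_rate: float = 0.5
    c50: float = 0.05
    slope: float = 4.0
    lapse: float = 0.02
    fixation_break_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 < c <= 1 for c in self.contrasts):
            raise SpecError("contrasts must lie in (0, 1]")
        if self.guess_rate != 0.5:
            raise SpecError("guess_rate is fixed at 0.5 for 2AFC")
        if not 0 <= self.lapse < 0.5:
            raise SpecError("lapse must lie in [0, 0.5)")
        if not 0 <= self.fixation_break_rate < 1:
            raise SpecError("fixation_break_rate must lie in [0, 1)")
        if self.n_trials_per_contrast < 1:
            raise SpecError("n_trials_per_contrast must be >= 1")

    def p_correct(self, contrast: float) -> float:
        x = self.slope * (np.log(contrast) - np.log(self.c50))
        return float(self.guess_rate + (1 - self.guess_rate - self.lapse) * expit(x))


def _fixation_scale(rate: float) -> float:
    """Half-normal scale with P(deviation > 1 deg) = rate.

    For rate 0 a nominal 0.2 deg scale is used (exceedance ~ 6e-7).
    """
    if rate <= 0:
        return 0.2
    return 1.0 / ndtri(1.0 - rate / 2.0)


def gen_behavior(
    spec: PsychoSpec,
    participant_ids: Sequence[str],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a 2AFC trial table for the given participants.

    Columns: participant, contrast, true_interval, response,
    fixation_deg. Trial order is contrast-blocked for readability;
    downstream scoring is order-invariant.
    """
    if len(participant_ids) == 0:
        raise SpecError("participant_ids must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    scale = _fixation_scale(spec.fixation_break_rate)
    rows = []
    for pid in participant_ids:
        for contrast in spec.contrasts:
            p = spec.p_correct(contrast)
            n = spec.n_trials_per_contrast
            true_interval = rng.integers(1, 3, size=n)
            correct = rng.random(n) < p
            response = np.where(correct, true_interval, 3 - true_interval)
            deviation = np.abs(rng.normal(0.0, scale, size=n))
            for j in range(n):
                rows.append((pid, contrast, int(true_interval[j]),
                             int(response[j]), float(deviation[j])))
    return pd.DataFrame(
        rows, columns=["participant", "contrast", "true_interval", "response", "fixation_deg"]
    )
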