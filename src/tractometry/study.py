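"""Simulate a complete small study on disk: bundles, volumes, behaviour, manifest.

This builds the dataset the end-to-end pipeline expects: per
participant, one tract per hemisphere (mirrored geniculate-hMT+-like
geometry), shared FA/MD volumes in which patients carry a focal lesion
intersecting the distal portion of the ipsilesional bundle (large for
the "negative" group, mild for "positive", none for controls), and a
2AFC behaviour table whose psychometric function matches the group
(low detection threshold for positives, no detectable signal for
negatives).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import RunConfig
from .io import write_behavior_table, write_streamlines, write_volume, ScalarVolume
from .synthetic import (
    BundleSpec,
    LesionSpec,
    PsychoSpec,
    curved_core,
    gen_behavior,
    gen_bundle,
    gen_scalar_volumes,
)

__all__ = ["StudySpec", "simulate_study", "bundle_endpoints"]

# Mirrored tract geometry (world mm): LGN-like start to hMT+-like end,
# one per hemisphere along +/- x.
LGN = {"ipsi": np.array([-20.0, 10.0, 0.0]), "contra": np.array([20.0, 10.0, 0.0])}
HMT = {"ipsi": np.array([-44.0, 64.0, 0.0]), "contra": np.array([44.0, 64.0, 0.0])}

GRID_SHAPE = (60, 50, 20)
VOXEL_MM = 2.0
GRID_ORIGIN = (-59.0, -15.0, -19.0)


def bundle_endpoints(hemi: str) -> tuple[np.ndarray, np.ndarray]:
    return LGN[hemi], HMT[hemi]


@dataclass
class StudySpec:
    """Cohort sizes and generator settings for a simulated study."""

    n_positive: int = 12
    n_negative: int = 5
    n_controls: int = 9
    n_fascicles: int = 100
    jitter_sd: float = 1.0
    outlier_fraction: float = 0.10
    outlier_offset_mm: float = 10.0
    lesion_radius_mm: float = 9.0
    positive_psycho: PsychoSpec = None  # type: ignore[assignment]
    negative_psycho: PsychoSpec = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.positive_psycho is None:
            self.positive_psycho = PsychoSpec(c50=0.05, slope=4.0, lapse=0.02)
        if self.negative_psycho is None:
            self.negative_psycho = PsychoSpec(c50=50.0, slope=4.0, lapse=0.0)


def _lesion_center(distal_fraction: float = 0.72) -> np.ndarray:
    """World position of the given arc fraction along the ipsi core curve."""
    core = curved_core(LGN["ipsi"], HMT["ipsi"])
    return core(np.array([distal_fraction]))[0]


def _patient_volumes(group: str, radius: float) -> tuple[ScalarVolume, ScalarVolume]:
    """FA/MD volumes; patients get a distal ipsilesional lesion."""
    if group == "negative":
        lesion = LesionSpec(center=_lesion_center(), radius=radius,
                            fa_inside=0.15, md_inside=1.5e-3)
    elif group == "positive":
        lesion = LesionSpec(center=_lesion_center(), radius=radius * 0.5,
                            fa_inside=0.38, md_inside=0.95e-3)
    else:
        # controls: a vanishingly mild sphere far from both bundles
        lesion = LesionSpec(center=(0.0, 0.0, 0.0), radius=2.0,
                            fa_inside=0.499, md_inside=0.7501e-3)
    return gen_scalar_volumes(lesion, shape=GRID_SHAPE, voxel_mm=VOXEL_MM,
                              origin=GRID_ORIGIN)


def simulate_study(
    out_dir: str | Path,
    spec: StudySpec | None = None,
    config: RunConfig | None = None,
) -> Path:
    """Write a full synthetic study under ``out_dir``; returns the manifest path.

    Every random draw is seeded from ``config.rng_seed``, so the same
    (spec, config) pair regenerates byte-identical inputs.
    """
    spec = spec or StudySpec()
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = np.random.SeedSequence(config.rng_seed)

    cohort = (
        [(f"PB{i + 1}", "positive") for i in range(spec.n_positive)]
        + [(f"PN{i + 1}", "negative") for i in range(spec.n_negative)]
        + [(f"C{i + 1}", "control") for i in range(spec.n_controls)]
    )
    participants = []
    child_seeds = seed.spawn(len(cohort))
    for (pid, group), part_seed in zip(cohort, child_seeds):
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        sub_seeds = part_seed.generate_state(4, dtype=np.uint32)
        entry: dict = {"id": pid, "group": group, "tracts": {"lgn_hmt": {}}, "volumes": {}}

        for hemi, hemi_seed in zip(("ipsi", "contra"), sub_seeds[:2]):
            start, end = bundle_endpoints(hemi)
            bundle = gen_bundle(
                BundleSpec(
                    core_curve=curved_core(start, end),
                    n_fascicles=spec.n_fascicles,
                    jitter_sd=spec.jitter_sd,
                    outlier_fraction=spec.outlier_fraction,
                    outlier_offset=spec.outlier_offset_mm * spec.jitter_sd,
                    rng_seed=int(hemi_seed),
                )
            )
            path = pdir / f"lgn_hmt_{hemi}.tck"
            write_streamlines(bundle, path)
            (pdir / f"lgn_hmt_{hemi}_truth.json").write_text(
                json.dumps({"outlier_indices": bundle.outlier_indices}) + "\n"
            )
            entry["tracts"]["lgn_hmt"][hemi] = {
                "bundle": str(path.relative_to(out_dir)),
                "start_anchor": start.tolist(),
            }

        fa, md = _patient_volumes(group, spec.lesion_radius_mm)
        for kind, vol in (("FA", fa), ("MD", md)):
            vpath = pdir / f"{kind.lower()}.nii.gz"
            write_volume(vol, vpath)
            entry["volumes"][kind] = str(vpath.relative_to(out_dir))

        if group in ("positive", "negative"):
            psycho = spec.positive_psycho if group == "positive" else spec.negative_psycho
            table = gen_behavior(psycho, [pid], rng=np.random.default_rng(int(sub_seeds[2])))
            bpath = pdir / "behavior.csv"
            write_behavior_table(table, bpath)
            entry["behavior"] = str(bpath.relative_to(out_dir))

        participants.append(entry)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps({"participants": participants}, indent=2) + "\n")
    return manifest_path
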