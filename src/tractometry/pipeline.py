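"""Manifest-driven end-to-end run: clean, profile, lateralise, classify, test.

The manifest is a JSON document listing participants, their group
("positive" / "negative" / "control"), per-tract bundle files with the
start-ROI (LGN-end) anchor for each hemisphere, shared FA/MD volumes,
and a behaviour trial table. Hemisphere keys are "ipsi" and "contra";
for controls put the right hemisphere under "ipsi" so the laterality
denominator matches the control convention (left-right over right).

Outputs are plain CSV tables plus per-bundle cleaning JSON; identical
inputs, config and seed give byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from .cleaning import clean_bundle, core_tract, orient_bundle, retention_fraction
from .config import RunConfig
from .errors import ManifestError, TractometryError
from .io import read_behavior_table, read_streamlines, read_volume
from .profiles import clip_profile, distal_summary, laterality, tract_profile
from .stats import two_way_anova

__all__ = ["PipelineReport", "run_pipeline"]

logger = logging.getLogger(__name__)

HEMISPHERES = ("ipsi", "contra")


@dataclass
class PipelineReport:
    """Tables produced by one pipeline run."""

    profiles: pd.DataFrame
    summaries: pd.DataFrame
    laterality: pd.DataFrame
    classification: pd.DataFrame
    stats_text: str
    out_dir: Path | None = None
    cleaning: dict = field(default_factory=dict)


def _require_file(path: Path, participant: str, role: str) -> Path:
    if not path.exists():
        raise ManifestError(f"participant {participant!r}: missing {role} file {path}")
    return path


def _load_manifest(manifest_path: str | Path) -> tuple[dict, Path]:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    if "participants" not in manifest or not manifest["participants"]:
        raise ManifestError(f"{manifest_path}: manifest lists no participants")
    return manifest, manifest_path.parent


def run_pipeline(
    config: RunConfig,
    manifest_path: str | Path,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run cleaning, profiling, laterality, classification and group stats.

    Relative paths in the manifest resolve against the manifest's
    directory. All randomness derives from ``config.rng_seed``.
    """
    manifest, root = _load_manifest(manifest_path)

    profile_rows, summary_rows, laterality_rows = [], [], []
    cleaning_results: dict[str, dict] = {}
    perf_rows = []

    for part in manifest["participants"]:
        pid = part["id"]
        group = part.get("group", "control")
        volumes = {
            kind: read_volume(_require_file(root / p, pid, f"{kind} volume"), kind=kind)
            for kind, p in part.get("volumes", {}).items()
        }
        for tract_name, hemis in part.get("tracts", {}).items():
            means: dict[tuple[str, str, str], float] = {}
            for hemi in HEMISPHERES:
                if hemi not in hemis:
                    continue
                entry = hemis[hemi]
                bundle_path = _require_file(root / entry["bundle"], pid, f"{tract_name}/{hemi} bundle")
                sf = read_streamlines(bundle_path)
                anchor = np.asarray(entry["start_anchor"], dtype=float)
                bundle = orient_bundle(sf.streamlines, anchor, config.n_nodes)
                result = clean_bundle(bundle, config)
                key = f"{pid}/{tract_name}/{hemi}"
                cleaning_results[key] = json.loads(result.to_json())
                logger.info(
                    "%s: kept %d/%d fascicles (retention %.2f)%s",
                    key, len(result.kept), result.original_count,
                    retention_fraction(result),
                    " [FAILED]" if result.failed else "",
                )
                if result.failed:
                    continue
                cleaned = bundle.subset(result.kept)
                core = core_tract(cleaned)
                for kind in ("FA", "MD"):
                    if kind not in volumes:
                        continue
                    prof = tract_profile(cleaned, core, volumes[kind], config)
                    for node, (v, s) in enumerate(zip(prof.node_values, prof.node_sd)):
                        profile_rows.append(
                            (pid, group, tract_name, hemi, kind, node, v, s)
                        )
                    whole_mean, whole_sd = clip_profile(prof, config)
                    distal_mean, distal_sd = distal_summary(prof, config)
                    summary_rows.append((pid, group, tract_name, hemi, kind,
                                         "whole", whole_mean, whole_sd))
                    summary_rows.append((pid, group, tract_name, hemi, kind,
                                         "distal", distal_mean, distal_sd))
                    means[(kind, "whole", hemi)] = whole_mean
                    means[(kind, "distal", hemi)] = distal_mean
            for kind in ("FA", "MD"):
                for rng_name in ("whole", "distal"):
                    ipsi = means.get((kind, rng_name, "ipsi"))
                    contra = means.get((kind, rng_name, "contra"))
                    if ipsi is None or contra is None:
                        continue
                    laterality_rows.append(
                        (pid, group, tract_name, kind, rng_name,
                         ipsi, contra, laterality(ipsi, contra))
                    )

        if "behavior" in part:
            table = read_behavior_table(_require_file(root / part["behavior"], pid, "behavior"))
            table = beh.exclude_fixation_breaks(table[table["participant"] == pid]
                                                if "participant" in table else table)
            perf = beh.score_performance(table)
            label = beh.classify_blindsight(perf, config.alpha)
            perf_rows.append((pid, group, perf, label))

    profiles = pd.DataFrame(
        profile_rows,
        columns=["participant", "group", "tract", "hemisphere", "scalar", "node", "value", "sd"],
    )
    summaries = pd.DataFrame(
        summary_rows,
        columns=["participant", "group", "tract", "hemisphere", "scalar", "range", "mean", "sd"],
    )
    laterality_df = pd.DataFrame(
        laterality_rows,
        columns=["participant", "group", "tract", "scalar", "range",
                 "mean_ipsi", "mean_contra", "laterality_pct"],
    )
    classification = _classify_cohort(perf_rows, config)
    stats_text = _group_stats_report(summaries, laterality_df)

    report = PipelineReport(
        profiles=profiles,
        summaries=summaries,
        laterality=laterality_df,
        classification=classification,
        stats_text=stats_text,
        cleaning=cleaning_results,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        profiles.to_csv(out_dir / "profiles.csv", index=False)
        summaries.to_csv(out_dir / "summaries.csv", index=False)
        laterality_df.to_csv(out_dir / "laterality.csv", index=False)
        classification.to_csv(out_dir / "classification.csv", index=False)
        (out_dir / "cleaning.json").write_text(json.dumps(cleaning_results, indent=2) + "\n")
        (out_dir / "stats.txt").write_text(stats_text)
        report.out_dir = out_dir
    return report


def _classify_cohort(perf_rows, config: RunConfig) -> pd.DataFrame:
    """Binomial labels plus k-NN and GMM cross-validation for the cohort."""
    if not perf_rows:
        return pd.DataFrame(
            columns=["participant", "group", "overall_pct", "p_overall", "p_at_100",
                     "label", "knn_pred", "gmm_pred"]
        )
    ids = [pid for pid, *_ in perf_rows]
    groups = [g for _, g, *_ in perf_rows]
    perfs = [p for _, _, p, _ in perf_rows]
    labels = [l.label for *_, l in perf_rows]
    contrasts = perfs[0].contrasts
    matrix = np.vstack([np.nan_to_num(p.percent_correct, nan=50.0) for p in perfs])
    if any(len(p.contrasts) != len(contrasts) for p in perfs):
        raise TractometryError("participants were tested at different contrast sets")
    knn_pred = [None] * len(ids)
    gmm_pred = [None] * len(ids)
    if len(ids) >= config.k + 1:
        knn_pred, knn_agree = beh.knn_crossval(matrix, labels, config.k)
        logger.info("k-NN agreement with binomial labels: %d/%d", knn_agree, len(ids))
    if len(ids) >= 3:
        try:
            gmm_pred, _ = beh.gmm_classify(matrix, rng_seed=config.rng_seed)
        except TractometryError as exc:
            logger.warning("GMM classification skipped: %s", exc)
    return pd.DataFrame(
        {
            "participant": ids,
            "group": groups,
            "overall_pct": [p.overall_percent for p in perfs],
            "p_overall": [l.p_overall for *_, l in perf_rows],
            "p_at_100": [l.p_at_100 for *_, l in perf_rows],
            "label": labels,
            "knn_pred": knn_pred,
            "gmm_pred": gmm_pred,
        }
    )


def _group_stats_report(summaries: pd.DataFrame, laterality_df: pd.DataFrame) -> str:
    """Two-way ANOVA (status x hemisphere) per tract/scalar/range where possible."""
    lines = ["Group statistics", "================", ""]
    n_tests = 0
    patients = summaries[summaries["group"].isin(["positive", "negative"])]
    for (tract, scalar, rng_name), sub in patients.groupby(["tract", "scalar", "range"]):
        cells = sub.groupby(["group", "hemisphere"]).size()
        if len(cells) < 4 or cells.min() < 1 or sub["group"].nunique() < 2:
            lines.append(f"{tract} {scalar} {rng_name}: skipped (incomplete design)")
            continue
        try:
            res = two_way_anova(sub, "mean", "group", "hemisphere")
        except TractometryError as exc:
            lines.append(f"{tract} {scalar} {rng_name}: skipped ({exc})")
            continue
        n_tests += 1
        lines.append(
            f"{tract} {scalar} {rng_name}: "
            f"status F={res.F_A:.2f} p={res.p_A:.4f}; "
            f"side F={res.F_B:.2f} p={res.p_B:.4f}; "
            f"interaction F={res.F_interaction:.2f} p={res.p_interaction:.4f} "
            f"(df error {res.df_error}, Type {res.ss_type} SS, n={len(sub)})"
        )
    lines.append("")
    lines.append(f"Tests run: {n_tests} (no multiple-comparison correction applied)")
    lines.append("")
    return "\n".join(lines)
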