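"""Run configuration shared by every pipeline stage.

The defaults encode the analysis conventions of the tract-profile
lineage this package implements: 100 nodes per tract, whole-tract
summaries clipped to nodes 15-85, distal summaries over nodes 60-85
(anchored at the LGN end), iterative outlier rejection at 2.6 SD
(distance) / 2.8 SD (length), a minimum of 10 surviving fascicles,
a p < 0.01 binomial detection criterion and k = 5 nearest neighbours.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Parameters controlling cleaning, profiling and classification.

    Attributes
    ----------
    n_nodes
        Number of equidistant nodes each streamline is resampled to.
    clip_range
        Inclusive node interval used for "whole tract" summaries; the
        proximal and distal nodes outside it are ignored to avoid
        grey-matter partial-volume contamination.
    distal_range
        Inclusive node interval (on the full profile) for the distal
        summary, measured from the start-ROI (LGN) end.
    dist_sd
        Mahalanobis-distance threshold, in SD units, beyond which a
        fascicle is rejected as a positional outlier.
    len_sd
        Length threshold: fascicles longer than mean + ``len_sd`` * SD
        of bundle length are rejected (one-sided).
    min_fascicles
        Bundles retaining fewer streamlines than this after cleaning
        are flagged as tracking failures.
    alpha
        Significance level of the binomial detection criterion.
    k
        Neighbour count for the k-NN cross-validation classifier.
    rng_seed
        Seed for every stochastic stage.
    distance_stat
        Aggregation of node-wise Mahalanobis distances into one score
        per fascicle: "mean" (default) or "max".
    weighting
        Profile weighting: "gaussian" (by core distance) or "uniform".
    interpolation
        Scalar sampling: "trilinear" (default) or "nearest".
    """

    n_nodes: int = 100
    clip_range: tuple[int, int] = (15, 85)
    distal_range: tuple[int, int] = (60, 85)
    dist_sd: float = 2.6
    len_sd: float = 2.8
    min_fascicles: int = 10
    alpha: float = 0.01
    k: int = 5
    rng_seed: int = 0
    distance_stat: str = "mean"
    weighting: str = "gaussian"
    interpolation: str = "trilinear"
    max_clean_iterations: int = 20

    def __post_init__(self) -> None:
        self.clip_range = tuple(int(v) for v in self.clip_range)  # type: ignore[assignment]
        self.distal_range = tuple(int(v) for v in self.distal_range)  # type: ignore[assignment]
        if self.n_nodes < 2:
            raise ConfigError(f"n_nodes must be >= 2, got {self.n_nodes}")
        for name in ("clip_range", "distal_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi < self.n_nodes):
                raise ConfigError(
                    f"{name}=({lo}, {hi}) must satisfy 0 <= lo <= hi < n_nodes={self.n_nodes}"
                )
        if self.dist_sd <= 0 or self.len_sd <= 0:
            raise ConfigError("dist_sd and len_sd must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.min_fascicles < 1:
            raise ConfigError("min_fascicles must be >= 1")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.distance_stat not in ("mean", "max"):
            raise ConfigError(f"distance_stat must be 'mean' or 'max', got {self.distance_stat!r}")
        if self.weighting not in ("gaussian", "uniform"):
            raise ConfigError(f"weighting must be 'gaussian' or 'uniform', got {self.weighting!r}")
        if self.interpolation not in ("trilinear", "nearest"):
            raise ConfigError(
                f"interpolation must be 'trilinear' or 'nearest', got {self.interpolation!r}"
            )

    def replace(self, **updates) -> "RunConfig":
        return dataclasses.replace(self, **updates)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clip_range"] = list(self.clip_range)
        d["distal_range"] = list(self.distal_range)
        return d


def _coerce(field: dataclasses.Field, raw: str):
    """Parse a flat key=value string into the field's type."""
    if field.name in ("clip_range", "distal_range"):
        parts = raw.replace("[", "").replace("]", "").replace(",", " ").split()
        return tuple(int(p) for p in parts)
    if field.type in ("int", int):
        return int(raw)
    if field.type in ("float", float):
        return float(raw)
    return raw


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a :class:`RunConfig` from JSON or flat ``key=value`` text.

    Keyword arguments override file values (the CLI passes its flags
    through here), so a run is fully described by (file, flags).
    """
    path = Path(path)
    text = path.read_text()
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        data = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
            data[key] = _coerce(fields[key], raw.strip())
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")
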