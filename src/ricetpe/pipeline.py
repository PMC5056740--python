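"""End-to-end pipeline: simulate -> best season -> classify -> stability ->
rank, with YAML configuration and a manifest recording every threshold used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as tpio
from .matrices import (
    best_season_slice,
    clean_unsuitable_dates,
    panels_from_cube,
    select_best_season,
)
from .ranking import adaptability_table
from .stability import indicator_table
from .synthetic import (
    ARCHETYPE_LABELS,
    SimulationDesign,
    default_varieties,
    make_archetype_grid,
    simulate_grid,
)
from .tpe import class_proportions, classify_grid, genotype_count_sensitivity

__all__ = ["PipelineConfig", "run_pipeline", "best_seasons_and_slices"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; defaults give the 50-environment demo."""

    outdir: str = "results/pipeline"
    n_environments: int = 50
    seed: int = 0
    # classification thresholds (all in (0, 1))
    yield_ratio: float = 0.75
    severity_bounds: tuple[float, float] = (0.25, 0.50)
    timing_factor: float = 0.90
    # clustering
    n_rank_groups: int = 5
    linkage_method: str = "ward"
    # genotype-count sensitivity
    sensitivity_sizes: list[int] = field(default_factory=list)
    sensitivity_replicates: int = 100
    # design overrides (subset of SimulationDesign fields)
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in [
            ("yield_ratio", self.yield_ratio),
            ("severity bound", self.severity_bounds[0]),
            ("severity bound", self.severity_bounds[1]),
            ("timing_factor", self.timing_factor),
        ]:
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        if self.severity_bounds[0] >= self.severity_bounds[1]:
            raise ValueError("severity bounds must be increasing")
        if self.n_environments < 1:
            raise ValueError("n_environments must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "severity_bounds" in raw:
            raw["severity_bounds"] = tuple(raw["severity_bounds"])
        return cls(**raw)

    def simulation_design(self) -> SimulationDesign:
        return SimulationDesign(**self.design)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


def best_seasons_and_slices(cubes):
    """Clean panels and select the best rainfed season for every environment."""
    best, slices = {}, {}
    for env_id, cube in cubes.items():
        panels = clean_unsuitable_dates(panels_from_cube(cube))
        b = select_best_season(panels)
        best[env_id] = b
        slices[env_id] = best_season_slice(panels, b)
    return best, slices


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write all artifacts under ``config.outdir``.

    Idempotent: the same config and seed reproduce byte-identical tables.
    Returns the output directory.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.simulation_design()
    varieties = default_varieties()
    environments = make_archetype_grid(config.n_environments, seed=config.seed, design=design)

    cubes = simulate_grid(environments, varieties, design, seed=config.seed)
    tpio.write_gei_long(cubes, out / "gei_long.csv")
    tpio.write_environments_csv(environments, out / "environments.csv")
    tpio.write_environments_geojson(environments, out / "environments.geojson")

    best, slices = best_seasons_and_slices(cubes)
    tpio.write_best_seasons(best, out / "best_seasons.csv")

    classification = classify_grid(
        slices,
        ratio=config.yield_ratio,
        bounds=config.severity_bounds,
        factor=config.timing_factor,
    )
    coords = pd.DataFrame(
        {"env_id": [e.env_id for e in environments], "lon": [e.lon for e in environments], "lat": [e.lat for e in environments]}
    )
    tpio.write_classification(classification, coords, out / "classification.csv")
    tpio.classification_geojson(
        classification.merge(coords, on="env_id"), out / "classification.geojson"
    )
    class_proportions(classification).rename_axis("label").reset_index().to_csv(
        out / "class_proportions.csv", index=False
    )

    env_labels = dict(zip(classification["env_id"], classification["label"]))
    scopes = ["ALL", "S", "M", "L", "1", "2", "3", *ARCHETYPE_LABELS]
    indicators = indicator_table(slices, env_labels, scopes)
    tpio.write_indicators(indicators, out / "indicators.csv")

    ranks = adaptability_table(
        slices, env_labels, n_groups=config.n_rank_groups, method=config.linkage_method
    )
    tpio.write_ranks(ranks, out / "ranks.csv")

    if config.sensitivity_sizes:
        sens = genotype_count_sensitivity(
            cubes,
            config.sensitivity_sizes,
            n_replicates=config.sensitivity_replicates,
            seed=config.seed,
        )
        sens.to_csv(out / "genotype_sensitivity.csv", index=False)

    import ricetpe

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_environments": config.n_environments,
        "n_varieties": len(varieties),
        "thresholds": {
            "yield_ratio": config.yield_ratio,
            "severity_bounds": list(config.severity_bounds),
            "timing_factor": config.timing_factor,
        },
        "versions": {"ricetpe": getattr(ricetpe, "__version__", "unknown"), "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
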