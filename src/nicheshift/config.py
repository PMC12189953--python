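"""Run configuration.

Defaults follow the study design this pipeline reproduces: 5.5 km thinning
distance, |r| < 0.70 with top k = 6 variables, 5000 pseudoabsences × 3
replicates, 75/25 train/test with 5 + 1 folds, TSS gate 0.75, hotspot cutoff
0.80.  Scenario warming deltas approximate the end-of-century warming levels
of the three socioeconomic pathways (~1.8 / 2.7 / 4.4 °C) with roughly half
realized by mid-century.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .models import ALGORITHMS
from .synthetic import WorldConfig


def default_scenarios() -> dict[str, float]:
    return {
        "SSP1-2.6_2050": 0.9, "SSP1-2.6_2100": 1.8,
        "SSP2-4.5_2050": 1.35, "SSP2-4.5_2100": 2.7,
        "SSP5-8.5_2050": 2.2, "SSP5-8.5_2100": 4.4,
    }


def default_error_rates() -> dict[str, float]:
    return {"duplicate": 0.10, "zero_coord": 0.02, "land": 0.05,
            "low_precision": 0.05}


@dataclass
class RunConfig:
    """All knobs of one pipeline run; YAML round-trippable."""

    # synthetic world
    world: WorldConfig = field(default_factory=WorldConfig)
    n_occurrences: int = 500
    error_rates: dict[str, float] = field(default_factory=default_error_rates)
    mpa_fraction: float = 0.10
    n_eez: int = 5
    n_shipping_lanes: int = 6
    scenarios: dict[str, float] = field(default_factory=default_scenarios)
    # occurrence QC
    min_dist_km: float = 5.5
    precision_decimals: int = 2
    # variable selection
    r_max: float = 0.70
    k_variables: int = 6
    # SDM
    n_pseudoabsences: int = 5000
    n_pa_reps: int = 3
    train_fraction: float = 0.75
    n_folds: int = 5
    tss_min: float = 0.75
    algorithms: tuple[str, ...] = ALGORITHMS
    # hotspots
    hotspot_cutoff: float = 0.80
    # reproducibility
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "world" in raw:
            raw["world"] = WorldConfig(**raw["world"])
        if "algorithms" in raw:
            raw["algorithms"] = tuple(raw["algorithms"])
        return cls(**raw)
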