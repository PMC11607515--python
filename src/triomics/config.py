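"""Pipeline configuration: every tunable threshold in one place.

Defaults mirror the analysis conventions the pipeline encodes: the
species screen gate (raw p < 0.01 with fold change > 1.2 or < 0.83), the
reporter-score significance threshold |1.6|, the signed-network soft
power beta = 14 with deepSplit level 4, 9999 label permutations for
perMANOVA, the 5% KO prevalence gate, and the FDR < 0.1 band for
phenotype associations.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import yaml


@dataclass
class PipelineConfig:
    p_species: float = 0.01
    fc_high: float = 1.2
    fc_low: float = 0.83
    q_metabolite: float = 0.05
    p_setB: float = 0.05
    reporter_threshold: float = 1.6
    soft_power_beta: float = 14.0
    deep_split: int = 4
    n_permutations: int = 9999
    prevalence_min: float = 0.05
    fdr_phenotype: float = 0.1
    background_draws: int = 1000
    min_cluster_size: int = 5
    pseudocount: float | None = None  # None -> half the smallest non-zero value
    random_seed: int = 0
    tier_edges: tuple[float, float, float] = field(default=(0.001, 0.05, 0.1))

    def __post_init__(self) -> None:
        for name in ("p_species", "q_metabolite", "p_setB", "prevalence_min",
                     "fdr_phenotype"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not self.fc_low < 1 < self.fc_high:
            raise ValueError("need fc_low < 1 < fc_high")
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise ValueError("deep_split must be one of 0..4")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.background_draws < 100:
            raise ValueError("background_draws must be >= 100")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tier_edges"] = list(self.tier_edges)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "tier_edges" in raw:
            raw["tier_edges"] = tuple(raw["tier_edges"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
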