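"""Synthetic three-stage cohort with planted, recoverable ground truth.

Emulates the statistical structure of a disease-stage gut-microbiome /
serum-metabolome cohort (healthy controls, stable disease, infarction;
36/64/46 samples by default):

* **Species**: heavy-tailed log-normal relative abundances closed to 1,
  with a subset of species multiplied by a planted effect in the disease
  groups before closure.
* **KO functional profiles**: induced from species through a sparse
  binary species-carries-KO incidence matrix plus log-normal noise, so
  species-level effects propagate into KEGG-module-level reporter
  signal.  KOs of planted "enriched" modules are carried exclusively by
  planted differential species of the matching direction.
* **Metabolite features**: latent-factor model — feature = loading x
  cluster factor + Gaussian noise on the log scale, exponentiated to
  intensities; designated factors receive monotone group mean-shifts.
* **Phenotypes** (Gensini, Syntax, cTnI, TIMI): monotone functions of
  the stage index plus noise; magnitudes are arbitrary.

The three omics tables draw from independent child seeds of the design
seed, so regenerating one table never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables import AbundanceTable, CohortMetadata, ModuleMap, GROUP_ORDER


class DesignError(ValueError):
    pass


@dataclass
class SyntheticTruth:
    """Planted ground truth for downstream recovery checks."""

    differential_species: list[tuple[str, int, float]] = field(default_factory=list)
    enriched_modules: list[tuple[str, int]] = field(default_factory=list)
    metabotype_assignments: dict[str, int] = field(default_factory=dict)
    shifted_clusters: list[tuple[int, float]] = field(default_factory=list)
    phenotype_links: list[tuple[str, str, int]] = field(default_factory=list)


@dataclass
class CohortDesign:
    """Knobs of the generator; defaults are the reference study conditions."""

    group_sizes: tuple[int, int, int] = (36, 64, 46)
    n_species: int = 150
    n_kos: int = 600
    n_modules: int = 30
    module_size_range: tuple[int, int] = (8, 16)
    n_metabolites: int = 200
    n_latent_clusters: int = 5
    n_diff_species: int = 12
    species_effect: float = 3.0  # multiplicative, disease groups vs HC
    n_enriched_modules: int = 5
    species_log_mean_sd: float = 1.5
    species_log_sd: float = 1.0
    carriers_per_ko: int = 3
    ko_noise_sd: float = 0.3
    metabolite_loading: float = 0.8
    metabolite_noise_sd: float = 0.6
    cluster_shift: float = 0.8  # latent-factor mean shift per stage step
    phenotype_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.group_sizes) or sum(self.group_sizes) < 10:
            raise DesignError("group sizes must be positive and sum to >= 10")
        if self.species_effect <= 0:
            raise DesignError("species_effect must be a positive multiplier")
        if self.n_diff_species > self.n_species:
            raise DesignError("more planted species than species")
        if self.n_enriched_modules > self.n_modules:
            raise DesignError("more planted modules than modules")
        for n in (self.n_species, self.n_kos, self.n_modules, self.n_metabolites,
                  self.n_latent_clusters):
            if n <= 0:
                raise DesignError("all counts must be positive")


def _sample_ids(design: CohortDesign) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(sum(design.group_sizes))]


def _group_labels(design: CohortDesign) -> np.ndarray:
    return np.repeat(list(GROUP_ORDER), design.group_sizes)


def generate_cohort(
    design: CohortDesign,
) -> tuple[AbundanceTable, AbundanceTable, AbundanceTable, CohortMetadata, ModuleMap, SyntheticTruth]:
    """Generate (species, ko, metabolite) tables, metadata, module map, truth."""
    ss = np.random.SeedSequence(design.seed)
    rng_struct, rng_species, rng_ko, rng_met, rng_pheno = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    samples = _sample_ids(design)
    labels = _group_labels(design)
    disease = labels != GROUP_ORDER[0]
    stage = np.concatenate(
        [np.full(n, i) for i, n in enumerate(design.group_sizes)]
    ).astype(float)
    n_samp = len(samples)
    truth = SyntheticTruth()

    # --- structural choices (shared across tables) --------------------------
    species_ids = [f"sp{i + 1:03d}" for i in range(design.n_species)]
    ko_ids = [f"K{i + 1:05d}" for i in range(design.n_kos)]
    planted_idx = rng_struct.choice(
        design.n_species, size=design.n_diff_species, replace=False
    )
    directions = np.where(np.arange(design.n_diff_species) % 2 == 0, 1, -1)
    for i, d in zip(planted_idx, directions):
        truth.differential_species.append(
            (species_ids[i], int(d), float(design.species_effect))
        )

    # module plan: planted modules alternate direction (up-biased)
    module_ids = [f"M{i + 1:04d}" for i in range(design.n_modules)]
    planted_modules = list(range(design.n_enriched_modules))
    module_dirs = {m: (1 if j % 2 == 0 else -1) for j, m in enumerate(planted_modules)}
    sizes = rng_struct.integers(
        design.module_size_range[0], design.module_size_range[1] + 1,
        size=design.n_modules,
    )
    if sizes.sum() > design.n_kos:
        raise DesignError("not enough KOs for the requested modules")
    ko_pool = rng_struct.permutation(design.n_kos)
    entries = []
    module_kos: dict[int, np.ndarray] = {}
    cursor = 0
    for m, size in enumerate(sizes):
        kos = ko_pool[cursor : cursor + size]
        cursor += size
        module_kos[m] = kos
        entries.extend((ko_ids[k], module_ids[m]) for k in kos)
    module_map = ModuleMap(pd.DataFrame(entries, columns=["ko_id", "module_id"]))
    for m in planted_modules:
        truth.enriched_modules.append((module_ids[m], module_dirs[m]))

    # incidence: which species carry which KO
    up_species = planted_idx[directions == 1]
    down_species = planted_idx[directions == -1]
    background_species = np.setdiff1d(np.arange(design.n_species), planted_idx)
    incidence = np.zeros((design.n_species, design.n_kos))
    planted_ko_set = set()
    for m in planted_modules:
        pool = up_species if module_dirs[m] == 1 else down_species
        for k in module_kos[m]:
            carriers = rng_struct.choice(
                pool, size=min(design.carriers_per_ko, len(pool)), replace=False
            )
            incidence[carriers, k] = 1.0
            planted_ko_set.add(int(k))
    for k in range(design.n_kos):
        if k in planted_ko_set:
            continue
        carriers = rng_struct.choice(
            background_species, size=design.carriers_per_ko, replace=False
        )
        incidence[carriers, k] = 1.0

    # --- species table -------------------------------------------------------
    log_mean = rng_species.normal(0.0, design.species_log_mean_sd, design.n_species)
    logs = log_mean[:, None] + rng_species.normal(
        0.0, design.species_log_sd, (design.n_species, n_samp)
    )
    absolute = np.exp(logs)
    for i, d in zip(planted_idx, directions):
        factor = design.species_effect if d == 1 else 1.0 / design.species_effect
        absolute[i, disease] *= factor
    rel = absolute / absolute.sum(axis=0, keepdims=True)
    species = AbundanceTable(
        pd.DataFrame(rel, index=species_ids, columns=samples), "species"
    )

    # --- KO table ------------------------------------------------------------
    ko_vals = incidence.T @ absolute  # kos x samples
    ko_vals *= np.exp(rng_ko.normal(0.0, design.ko_noise_sd, ko_vals.shape))
    ko = AbundanceTable(pd.DataFrame(ko_vals, index=ko_ids, columns=samples), "ko")

    # --- metabolite table ----------------------------------------------------
    met_ids = [f"met{i + 1:04d}" for i in range(design.n_metabolites)]
    clusters = np.arange(design.n_metabolites) % design.n_latent_clusters
    shifts = np.array(
        [design.cluster_shift * (1 if c % 2 == 0 else -1)
         for c in range(design.n_latent_clusters)]
    )
    factors = rng_met.normal(0.0, 1.0, (design.n_latent_clusters, n_samp))
    factors += shifts[:, None] * stage[None, :]
    noise = rng_met.normal(
        0.0, design.metabolite_noise_sd, (design.n_metabolites, n_samp)
    )
    latent = design.metabolite_loading * factors[clusters, :] + noise
    met = AbundanceTable(
        pd.DataFrame(np.exp(latent), index=met_ids, columns=samples), "metabolite"
    )
    truth.metabotype_assignments = {f: int(c) + 1 for f, c in zip(met_ids, clusters)}
    if design.cluster_shift != 0:
        truth.shifted_clusters = [
            (c + 1, float(shifts[c])) for c in range(design.n_latent_clusters)
        ]

    # --- metadata ------------------------------------------------------------
    pheno = {
        "Gensini": 8.0 + 30.0 * stage,
        "Syntax": 4.0 + 12.0 * stage,
        "cTnI": 0.05 + 1.5 * stage,
        "TIMI": 1.0 + 1.0 * stage,
    }
    frame = pd.DataFrame({"group": labels}, index=pd.Index(samples, name="sample_id"))
    for name, base in pheno.items():
        vals = base * np.exp(
            rng_pheno.normal(0.0, design.phenotype_noise_sd, n_samp)
        )
        frame[name] = vals
        if design.cluster_shift != 0 or design.species_effect != 1.0:
            truth.phenotype_links.append((name, "group", 1))
    meta = CohortMetadata(frame)
    return species, ko, met, meta, module_map, truth


def null_design(design: CohortDesign) -> CohortDesign:
    """Copy of a design with every planted effect removed."""
    return replace(
        design,
        species_effect=1.0,
        n_diff_species=0,
        n_enriched_modules=0,
        cluster_shift=0.0,
    )


def generate_null_cohort(design: CohortDesign):
    """As :func:`generate_cohort` with all effects zeroed; truth is empty."""
    out = generate_cohort(null_design(design))
    truth = out[-1]
    truth.differential_species = []
    truth.enriched_modules = []
    truth.shifted_clusters = []
    truth.phenotype_links = []
    return out
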