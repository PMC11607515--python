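"""End-to-end orchestration: generate-or-load, filter, diversity, screen,
reporter, metabotype, integrate, baseline — with a JSON run manifest.

Every stage writes plain TSV outputs; the manifest records the config
echo, seed, input digests and per-stage output paths, so two runs with
the same seed and inputs are value-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import VariableSpec, baseline_table
from .config import PipelineConfig
from .diversity import alpha_diversity, bray_curtis, dbrda, pcoa, permanova
from .integrate import module_metabotype_grid, phenotype_association
from .metabotype import metabotype_chain, selected_features
from .reporter import (
    ko_differential,
    module_sample_scores,
    reporter_frame,
    reporter_score,
)
from .screen import records_frame, screen_species
from .synthetic import CohortDesign, generate_cohort
from .tables import (
    AbundanceTable,
    CohortMetadata,
    ModuleMap,
    align_samples,
    filter_prevalence,
    read_abundance_table,
    read_metadata,
    read_module_map,
    to_relative,
    write_abundance_table,
    write_metadata,
    write_module_map,
)

logger = logging.getLogger("triomics")

ALL_STAGES = (
    "diversity", "screen", "reporter", "metabotype", "integrate", "baseline",
)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def load_inputs(input_dir: Path):
    input_dir = Path(input_dir)
    species = read_abundance_table(input_dir / "species.tsv", "species")
    ko = read_abundance_table(input_dir / "ko.tsv", "ko")
    met = read_abundance_table(input_dir / "metabolites.tsv", "metabolite")
    meta = read_metadata(input_dir / "metadata.tsv")
    module_map = read_module_map(input_dir / "module_map.tsv")
    return species, ko, met, meta, module_map


def write_cohort(out_dir: Path, species, ko, met, meta, module_map) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_abundance_table(species, out_dir / "species.tsv")
    write_abundance_table(ko, out_dir / "ko.tsv")
    write_abundance_table(met, out_dir / "metabolites.tsv")
    write_metadata(meta, out_dir / "metadata.tsv")
    write_module_map(module_map, out_dir / "module_map.tsv")


def run_pipeline(
    output_dir,
    input_dir=None,
    synthetic: bool = False,
    config: PipelineConfig | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
    comparison: tuple[str, str] = ("HC", "CAD"),
    design: CohortDesign | None = None,
) -> dict:
    """Execute the pipeline and return the run manifest (also written to
    ``output_dir/manifest.json``)."""
    config = config or PipelineConfig()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("seed=%d config=%s", config.random_seed, config.to_dict())

    manifest: dict = {
        "version": __version__,
        "seed": config.random_seed,
        "config": config.to_dict(),
        "stages": {},
        "inputs": {},
    }

    if synthetic:
        design = design or CohortDesign(seed=config.random_seed)
        design = replace(design, seed=config.random_seed)
        species, ko, met, meta, module_map, truth = generate_cohort(design)
        write_cohort(out / "inputs", species, ko, met, meta, module_map)
        with open(out / "inputs" / "truth.json", "w") as fh:
            json.dump(
                {
                    "differential_species": truth.differential_species,
                    "enriched_modules": truth.enriched_modules,
                    "shifted_clusters": truth.shifted_clusters,
                },
                fh, indent=1,
            )
        manifest["inputs"]["synthetic_design"] = str(design)
    else:
        if input_dir is None:
            raise ValueError("need input_dir or synthetic=True")
        species, ko, met, meta, module_map = load_inputs(input_dir)
        for f in sorted(Path(input_dir).glob("*.tsv")):
            manifest["inputs"][f.name] = _digest(f)

    species, meta_s = align_samples(species, meta)
    ko, _ = align_samples(ko, meta)
    met, _ = align_samples(met, meta)
    meta = meta_s
    species_rel = to_relative(species)

    if "diversity" in stages:
        adiv = alpha_diversity(species_rel)
        adiv.to_csv(out / "alpha_diversity.tsv", sep="\t")
        dist = bray_curtis(species_rel)
        dist.to_frame().to_csv(out / "bray_curtis.tsv", sep="\t")
        perma = permanova(
            dist, meta.group, n_perm=config.n_permutations, seed=config.random_seed
        )
        ord_res = pcoa(dist)
        ord_res.scores_frame().to_csv(out / "pcoa_scores.tsv", sep="\t")
        db = dbrda(dist, meta.group)
        db.scores_frame().to_csv(out / "dbrda_scores.tsv", sep="\t")
        with open(out / "diversity_summary.json", "w") as fh:
            json.dump(
                {
                    "permanova_F": perma.statistic,
                    "permanova_p": perma.p_value,
                    "pcoa_prop_explained": ord_res.proportion_explained[:5].tolist(),
                    "dbrda_constrained_proportion": db.constrained_proportion,
                },
                fh, indent=1,
            )
        manifest["stages"]["diversity"] = str(out / "diversity_summary.json")

    screen_records = None
    if "screen" in stages:
        screen_records = screen_species(species_rel, meta, comparison, config)
        frame = records_frame(screen_records)
        frame.to_csv(out / "differential_species.tsv", sep="\t")
        manifest["stages"]["screen"] = str(out / "differential_species.tsv")

    reporter_results = None
    ko_filtered = None
    if "reporter" in stages:
        ko_filtered = filter_prevalence(ko, config.prevalence_min)
        kos = ko_differential(ko_filtered, meta, comparison, config)
        reporter_results = reporter_score(kos, module_map, config)
        reporter_frame(reporter_results).to_csv(out / "reporter_scores.tsv", sep="\t")
        manifest["stages"]["reporter"] = str(out / "reporter_scores.tsv")

    assignment = None
    if "metabotype" in stages:
        results, assignment = metabotype_chain(met, meta, config)
        pd.DataFrame(
            {
                "feature_id": [r.feature_id for r in results],
                "setA_pass": [r.setA_pass for r in results],
                "setB_pass": [r.setB_pass for r in results],
                "selected": [r.selected for r in results],
            }
        ).set_index("feature_id").to_csv(out / "metabolite_selection.tsv", sep="\t")
        assignment.labels.rename("cluster").to_csv(
            out / "metabotype_assignment.tsv", sep="\t"
        )
        assignment.eigen_features.to_csv(out / "metabotype_eigens.tsv", sep="\t")
        manifest["stages"]["metabotype"] = str(out / "metabotype_assignment.tsv")
        manifest["n_selected_metabolites"] = len(selected_features(results))
        manifest["n_metabotypes"] = len(assignment.cluster_ids)

    if "integrate" in stages:
        if reporter_results is None or assignment is None or ko_filtered is None:
            logger.warning("integrate needs reporter + metabotype stages; skipped")
        elif not assignment.cluster_ids:
            logger.warning("no metabotype clusters formed; integrate skipped")
        else:
            mod_scores = module_sample_scores(ko_filtered, module_map)
            grid = module_metabotype_grid(mod_scores, assignment.eigen_features, config)
            grid.rho.to_csv(out / "grid_rho.tsv", sep="\t")
            grid.q.to_csv(out / "grid_q.tsv", sep="\t")
            grid.tier.to_csv(out / "grid_tier.tsv", sep="\t")
            grid.to_long().to_csv(out / "grid_long.tsv", sep="\t", index=False)
            pheno_rows = []
            for ph in meta.phenotype_names:
                for unit, scores in (
                    ("module", mod_scores),
                    ("metabotype", assignment.eigen_features),
                ):
                    for cell in phenotype_association(scores, meta, ph, config):
                        pheno_rows.append(
                            {
                                "unit": unit, "row_id": cell.row_id,
                                "phenotype": ph, "rho": cell.rho,
                                "p_value": cell.p_value, "q_value": cell.q_value,
                                "tier": cell.tier,
                            }
                        )
            pd.DataFrame(pheno_rows).to_csv(
                out / "phenotype_associations.tsv", sep="\t", index=False
            )
            manifest["stages"]["integrate"] = str(out / "grid_long.tsv")

    if "baseline" in stages:
        specs = [VariableSpec(name) for name in meta.phenotype_names]
        table = baseline_table(meta, specs)
        table.to_csv(out / "baseline_table.tsv", sep="\t")
        table.to_markdown(out / "baseline_table.md")
        manifest["stages"]["baseline"] = str(out / "baseline_table.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
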