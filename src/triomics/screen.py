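"""Two-group differential-abundance screen with fold-change gates, and
Spearman association of selected species with disease-severity scores.

The screen gates on the raw Wilcoxon p-value (p < 0.01 by default) AND a
fold-change outside (0.83, 1.2); BH q-values are attached for reporting
but do not enter the gate.  Fold changes are case-group over reference
with a shared pseudocount (half the smallest non-zero value by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import PipelineConfig
from .stats import bh_adjust, fold_change, wilcoxon_rank_sum
from .tables import AbundanceTable, CohortMetadata, to_relative


@dataclass
class DifferentialRecord:
    feature_id: str
    comparison: tuple[str, str]  # (reference, case)
    p_value: float
    q_value: float
    fold_change: float
    enriched_in: str | None
    passes: bool


def default_pseudocount(table: AbundanceTable) -> float:
    nz = table.values[table.values > 0]
    if len(nz) == 0:
        raise ValueError("table has no positive values")
    return float(nz.min() / 2.0)


def screen_species(
    table: AbundanceTable,
    meta: CohortMetadata,
    comparison: tuple[str, str] = ("HC", "CAD"),
    config: PipelineConfig | None = None,
) -> list[DifferentialRecord]:
    """One record per feature for a reference-vs-case contrast.

    ``passes`` iff raw p < ``p_species`` and fold change > ``fc_high`` or
    < ``fc_low`` (strict, unrounded).
    """
    config = config or PipelineConfig()
    ref_label, case_label = comparison
    ref_ids = meta.samples_in_group(ref_label)
    case_ids = meta.samples_in_group(case_label)
    if len(ref_ids) < 3 or len(case_ids) < 3:
        raise ValueError("both comparison groups need >= 3 samples")
    table = to_relative(table)  # screen is defined on relative abundances
    pc = config.pseudocount
    if pc is None:
        pc = default_pseudocount(table)
    ref = table.data[ref_ids].to_numpy()
    case = table.data[case_ids].to_numpy()
    p_values = np.empty(table.n_features)
    fcs = np.empty(table.n_features)
    dirs = np.empty(table.n_features, dtype=int)
    for i in range(table.n_features):
        res = wilcoxon_rank_sum(ref[i], case[i])
        p_values[i] = res.p_value
        dirs[i] = res.direction
        fcs[i] = fold_change(ref[i], case[i], pseudocount=pc)
    q_values = bh_adjust(p_values)
    records = []
    for i, fid in enumerate(table.feature_ids):
        gate = fcs[i] > config.fc_high or fcs[i] < config.fc_low
        passes = bool(p_values[i] < config.p_species and gate)
        enriched = None
        if passes:
            enriched = case_label if fcs[i] > 1 else ref_label
        records.append(
            DifferentialRecord(
                fid, comparison, float(p_values[i]), float(q_values[i]),
                float(fcs[i]), enriched, passes,
            )
        )
    return records


def records_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "reference": [r.comparison[0] for r in records],
            "case": [r.comparison[1] for r in records],
            "p_value": [r.p_value for r in records],
            "q_value": [r.q_value for r in records],
            "fold_change": [r.fold_change for r in records],
            "enriched_in": [r.enriched_in for r in records],
            "passes": [r.passes for r in records],
        }
    ).set_index("feature_id")


def species_phenotype_correlation(
    table: AbundanceTable,
    meta: CohortMetadata,
    features: list[str],
    phenotypes: list[str],
    min_pairs: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman rho/p/q matrices (features x phenotypes).

    Missing phenotype values are excluded pairwise; cells with fewer
    than ``min_pairs`` complete pairs are left NaN and excluded from the
    BH family.
    """
    sub = table.subset_features(features)
    rho = pd.DataFrame(np.nan, index=features, columns=phenotypes)
    pval = pd.DataFrame(np.nan, index=features, columns=phenotypes)
    for ph in phenotypes:
        y = meta.phenotype(ph).reindex(sub.sample_ids).to_numpy(dtype=float)
        ok = np.isfinite(y)
        for fid in features:
            x = sub.data.loc[fid].to_numpy()[ok]
            if len(x) < min_pairs:
                continue
            r, p = spearmanr(x, y[ok])
            rho.loc[fid, ph] = r
            pval.loc[fid, ph] = p
    flat = pval.to_numpy().ravel()
    mask = np.isfinite(flat)
    qflat = np.full_like(flat, np.nan)
    if mask.any():
        qflat[mask] = bh_adjust(flat[mask])
    qval = pd.DataFrame(
        qflat.reshape(pval.shape), index=features, columns=phenotypes
    )
    return rho, pval, qval
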