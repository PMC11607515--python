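"""Three-way association map: modules x metabotypes x clinical phenotypes.

Two-group phenotype contrasts use the Mann-Whitney test; continuous
phenotypes and the module-by-metabotype grid use Spearman correlation.
Each grid forms a single Benjamini-Hochberg family, and every cell is
annotated with a significance tier: strong (q < 0.001), moderate
(0.001 <= q < 0.05), weak (0.05 <= q < 0.1), ns otherwise.  Tier
boundaries are half-open so each cell has exactly one tier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import PipelineConfig
from .stats import bh_adjust, wilcoxon_rank_sum
from .tables import CohortMetadata

TIERS = ("strong", "moderate", "weak", "ns")


def assign_tier(q: float, edges: tuple[float, float, float] = (0.001, 0.05, 0.1)) -> str:
    if not np.isfinite(q):
        return "ns"
    if q < edges[0]:
        return "strong"
    if q < edges[1]:
        return "moderate"
    if q < edges[2]:
        return "weak"
    return "ns"


@dataclass
class AssociationCell:
    row_id: str
    col_id: str
    rho: float  # Spearman rho, or +/-1 direction for two-group contrasts
    p_value: float
    q_value: float
    tier: str


def phenotype_association(
    features: pd.DataFrame,  # rows: feature/module/metabotype; cols: samples
    meta: CohortMetadata,
    phenotype: str | tuple[str, str],
    config: PipelineConfig | None = None,
) -> list[AssociationCell]:
    """Associate per-sample score vectors with one phenotype.

    ``phenotype`` is either a metadata column name (continuous ->
    Spearman) or a pair of group labels (two-group contrast ->
    Mann-Whitney, rho column carries the direction sign).
    """
    config = config or PipelineConfig()
    cells: list[tuple[str, float, float]] = []
    if isinstance(phenotype, tuple):
        ref_ids = meta.samples_in_group(phenotype[0])
        case_ids = meta.samples_in_group(phenotype[1])
        col_name = f"{phenotype[0]}_vs_{phenotype[1]}"
        for rid, row in features.iterrows():
            x = row.reindex(ref_ids).to_numpy(dtype=float)
            y = row.reindex(case_ids).to_numpy(dtype=float)
            res = wilcoxon_rank_sum(x, y)
            cells.append((rid, float(res.direction), res.p_value))
    else:
        col_name = phenotype
        y_all = meta.phenotype(phenotype)
        for rid, row in features.iterrows():
            y = y_all.reindex(row.index).to_numpy(dtype=float)
            ok = np.isfinite(y) & np.isfinite(row.to_numpy(dtype=float))
            if ok.sum() < 4 or np.ptp(row.to_numpy(dtype=float)[ok]) == 0:
                cells.append((rid, 0.0, 1.0))
                continue
            r, p = spearmanr(row.to_numpy(dtype=float)[ok], y[ok])
            cells.append((rid, float(r), float(p)))
    q = bh_adjust([c[2] for c in cells])
    return [
        AssociationCell(rid, col_name, rho, p, float(qi),
                        assign_tier(float(qi), config.tier_edges))
        for (rid, rho, p), qi in zip(cells, q)
    ]


@dataclass
class AssociationGrid:
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    tier: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        recs = []
        for r in self.rho.index:
            for c in self.rho.columns:
                recs.append(
                    {
                        "row_id": r,
                        "col_id": c,
                        "rho": self.rho.loc[r, c],
                        "p_value": self.p.loc[r, c],
                        "q_value": self.q.loc[r, c],
                        "tier": self.tier.loc[r, c],
                    }
                )
        return pd.DataFrame(recs)


def module_metabotype_grid(
    module_scores: pd.DataFrame,  # modules x samples
    metabotype_eigens: pd.DataFrame,  # metabotypes x samples
    config: PipelineConfig | None = None,
) -> AssociationGrid:
    """Full Spearman grid with a single BH family and tier annotation."""
    import logging

    config = config or PipelineConfig()
    if module_scores.shape[0] == 0 or metabotype_eigens.shape[0] == 0:
        raise ValueError("association grid needs at least one row on each side")
    shared = [s for s in module_scores.columns if s in set(metabotype_eigens.columns)]
    if len(shared) < 8:
        logging.getLogger("triomics").warning(
            "only %d shared samples; grid power is low", len(shared)
        )
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    a = module_scores[shared].to_numpy(dtype=float)
    b = metabotype_eigens[shared].to_numpy(dtype=float)
    n_r, n_c = a.shape[0], b.shape[0]
    rho = np.empty((n_r, n_c))
    p = np.empty((n_r, n_c))
    for i in range(n_r):
        for j in range(n_c):
            if np.ptp(a[i]) == 0 or np.ptp(b[j]) == 0:
                rho[i, j], p[i, j] = 0.0, 1.0
            else:
                rho[i, j], p[i, j] = spearmanr(a[i], b[j])
    q = bh_adjust(p.ravel()).reshape(p.shape)
    tier = np.vectorize(lambda v: assign_tier(v, config.tier_edges))(q)
    idx, cols = module_scores.index, metabotype_eigens.index
    return AssociationGrid(
        pd.DataFrame(rho, index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
        pd.DataFrame(q, index=idx, columns=cols),
        pd.DataFrame(tier, index=idx, columns=cols),
    )
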