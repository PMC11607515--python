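"""KEGG-module reporter scores from per-KO two-group tests.

Each prevalent KO is tested between the two contrast groups with the
Wilcoxon rank-sum test; the two-sided p-value is mapped to a signed
z-score, z = Phi^-1(1 - p/2) * direction.  A module of k tested KOs
aggregates to raw_z = sum(z) / sqrt(k), which is then corrected against
a size-matched random background: reporter = (raw_z - mu_k) / sigma_k
with mu_k, sigma_k the mean and sd of raw_z over ``background_draws``
random k-subsets of all tested KOs (seeded, hence bit-reproducible).
|reporter| > 1.6 marks a module as significantly shifted (about 95%
one-tail normal confidence); the sign gives the direction of change.

Aggregation uses raw p-values; BH q-values are carried for reporting
only, since aggregating adjusted p-values would penalize twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import PipelineConfig
from .stats import bh_adjust, wilcoxon_rank_sum
from .tables import AbundanceTable, CohortMetadata, ModuleMap

# two-sided p floored here before the inverse-normal map, so z stays finite
_P_FLOOR = 1e-300


@dataclass
class KODifferential:
    ko_id: str
    p_value: float
    q_value: float
    direction: int


@dataclass
class ReporterResult:
    module_id: str
    n_kos: int
    raw_z: float
    reporter_score: float
    significant: bool
    direction: int


def ko_differential(
    ko_table: AbundanceTable,
    meta: CohortMetadata,
    comparison: tuple[str, str] = ("HC", "CAD"),
    config: PipelineConfig | None = None,
) -> list[KODifferential]:
    """Per-KO Wilcoxon p, BH q and direction for a two-group contrast.

    The table is expected to be prevalence-filtered upstream.
    """
    config = config or PipelineConfig()
    ref_ids = meta.samples_in_group(comparison[0])
    case_ids = meta.samples_in_group(comparison[1])
    if not ref_ids or not case_ids:
        raise ValueError(f"comparison group missing samples: {comparison}")
    ref = ko_table.data[ref_ids].to_numpy()
    case = ko_table.data[case_ids].to_numpy()
    p = np.empty(ko_table.n_features)
    d = np.empty(ko_table.n_features, dtype=int)
    for i in range(ko_table.n_features):
        res = wilcoxon_rank_sum(ref[i], case[i])
        p[i], d[i] = res.p_value, res.direction
    q = bh_adjust(p)
    return [
        KODifferential(ko, float(pi), float(qi), int(di))
        for ko, pi, qi, di in zip(ko_table.feature_ids, p, q, d)
    ]


def _signed_z(kos: list[KODifferential]) -> pd.Series:
    p = np.array([max(k.p_value, _P_FLOOR) for k in kos])
    d = np.array([k.direction for k in kos], dtype=float)
    z = norm.isf(p / 2.0) * d
    return pd.Series(z, index=[k.ko_id for k in kos])


def reporter_score(
    kos: list[KODifferential],
    module_map: ModuleMap,
    config: PipelineConfig | None = None,
) -> list[ReporterResult]:
    """Background-corrected reporter score per KEGG module.

    Modules with no tested KO are dropped with a warning; results are
    independent of module order and of KO order within modules.
    """
    import logging

    config = config or PipelineConfig()
    logger = logging.getLogger("triomics")
    z = _signed_z(kos).sort_index()  # background independent of input order
    tested = set(z.index)
    rng = np.random.default_rng(config.random_seed)
    z_arr = z.to_numpy()
    # background raw_z moments per module size, shared across equal-size modules
    cache: dict[int, tuple[float, float]] = {}

    def background(k: int) -> tuple[float, float]:
        if k not in cache:
            # each draw is a size-k KO set without replacement
            draws = np.argsort(
                rng.random((config.background_draws, len(z_arr))), axis=1
            )[:, :k]
            raw = z_arr[draws].sum(axis=1) / np.sqrt(k)
            cache[k] = (float(raw.mean()), float(raw.std(ddof=1)))
        return cache[k]

    z_map = dict(zip(z.index, z_arr))
    module_members = module_map.as_dict()
    results = []
    for mid in sorted(module_members):
        members = [k for k in module_members[mid] if k in tested]
        if not members:
            logger.warning("module %s has no tested KOs; dropped", mid)
            continue
        k = len(members)
        raw = float(sum(z_map[m] for m in members) / np.sqrt(k))
        mu, sd = background(k)
        score = (raw - mu) / sd if sd > 0 else 0.0
        results.append(
            ReporterResult(
                mid, k, raw, float(score),
                bool(abs(score) > config.reporter_threshold),
                int(np.sign(score)),
            )
        )
    return results


def reporter_frame(results: list[ReporterResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "module_id": [r.module_id for r in results],
            "n_kos": [r.n_kos for r in results],
            "raw_z": [r.raw_z for r in results],
            "reporter_score": [r.reporter_score for r in results],
            "direction": [r.direction for r in results],
            "significant": [r.significant for r in results],
        }
    ).set_index("module_id")


def module_sample_scores(
    ko_table: AbundanceTable, module_map: ModuleMap, relative: bool = True
) -> pd.DataFrame:
    """Per-sample module activity: summed (relative) abundance of the
    module's KOs.  Sample-level counterpart of the group-level reporter
    score, used for phenotype and metabotype correlation."""
    data = ko_table.data
    if relative:
        sums = data.sum(axis=0)
        sums = sums.replace(0, np.nan)
        data = data.div(sums, axis=1).fillna(0.0)
    rows = {}
    present = set(ko_table.feature_ids)
    module_members = module_map.as_dict()
    for mid in sorted(module_members):
        members = [k for k in module_members[mid] if k in present]
        if members:
            rows[mid] = data.loc[members].sum(axis=0)
    return pd.DataFrame(rows).T  # modules x samples
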