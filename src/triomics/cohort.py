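"""Baseline-characteristics table with automatic test selection.

Continuous, normally distributed variables are summarized as mean +/- SD
and compared by one-way ANOVA; skewed continuous variables as median
(IQR) with Kruskal-Wallis; categorical variables as n (%) with the
Pearson chi-squared test (Fisher's exact for 2x2 tables with any
expected count below 5).  When a variable's type is unspecified the
normality gate is a Shapiro-Wilk test at alpha = 0.05 within each group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import (
    TestResult,
    chi_square_contingency,
    fisher_exact_2x2,
    kruskal_wallis,
    t_test_welch,
    wilcoxon_rank_sum,
)
from .tables import CohortMetadata

VARIABLE_TYPES = ("continuous_normal", "continuous_skewed", "categorical")


@dataclass
class VariableSpec:
    name: str
    type: str | None = None  # None -> auto via Shapiro-Wilk gate

    def __post_init__(self) -> None:
        if self.type is not None and self.type not in VARIABLE_TYPES:
            raise ValueError(f"unknown variable type {self.type!r}")


def _infer_type(values: pd.Series, groups: pd.Series) -> str:
    if values.dtype == object or str(values.dtype) == "category":
        return "categorical"
    clean = values.dropna()
    if clean.nunique() <= 3:
        return "categorical"
    for g in groups.unique():
        sub = values[groups == g].dropna()
        if len(sub) >= 3 and np.ptp(sub) > 0:
            if _sps.shapiro(sub).pvalue < 0.05:
                return "continuous_skewed"
    return "continuous_normal"


def _anova(groups_vals: list[np.ndarray]) -> TestResult:
    if np.ptp(np.concatenate(groups_vals)) == 0:
        return TestResult(0.0, 1.0, 0, "anova")
    f, p = _sps.f_oneway(*groups_vals)
    if not np.isfinite(f):
        return TestResult(0.0, 1.0, 0, "anova")
    return TestResult(float(f), float(p), 0, "anova")


def _categorical_test(values: pd.Series, groups: pd.Series) -> TestResult:
    tab = pd.crosstab(values, groups)
    counts = tab.to_numpy()
    if counts.shape == (2, 2):
        row = counts.sum(axis=1, keepdims=True)
        col = counts.sum(axis=0, keepdims=True)
        expected = row @ col / counts.sum()
        if (expected < 5).any():
            return fisher_exact_2x2(counts)
    return chi_square_contingency(counts)


def baseline_table(
    meta: CohortMetadata, specs: list[VariableSpec]
) -> pd.DataFrame:
    """Group-wise summaries plus one p-value per variable."""
    groups = meta.group
    labels = [g for g in meta.group_order if (groups == g).any()]
    if len(labels) < 2:
        raise ValueError("baseline table needs >= 2 groups")
    rows = []
    for spec in specs:
        if spec.name not in meta.frame.columns:
            raise KeyError(f"variable {spec.name!r} not in metadata")
        values = meta.frame[spec.name]
        vtype = spec.type or _infer_type(values, groups)
        summaries = {}
        if vtype == "categorical":
            # n (%) of the lexicographically last level (yes/male convention)
            levels = sorted(values.dropna().unique().astype(str))
            pos = levels[-1] if levels else ""
            for g in labels:
                sub = values[groups == g].dropna().astype(str)
                n_pos = int((sub == pos).sum())
                summaries[g] = f"{n_pos} ({100 * n_pos / max(len(sub), 1):.1f}%)"
            result = _categorical_test(values.dropna(), groups[values.notna()])
        else:
            vals = [values[groups == g].dropna().to_numpy(dtype=float) for g in labels]
            if vtype == "continuous_normal":
                for g, v in zip(labels, vals):
                    summaries[g] = f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"
                if np.ptp(np.concatenate(vals)) == 0:
                    result = TestResult(0.0, 1.0, 0, "anova")
                else:
                    result = _anova(vals)
            else:
                for g, v in zip(labels, vals):
                    q1, q2, q3 = np.percentile(v, [25, 50, 75])
                    summaries[g] = f"{q2:.2f} ({q1:.2f}, {q3:.2f})"
                result = kruskal_wallis(vals)
        row = {"variable": spec.name, "type": vtype, **summaries,
               "p_value": round(result.p_value, 3), "method": result.method}
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def pairwise_contrasts(
    meta: CohortMetadata,
    variable: VariableSpec,
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pair two-group tests with footnote-style significance flags."""
    groups = meta.group
    if variable.name not in meta.frame.columns:
        raise KeyError(f"variable {variable.name!r} not in metadata")
    values = meta.frame[variable.name]
    vtype = variable.type or _infer_type(values, groups)
    if pairs is None:
        labs = list(meta.group_order)
        pairs = [(labs[i], labs[j]) for i in range(len(labs))
                 for j in range(i + 1, len(labs))]
    flags = "abcdefgh"
    rows = []
    for k, (g1, g2) in enumerate(pairs):
        x = values[groups == g1].dropna().to_numpy(dtype=float)
        y = values[groups == g2].dropna().to_numpy(dtype=float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"empty group in pair ({g1}, {g2})")
        if vtype == "continuous_normal":
            res = t_test_welch(x, y)
        else:
            res = wilcoxon_rank_sum(x, y)
        rows.append(
            {
                "pair": f"{g1}_vs_{g2}",
                "statistic": res.statistic,
                "p_value": res.p_value,
                "direction": res.direction,
                "flag": flags[k] if res.p_value < alpha else "",
            }
        )
    return pd.DataFrame(rows).set_index("pair")
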