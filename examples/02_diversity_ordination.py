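"""Alpha diversity, Bray-Curtis perMANOVA and dbRDA on a synthetic cohort.

Generates the default three-stage cohort with planted differential
species, then quantifies community-level separation between disease
stages.
"""

import numpy as np

from triomics import (
    CohortDesign,
    alpha_diversity,
    bray_curtis,
    dbrda,
    generate_cohort,
    permanova,
    to_relative,
)

species, _, _, meta, _, truth = generate_cohort(CohortDesign(seed=1))
rel = to_relative(species)

adiv = alpha_diversity(rel)
means = adiv.join(meta.frame["group"]).groupby("group")["shannon"].mean()
print("mean Shannon index per stage:")
print(means.round(3).to_string())

dist = bray_curtis(rel)
res = permanova(dist, meta.group, n_perm=9999, seed=1)
print(f"\nperMANOVA (9999 permutations): pseudo-F = {res.statistic:.2f}, "
      f"p = {res.p_value:.4f}")

ord_res = dbrda(dist, meta.group)
print(f"dbRDA: {ord_res.scores.shape[1]} constrained axes, "
      f"{100 * ord_res.constrained_proportion:.1f}% of total inertia "
      f"explained by disease stage")
print("\nA small p with a few percent constrained inertia is typical of "
      "community-level shifts driven by a modest set of planted species.")
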