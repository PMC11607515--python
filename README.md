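# triomics

Microbiome–metabolome–phenotype association pipeline for staged-disease
cohorts: from species/KO abundance tables and serum metabolite feature
tables to differential species, KEGG-module reporter scores,
co-abundance serum metabotypes, and a tiered-FDR three-way association
map against clinical phenotypes.

The package targets the common design in cardiometabolic microbiome
studies: an ordered three-group cohort — healthy controls (HC), stable
coronary artery disease (SCAD) and myocardial infarction (MI) — profiled
by shotgun metagenomics (species and KO functional abundances) and
untargeted serum metabolomics, with clinical severity scores (Gensini,
Syntax, cTnI, TIMI) per subject. It ships a synthetic-cohort generator
with planted ground truth so every stage of the chain can be validated
end to end without access to patient data.

## What it computes

**Differential species screen.** For a reference-vs-case contrast
(e.g. HC vs pooled CAD), each species is tested with the two-sided
Mann–Whitney U test; a species passes when

&nbsp;&nbsp;*p* < 0.01 **and** (FC > 1.2 **or** FC < 0.83),

where FC = (mean case + c)/(mean reference + c) on relative abundances
with pseudocount *c*. BH q-values are attached for reporting.

**KEGG-module reporter scores.** Per-KO Wilcoxon p-values are mapped to
signed z-scores, z = Φ⁻¹(1 − p/2)·sign, aggregated per module as
Z_raw = Σz/√k, and corrected against size-matched random KO sets:
Z = (Z_raw − μ_k)/σ_k. A module is significantly shifted when |Z| > 1.6
(≈95% one-tail normal confidence); the sign gives the direction.

**Co-abundance metabotypes.** Disease-associated metabolite features are
selected by a two-branch cross-comparison scheme (set A: any pairwise
comparison with Wilcoxon *q* < 0.05 and t-test *q* < 0.05 and a
fold-change gate; set B: Jonckheere–Terpstra or Kruskal–Wallis *p* <
0.05 across the ordered groups; union kept). The selected features are
clustered on a signed weighted network a = ((1+r)/2)^β with β = 14,
topological-overlap dissimilarity 1 − TOM, average linkage and a
deterministic dynamic tree cut at deepSplit 4; clusters M01, M02, … are
summarized by eigen-features (PC1 across samples).

**Multi-omics integration.** Module activities × metabotype
eigen-features form a Spearman grid with a single BH family; every cell
carries a tier (strong *q* < 0.001, moderate *q* < 0.05, weak *q* < 0.1,
ns). Clinical phenotypes are associated by Mann–Whitney (group
contrasts, FDR < 0.1) or Spearman (continuous scores).

Supporting machinery: Shannon/Simpson α-diversity, Bray–Curtis
distances, PCoA, perMANOVA (pseudo-F, "+1" permutation p, seeded),
dbRDA constrained on disease stage, and a baseline-characteristics
table with automatic test selection (ANOVA / Kruskal–Wallis / χ² /
Fisher). All rank tests, the trend test, χ², Fisher and BH are
implemented from first principles and validated against independent
oracles in the test suite.

## Worked example

```python
from triomics import (CohortDesign, generate_cohort, screen_species,
                      bray_curtis, permanova, to_relative)

species, ko, met, meta, module_map, truth = generate_cohort(CohortDesign(seed=1))

records = screen_species(species, meta, comparison=("HC", "CAD"))
passing = [r for r in records if r.passes]
print(len(passing))                       # 13 of 150 species pass the gate

dist = bray_curtis(to_relative(species))
res = permanova(dist, meta.group, n_perm=9999, seed=1)
print(round(res.statistic, 2), res.p_value)   # 2.55 0.0001
```

The screen recovers all 12 planted differential species (13 passing =
12 planted + 1 borderline false positive at the nominal gate), and
perMANOVA saturates at the minimum attainable p = 1/(1+9999) because the
planted shifts separate the stages at the community level. Running
`python examples/04_reporter_scores.py` prints the five planted KEGG
modules at |Z| between 8.6 and 10.8 with the planted signs, and
`examples/05_metabotypes.py` recovers the five planted metabolite
clusters with adjusted Rand index 1.000. Each script in `examples/` is a
short narrative of one capability; the `triomics` command line
(`triomics simulate`, `triomics run-all --synthetic --out runs/demo`)
orchestrates the full chain and writes TSV outputs plus a JSON run
manifest.

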