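# Synthetic fixture cohort

A tiny synthetic cohort (3 groups x 6 samples; 12 species, 30 KOs,
4 modules, 18 metabolite features) for documentation examples and quick
CLI experiments. Regenerate with:

    triomics simulate --seed 3 --out examples/data --small

Run the pipeline on it with:

    triomics run-all --input-dir examples/data --out runs/demo --seed 3
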