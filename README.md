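# costex

Cost–benefit modelling of gene-expression fitness, and analysis of gene
retention after whole-genome duplications (WGDs).

The package has three layers:

1. **Model** (`costex.model`) — fitness of a gene as the benefit of its
   expression minus a Monod-type cost of mobilising limited cellular
   resources, `C(X) = kX/(1 − X/M)`. The benefit is calibrated so a gene
   expressed at its optimum `X0` has relative fitness 1 and zero slope
   there. From the calibrated model follow selection coefficients against
   halving expression (duplicate loss), against expressing a
   non-functional peptide (pseudogenization), and against missense
   alleles — all increasing with `X0`.
2. **Simulator** (`costex.popgen`) — turns per-gene coefficients into
   stochastic post-WGD retention outcomes through a fixation-probability
   scaled loss hazard, `P(retained) = exp(−2·λ0·r(s)·T)` with
   `r(s) = 4Ne·s/(e^{4Ne·s} − 1)`, plus a calibration helper that solves
   the loss intensity for a target genome-wide retention.
3. **Analyses** (`costex.retention`, `costex.metrics`,
   `costex.pipeline`) — expression summarization (probe medians,
   between-array normalization, log2-of-median levels), random-member
   ohnologon expression assignment, fixed-interval retention binning with
   small-bin exclusion, extreme-decile contrasts, stratified retention,
   functional-category enrichment, ohnolog expression-divergence metrics,
   Ka–expression correlation and the heterozygous-KO fitness-by-expression
   analysis.

A seeded synthetic-data generator (`costex.synth`) produces every input
table with the statistical structure the analyses assume, so the whole
pipeline is testable without any external downloads.

## CLI

```bash
costex generate --seed 1 --outdir data/              # synthetic dataset
costex simulate --models data/gene_models.tsv --seed 1 --out sim.tsv
costex analyze-retention --expression data/expression.tsv \
    --ohnologons data/ohnologons.tsv --annotation data/annotation.tsv \
    --interval 0.2 --min-bin 30 --seed 1 --outdir results/
costex analyze-divergence --expression data/expression.tsv \
    --ohnologons data/ohnologons.tsv --ka data/ka_pairs.tsv --outdir results/
costex analyze-ko --ko data/ko_fitness.tsv --expression data/expression.tsv \
    --outdir results/
costex model-curves --x0 10 --x0 50 --x0 90 --out curves.tsv
costex run-all --seed 1 --outdir run/                # everything + summary.json
```

All interchange files are tab-separated UTF-8 text; outputs carry
provenance comment headers (`# key=value`). Generator parameters live in
a YAML config (`costex run-all --config cfg.yaml`); unknown keys are
rejected.

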