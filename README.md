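# txmeta

Cross-study transcriptome meta-analysis for small rodent early-life-stress
(ELS) cohorts, built as a tested, fully offline pipeline. It re-implements
the analysis chain used to synthesize ELS-versus-control prefrontal-cortex
expression effects across five public studies (GSE89692, GSE116416,
GSE14720, GSE153043, GSE124387): per-study differential expression with
empirical-Bayes variance moderation, per-gene random-effects meta-analysis,
Benjamini-Hochberg FDR control, and preranked permutation gene-set
enrichment. A synthetic multi-study cohort generator with known ground
truth stands in for the real GEO downloads, so every stage is verifiable
end to end on a laptop.

Intended users: computational biologists who want a transparent, scriptable
version of the "moderated DE per study, then random-effects synthesis"
workflow, and statisticians who want its components (REML τ², BH step-up,
the GSEA walk) as plain, tested functions.

## The model

Per study *i*, gene-wise linear models `y ~ Intercept + Treatment`
(plus `LibrarySize + Sex` for the one covariate-bearing design) yield a
log2 fold change y_gi and an unscaled coefficient SD u_gi. Residual
variances s²_g are shrunk toward an abundance-dependent prior s₀²(A) with
prior degrees of freedom d₀ (estimated by closed-form moment matching of
log-variances), giving moderated t-statistics and standard errors
SE_gi = u_gi · s̃_gi. Count-based studies instead receive per-observation
precision weights from the fitted mean-variance trend of log2-CPM values.

Per gene, effects are synthesized with an intercept-only random-effects
model

    y_i = μ + u_i + e_i,   u_i ~ N(0, τ²),  e_i ~ N(0, v_i),  v_i = SE_i²

with τ² estimated by REML (Fisher scoring with step halving,
DerSimonian-Laird fallback), weights w_i = 1/(v_i + τ²),
μ̂ = Σw_i y_i / Σw_i, SE(μ̂) = (Σw_i)^(-1/2), normal inference and 95% CIs.
Genes must be present in ≥ 4 of 5 studies to enter the meta-analysis; BH
FDR is computed over the genes with stable fits. Enrichment of gene sets
in the z-ranked results uses the weighted Kolmogorov-Smirnov running sum
with a seeded gene-sampling permutation null.

## Worked example

```python
from txmeta.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    outdir="demo",
    seed=7,
    simulate={"n_genes": 1000, "effect_fraction": 0.05, "effect_mean": 0.6},
)
bundle = run_pipeline(cfg)
print(bundle["totals"])
print(bundle["meta"].sort_values("p").head(3))
```

This simulates the five-study cohort (group sizes mirroring the emulated
manifest, two injected outlier samples in the 46-sample study and one in
the 10-sample study), runs QC, per-study DE, harmonization and the
meta-analysis, and prints:

```
{'n_ref': 45, 'n_els': 44, 'n_total': 89}
                estimate     se  tau2        p      fdr  k significance
harmonized_key
13977              0.949 0.0679     0 2.21e-44 2.04e-41  5     FDR<0.05
11275              0.996 0.0853     0 1.78e-31 8.24e-29  5     FDR<0.05
15398              0.822 0.0723     0 6.04e-30 1.86e-27  5     FDR<0.05
```

QC removed exactly the three injected outliers, leaving a final n of 89;
925 of 1000 genes survived the ortholog mapping and the 4-of-5 presence
filter; 44 genes were called at FDR < 0.05, of which 93% carry a true
simulated effect (the truth table is in `bundle["truth"]`). Per-study
outputs, the cohort manifest, drop logs and a run-metadata JSON land in
`demo/`.

The same pipeline is scriptable from the shell:

```sh
txmeta run-all --config pipeline.yaml
txmeta gsea --meta-results demo/meta_results.tsv --gmt sets.gmt \
    --out demo/gsea.tsv --n-perm 10000 --seed 1
```

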