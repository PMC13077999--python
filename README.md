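# mrscreen

Metabolome-wide **two-sample Mendelian randomisation** screening from GWAS
summary statistics, with the full sensitivity battery used in published
metabolite–disease screens and a synthetic-data generator that makes every
stage verifiable without downloading any GWAS.

## Who this is for

Epidemiologists and statistical geneticists running hypothesis-free MR
screens: hundreds of exposures (e.g. circulating metabolite
concentrations) tested against one disease outcome (a case-control GWAS),
where each exposure's instruments must be selected, harmonised and
stress-tested before its causal estimate is believed.

## The statistics

For exposure instruments j = 1..J with exposure effects γ̂_j (SE σ_xj) and
outcome effects Γ̂_j (SE σ_yj) aligned to the same allele, the primary
estimator is the multiplicative random-effects inverse-variance weighted
(IVW) estimate

    β̂ = Σ w_j γ̂_j Γ̂_j / Σ w_j γ̂_j²,   w_j = σ_yj⁻²,
    SE(β̂) = (Σ w_j γ̂_j²)^(-1/2) · √max(1, Q/(J−1)),

with Q = Σ w_j (Γ̂_j − β̂ γ̂_j)² Cochran's heterogeneity statistic. Around
it the battery reports the Wald ratio (J = 1), fixed-effect IVW, MR-Egger
(free intercept = average directional pleiotropy, t inference on J−2 df),
the weighted median and the weighted mode (both with seeded
parametric-bootstrap SEs), plus mean instrument F, I²_GX, radial-MR
outlier detection/removal, leave-one-out refits and the q-q median
inflation factor λ. Instrument selection walks a p-value ladder
(5e-8 → 5e-6) with greedy LD clumping (r² < 0.001 in a 10,000-kb window),
LD-proxy substitution (r² > 0.9) and a ≥ 5 independent-instrument rule;
harmonisation resolves allele swaps, strand flips and palindromic
ambiguity (MAF > 0.42 excluded). Screen-wide significance is Bonferroni
(α/number of exposures attempted; 0.05/575 ≈ 8.7e-5 for a 575-metabolite
panel) or Benjamini–Hochberg FDR. See `docs/methods.md` for the model,
assumptions and numerical choices.

## Worked example

Simulate a 6-metabolite panel (2 truly causal) with its outcome GWAS and
LD reference, then screen it:

```bash
mrscreen simulate --out demo --n-exposures 6 --n-causal 2 --seed 5
mrscreen screen --exposure-dir demo/exposures --outcome demo/outcome.tsv \
                --ld demo/ld.tsv --out demo/run
```

which prints

```
wrote 6 exposures (2 causal) to demo
6 exposures tested; threshold 0.00833 (bonferroni); 2 significant; lambda_median nan
wrote demo/run.batteries.tsv
wrote demo/run.screen.tsv
wrote demo/run.qq.tsv
wrote demo/run.log
```

`demo/run.screen.tsv` holds one row per exposure with the primary
(IVW random-effects) p-value, its Bonferroni-adjusted value and the
significance call — here the two simulated causal metabolites and no
false positive (the λ column is NaN because λ is only computed for
screens of ≥ 10 exposures):

```
exposure_id     primary_p           adjusted_p        significant
metabolite_0    0.279819669157      1                 False
metabolite_1    8.23154048025e-08   4.93892428815e-07 True
```

`demo/run.batteries.tsv` holds the full battery per exposure (all five
estimators, Q and its p, I²_GX, mean F, radial outliers removed,
leave-one-out count, SNP accounting). `demo/truth.tsv` carries the
generator's latent effects for comparison. The same machinery is callable
per exposure (`mrscreen single --method ivw_mre ...`) and from Python:

```python
from mrscreen import SimulationConfig, simulate_pair, ivw

exposure, outcome, truth = simulate_pair(SimulationConfig(true_beta=0.2, seed=3))
print(ivw(truth.to_harmonised()))
# EstimatorResult(method='ivw_mre', beta=0.2103..., se=0.0186..., pvalue=1.43e-29, n_snp=9, ...)
```

A harmonised set exports its per-SNP effect table (the scatter-plot data)
via `battery.final_pairs.to_frame()`.

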