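# Methods

## The screen

`mrscreen` implements a metabolome-wide two-sample Mendelian randomisation
(MR) screen: for each circulating metabolite (exposure), genetic variants
robustly associated with its concentration are used as instruments to
estimate the causal effect of the metabolite on a disease outcome (a
case-control GWAS on the log-odds scale), using only published summary
statistics from two non-overlapping samples.

Per exposure the pipeline runs a fixed stage order:

1. **Instrument selection** (`instruments`). Candidates are exposure
   associations passing a p-value ladder walked from the most stringent
   rung (default 5e-8) to the most permissive (5e-6); the first rung whose
   post-clump count reaches `min_instruments` (default 5) is used, and
   exposures that never reach it are rejected, not analysed. Clumping is
   greedy: the lowest-p SNP is kept and all SNPs with r² ≥ 0.001 within a
   10,000-kb window are dropped, repeating until exhaustion; ties in p are
   broken by (chromosome, position, variant id) so the result is invariant
   to input order, and the retained set is re-certified pairwise
   independent on every run. Instruments missing from the outcome GWAS are
   replaced by their best LD proxy with r² > 0.9 (signed r required; the
   sign maps the proxy's effect back onto the instrument), else excluded.
2. **Harmonisation** (`harmonisation`). Outcome effects are aligned to the
   exposure's effect allele: allele-order swaps flip the sign and the
   frequency; non-palindromic strand mismatches are resolved by
   complementing; palindromic variants (A/T, C/G) are aligned by
   minor-allele matching when the minor allele frequency is ≤ 0.42 on both
   traits and excluded (reason `palindromic_ambiguous`) above that or when
   either frequency is missing. Every exclusion is typed and the identity
   |instruments| = |pairs| + |exclusions| is asserted.
3. **Pleiotropy p-filter** (`instruments.pleiotropy_p_filter`). A SNP more
   significantly associated with the outcome than with the exposure
   (p_outcome < p_exposure, strict) is removed before estimation. The
   filter runs before radial outlier removal; both removal lists are kept
   separately so either order can be audited.
4. **Radial outlier removal** (`diagnostics.radial_outliers`). The radial
   reformulation of IVW regresses Γ̂/σ_y on γ̂/σ_y through the origin; each
   SNP's contribution Q_j is referred to χ²(1). Removal is worst-first —
   one SNP per iteration, then refit — because a gross outlier drags the
   slope and can make sound instruments look discrepant; iteration stops
   when nothing is flagged or removal would leave fewer than 3 pairs. The
   screen prunes at the Bonferroni-per-set threshold α/J (the convention of
   the radial-MR literature): per-SNP α = 0.05 over-prunes null exposures,
   which shrinks Q, deflates the random-effects SE and inflates the
   screen's family-wise error (measured per-test type I error 0.072 at
   nominal 0.05, vs 0.048 with α/J). Direct calls to the operation default
   to per-SNP α = 0.05.
5. **Estimator battery** (`estimators`), computed on the post-filter,
   post-radial set; all five estimators are reported but only the
   multiplicative random-effects IVW p-value gates significance:
   - *Wald ratio* (J = 1): Γ̂/γ̂ with first-order delta SE σ_y/|γ̂|.
   - *IVW*: weighted regression of Γ̂ on γ̂ through the origin with weights
     w = σ_y⁻²; the multiplicative random-effects variant scales the SE by
     √max(1, Q/(J−1)) so overdispersion widens but never narrows intervals
     (an untruncated variant exists behind a flag). Normal inference.
   - *MR-Egger*: the same regression with a free intercept after orienting
     all γ̂ ≥ 0 (the intercept — the average directional pleiotropic
     effect — is otherwise unidentified); t inference on J−2 df, SEs
     scaled by √max(1, Q/(J−2)).
   - *Weighted median*: weighted empirical 0.5-quantile of the per-SNP
     ratios (midpoint cumulative weights, linear interpolation), weights
     = inverse ratio variance; SE by seeded parametric bootstrap
     (default 1000 draws) resampling γ̂ and Γ̂ from their normal errors.
   - *Weighted mode*: argmax of the Gaussian-kernel weighted density of
     the ratios, bandwidth = `bandwidth_factor` × the modified Silverman
     rule 0.9·min(sd, 1.4826·MAD)·J^(−1/5); same bootstrap for the SE.
6. **Diagnostics** (`diagnostics`): Cochran's Q about the IVW fit with a
   χ²(J−1) p-value (reported as the statistic and its p separately);
   I²_GX = max(0, (Q_GX − (J−1))/Q_GX) measuring instrument-strength
   heterogeneity (low values warn of MR-Egger dilution toward the null);
   mean F = mean (γ̂/σ_x)² with a weak-instrument flag at mean F ≤ 10;
   leave-one-out IVW refits with the count of refits losing significance
   at 0.05; and, screen-level, the q-q median inflation factor
   λ = χ²₁-quantile(1 − median p)/median(χ²₁), flagged above 1.1.

Family-wise control divides α = 0.05 by the number of exposures
*attempted* (the full panel, e.g. 0.05/575 ≈ 8.7e-5), not the number
analysable; Benjamini–Hochberg FDR control is available as a config
switch and every Bonferroni-significant exposure is necessarily
BH-significant at the same family α. Validation and sex-stratified
analyses are plain config variants (different exposure/outcome files);
there is no special code path.

## The synthetic generator

`synthetic.simulate_pair` draws, per SNP j: a minor allele frequency m_j;
a true instrument effect γ_j ≥ 0 in SD units of the exposure, coded on the
exposure-increasing allele; a direct (pleiotropic) outcome effect α_j, zero
for valid instruments and otherwise normal with mean μ_α, SD σ_α and
correlation ρ with the standardised instrument strengths (ρ = 0 is the
InSIDE condition); and the true outcome effect Γ_j = β·γ_j + α_j on the
log-odds scale. Observed effects add normal noise with

    se(γ̂) = (2m(1−m)·n_x)^(−1/2)          (standardised continuous trait)
    se(Γ̂) = 2·(2m(1−m)·n_eff)^(−1/2),      n_eff = 4/(1/cases + 1/controls)

the latter being the logistic-regression information bound
Var(β̂) = 1/(φ(1−φ)·n·v) with φ(1−φ)·n = n_eff/4. At the default outcome
(29,612 cases / 122,656 controls, n_eff ≈ 95,400) this gives per-SNP
log-odds SEs ≈ 0.011 at m = 0.2, the scale real case-control GWAS report.
The standardised-trait formula ignores the per-SNP variance explained
(valid for small effects) — that is the generator's regime.

Two choices make the generator emulate *selected* instruments rather than
arbitrary variants, because the pipeline's inputs in practice are SNPs
that already survived genome-wide selection:

- **Instrument strength** defaults to a per-SNP true association strength
  λ² = n_x·2m(1−m)·γ² (the expected F − 1) drawn uniformly from [30, 50],
  giving mean F ≈ 41 — inside the 22–51 band a well-powered metabolite
  screen reports — and making the p-value ladder pass near-certain.
  Truncating the *true* effects rather than the observed ones introduces
  no winner's-curse bias. Setting `instrument_f_range=None` reverts to
  untruncated half-normal effects of SD `gamma_sd`.
- **The MAF spectrum** defaults to log-uniform on (0.003, 0.5): rare,
  larger-effect variants are prominent among top metabolite instruments,
  and the resulting spread of per-SNP precisions puts I²_GX at a median
  ≈ 0.92 (the 0.94–0.98 regime of real batteries) while a uniform spectrum
  at the same mean F sits near 0.6–0.7.

Harmonisation stressors — allele-order re-coding (default 50% of outcome
records), strand complementation, palindromic allele assignment, and
outcome-record deletion with a planted LD proxy (|r| = 0.95, random sign)
— are driven by a dedicated random substream, so toggling them never
changes the latent truth; all randomness descends from one seed through
named substreams (effects, noise, stressors). The truth record carries
every latent quantity plus a minimal LD reference (self pairs and planted
proxy pairs), and `truth.to_harmonised()` returns the ground-truth-aligned
pair set for estimator-level studies.

`simulate_ld_reference` builds block-AR(1) LD (within-block
r(i,j) = ρ^|i−j|) with candidate z-scores consistent with the blocks, for
clumping and proxy tests. `simulate_screen_panel` scales this to a
metabolome panel: a chosen number of causal exposures with |β| drawn from
[0.2, 0.7] (signs mixed — the effect band of reported screen hits), the
rest null, all sharing one outcome GWAS and one LD reference.

### What the generator does not emulate

No individual-level genotypes, no sample overlap between the two GWAS, no
winner's curse (selection acts on true effects), no LD between
instruments of different exposures, no population stratification, and no
non-collapsibility or attenuation specific to the liability scale. Passing
tests therefore demonstrate the statistical machinery is correct under
the stated generative model, not that any real metabolite is causal.

## Numerical and design notes

- IVW and Egger are closed-form weighted least squares evaluated from
  normal equations in double precision; tests verify agreement with an
  extended-precision oracle and statsmodels WLS to 1e-10.
- Weak-instrument attenuation: with mean F ≈ 40 the IVW estimate is
  attenuated by roughly λ²/(λ²+1) ≈ 2%, visible in recovery studies as a
  mean estimate ≈ 0.196 at a true 0.2. MR-Egger's slope attenuation
  likewise leaks β·(1−I²_GX)·γ̄ into its intercept; intercept-recovery
  studies are therefore run at β = 0 where the identity is exact.
- The two IVW modes share φ = Q/(J−1) truncated at 1; underdispersion
  cannot shrink SEs (conservatism), matching common practice.
- Bootstrap seeds are mandatory; the screen derives one per exposure from
  the config seed and a CRC of the exposure id, so results are independent
  of panel ordering and byte-identical across reruns (outputs carry fixed
  float formatting and no timestamps).
- Degenerate inputs: a zero exposure effect makes the ratio undefined and
  is a hard error naming the variant; identical ratios give the weighted
  mode a zero bandwidth, handled by returning the common value; the radial
  and leave-one-out stages refuse sets below 3 pairs, and the battery
  records refused methods as typed-unavailable rather than failing.
- Screen-level calibration: per-test type I error of the full pipeline is
  0.048 at nominal 0.05 and ≈ 1.9e-3 at the 1.25e-3 Bonferroni tail of a
  40-exposure screen — the residual tail heaviness is conditioning from
  outlier pruning before final estimation, a property of the published
  pipeline design itself (the raw random-effects IVW tail is conservative).

## Problem sizes used in the test suite and acceptance script

Simulation-based checks run at an exposure GWAS of n = 8,000–10,000
against an outcome of effective n = 80,000, J = 9–20 instruments, with
500–1000 replicates for calibration/recovery studies, 200–500 for
robustness and detection rates, and 12–20 replicate screens of 40
exposures (4 causal) for the end-to-end study; bootstrap draws are reduced
to 100–200 inside the replicated screens. These sizes make the whole suite
a few minutes of single-CPU work while keeping Monte-Carlo error well
inside the asserted tolerances.
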