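"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generative model is the standard summary-level instrumental-variable
model. For SNP j with minor allele frequency m_j and true instrument
effect γ_j (SD units of the exposure, coded on the exposure-increasing
allele), the true outcome effect on the log-odds scale is

    Γ_j = β · γ_j + α_j,

where β is the causal effect and α_j a direct (pleiotropic) effect: zero
for valid instruments, otherwise drawn with mean μ_α (directional
component), SD σ_α, and correlation ρ with the standardized instrument
strengths (ρ = 0 ⇔ InSIDE holds). Observed effects are the truth plus
normal noise with the standardized-trait standard errors

    se(γ̂_j) = (2 m_j (1−m_j) n_x)^(−1/2),
    se(Γ̂_j) = 2 (2 m_j (1−m_j) n_eff)^(−1/2),  n_eff = 4/(1/cases + 1/controls),

(the log-odds SE is the logistic-regression information bound
1/sqrt(φ(1−φ)·n·v) with φ(1−φ)n = n_eff/4),

valid for small per-SNP variance explained. Instruments emulate
genome-wide-selected SNPs: by default the per-SNP true association
strength λ_j² = n_x·2m(1−m)γ² (the expected F − 1) is drawn uniformly
from ``instrument_f_range``; truncating the TRUE effects rather than the
observed ones introduces no winner's-curse bias. Set
``instrument_f_range=None`` for untruncated half-normal effects of SD
``gamma_sd``.

Harmonisation stressors (allele re-coding, strand complementation,
palindromic assignment, outcome deletion with a planted LD proxy) are
applied from a dedicated random substream, so toggling them never changes
the latent truth. Every latent quantity is returned in the truth record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from mrscreen.harmonisation import COMPLEMENT, HarmonisedPair, HarmonisedSet
from mrscreen.sumstats_io import LDReference, SummaryStatRecord, SummaryStatSet

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = tuple(
    (a, b) for a in "ACGT" for b in "ACGT" if b not in (a, COMPLEMENT[a]))


def effective_n(cases: int, controls: int) -> float:
    """Effective sample size of a case-control GWAS: 4/(1/cases+1/controls)."""
    return 4.0 / (1.0 / cases + 1.0 / controls)


@dataclass
class SimulationConfig:
    """Parameters of the generative model (defaults = the screen's regime).

    Sample sizes default to a metabolite-GWAS-scale exposure (n = 8000)
    against a large case-control outcome (29,612 cases / 122,656
    controls); instrument strength defaults to expected F in 31–51,
    matching the mean-F range a well-powered screen reports (22–51).
    """

    n_snps: int = 9
    true_beta: float = 0.0
    maf_range: tuple = (0.003, 0.5)
    maf_log_uniform: bool = True
    gamma_sd: float = 0.115
    instrument_f_range: tuple | None = (30.0, 50.0)
    n_exposure: int = 8000
    n_outcome_cases: int = 29_612
    n_outcome_controls: int = 122_656
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    prop_invalid: float = 0.0
    inside_correlation: float = 0.0
    ld_block_size: int = 1
    ld_rho: float = 0.0
    palindromic_fraction: float = 0.0
    strand_flip_fraction: float = 0.0
    swap_fraction: float = 0.5
    missing_outcome_fraction: float = 0.0
    proxy_r: float = 0.95
    eaf_noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.prop_invalid <= 1):
            raise ValueError("prop_invalid must lie in [0, 1]")
        if abs(self.inside_correlation) >= 1:
            raise ValueError("|inside_correlation| must be < 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")

    @property
    def n_eff(self) -> float:
        return effective_n(self.n_outcome_cases, self.n_outcome_controls)

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class PairTruth:
    """Latent state of one simulated exposure/outcome pair."""

    config: SimulationConfig
    variant_ids: list
    maf: np.ndarray
    gamma: np.ndarray            # true instrument effects (aligned coding)
    alpha: np.ndarray            # true direct (pleiotropic) effects
    Gamma: np.ndarray            # true outcome effects
    invalid: np.ndarray          # bool: alpha_j != 0 allowed
    gamma_hat: np.ndarray        # observed, aligned coding
    se_gamma: np.ndarray
    p_gamma: np.ndarray
    Gamma_hat: np.ndarray        # observed, aligned coding
    se_Gamma: np.ndarray
    p_Gamma: np.ndarray
    palindromic: np.ndarray      # stressor bookkeeping, per SNP
    swapped: np.ndarray
    strand_flipped: np.ndarray
    missing_outcome: np.ndarray
    proxy_ids: dict              # variant_id -> (proxy_id, signed r)
    ld: LDReference              # self pairs + planted proxy pairs

    def to_harmonised(self, exposure_id: str = "exposure",
                      outcome_id: str = "outcome") -> HarmonisedSet:
        """Ground-truth-aligned harmonised set (bypasses stressors)."""
        pairs = []
        for j, vid in enumerate(self.variant_ids):
            pairs.append(HarmonisedPair(
                variant_id=vid,
                gamma=float(self.gamma_hat[j]), se_gamma=float(self.se_gamma[j]),
                p_gamma=float(self.p_gamma[j]),
                Gamma=float(self.Gamma_hat[j]), se_Gamma=float(self.se_Gamma[j]),
                p_Gamma=float(self.p_Gamma[j]), eaf=float(self.maf[j])))
        return HarmonisedSet(exposure_id, outcome_id, pairs)


def _substreams(seed: int, n: int = 3):
    """Named child generators (effects, noise, stressors) from one seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def _draw_alleles(rng, n: int, palindromic_fraction: float):
    pal = rng.random(n) < palindromic_fraction
    pairs = []
    for j in range(n):
        pool = _PALINDROMIC_PAIRS if pal[j] else _NONPALINDROMIC_PAIRS
        pairs.append(pool[rng.integers(len(pool))])
    return pairs, pal


def simulate_pair(config: SimulationConfig):
    """Simulate one exposure GWAS, the outcome GWAS rows, and the truth.

    Returns (exposure SummaryStatSet, outcome SummaryStatSet, PairTruth).
    Identical config (including seed) gives byte-identical output.
    """
    cfg = config
    J = cfg.n_snps
    rng_eff, rng_noise, rng_str = _substreams(cfg.seed)

    # --- latent truth (effects substream) ---------------------------------
    if cfg.maf_log_uniform:
        maf = np.exp(rng_eff.uniform(math.log(cfg.maf_range[0]),
                                     math.log(cfg.maf_range[1]), J))
    else:
        maf = rng_eff.uniform(cfg.maf_range[0], cfg.maf_range[1], J)
    var_per_allele = 2.0 * maf * (1.0 - maf)
    if cfg.instrument_f_range is not None:
        lam2 = rng_eff.uniform(cfg.instrument_f_range[0],
                               cfg.instrument_f_range[1], J)
        gamma = np.sqrt(lam2 / (var_per_allele * cfg.n_exposure))
    else:
        gamma = np.abs(rng_eff.normal(0.0, cfg.gamma_sd, J))
    invalid = rng_eff.random(J) < cfg.prop_invalid
    alpha = np.zeros(J)
    if invalid.any() and (cfg.pleiotropy_sd > 0 or cfg.pleiotropy_mean != 0):
        sd_g = gamma.std()
        z_g = (gamma - gamma.mean()) / sd_g if sd_g > 0 else np.zeros(J)
        rho = cfg.inside_correlation
        eps = rng_eff.standard_normal(J)
        alpha_all = (cfg.pleiotropy_mean
                     + cfg.pleiotropy_sd * (rho * z_g
                                            + math.sqrt(1 - rho ** 2) * eps))
        alpha = np.where(invalid, alpha_all, 0.0)
    Gamma = cfg.true_beta * gamma + alpha

    # --- observation noise (noise substream) ------------------------------
    se_gamma = (var_per_allele * cfg.n_exposure) ** -0.5
    se_Gamma = 2.0 * (var_per_allele * cfg.n_eff) ** -0.5
    gamma_hat = gamma + se_gamma * rng_noise.standard_normal(J)
    Gamma_hat = Gamma + se_Gamma * rng_noise.standard_normal(J)
    p_gamma = _two_sided_p(gamma_hat, se_gamma)
    p_Gamma = _two_sided_p(Gamma_hat, se_Gamma)

    # --- records and stressors (stressor substream) -----------------------
    variant_ids = [f"rs{cfg.seed % 100_000}_{j}" for j in range(J)]
    chroms = [str((j % 22) + 1) for j in range(J)]
    positions = [1_000_000 + 50_000_000 * (j // 22) for j in range(J)]
    allele_pairs, palindromic = _draw_alleles(rng_str, J,
                                              cfg.palindromic_fraction)
    swapped = rng_str.random(J) < cfg.swap_fraction
    strand = (rng_str.random(J) < cfg.strand_flip_fraction) & ~palindromic
    missing = rng_str.random(J) < cfg.missing_outcome_fraction
    proxy_sign = np.where(rng_str.random(J) < 0.5, 1.0, -1.0)
    out_eaf_noise = rng_str.normal(0.0, cfg.eaf_noise_sd, J)

    ld = LDReference(window_bp=10_000_000, signed=True)
    exposure = SummaryStatSet(f"exposure_{cfg.seed}", "continuous")
    outcome = SummaryStatSet("outcome", "binary")
    proxy_ids: dict = {}

    for j, vid in enumerate(variant_ids):
        ea, oa = allele_pairs[j]
        eaf = float(maf[j])  # effect allele coded exposure-increasing, minor
        exposure.add(SummaryStatRecord(
            variant_id=vid, effect_allele=ea, other_allele=oa,
            beta=float(gamma_hat[j]), se=float(se_gamma[j]),
            pvalue=float(p_gamma[j]), chromosome=chroms[j],
            position=positions[j], eaf=eaf, n=cfg.n_exposure))
        ld.positions[vid] = (chroms[j], positions[j])

        out_eaf = float(np.clip(eaf + out_eaf_noise[j], 1e-3, 1 - 1e-3))
        o_beta, o_ea, o_oa, o_eaf = float(Gamma_hat[j]), ea, oa, out_eaf
        if swapped[j]:
            o_beta, o_ea, o_oa, o_eaf = -o_beta, o_oa, o_ea, 1.0 - o_eaf
        if strand[j]:
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]

        if missing[j]:
            # plant an LD proxy instead of the instrument itself
            pid = f"{vid}px"
            r = float(proxy_sign[j] * cfg.proxy_r)
            pG = r * Gamma[j]
            pG_hat = float(pG + se_Gamma[j] * rng_str.standard_normal())
            pea, poa = _NONPALINDROMIC_PAIRS[
                rng_str.integers(len(_NONPALINDROMIC_PAIRS))]
            outcome.add(SummaryStatRecord(
                variant_id=pid, effect_allele=pea, other_allele=poa,
                beta=pG_hat, se=float(se_Gamma[j]),
                pvalue=float(_two_sided_p(np.array([pG_hat]),
                                          np.array([se_Gamma[j]]))[0]),
                chromosome=chroms[j], position=positions[j] + 10_000,
                eaf=o_eaf, n=cfg.n_outcome_cases + cfg.n_outcome_controls))
            ld.add(vid, pid, r)
            ld.positions[pid] = (chroms[j], positions[j] + 10_000)
            proxy_ids[vid] = (pid, r)
        else:
            outcome.add(SummaryStatRecord(
                variant_id=vid, effect_allele=o_ea, other_allele=o_oa,
                beta=o_beta, se=float(se_Gamma[j]), pvalue=float(p_Gamma[j]),
                chromosome=chroms[j], position=positions[j], eaf=o_eaf,
                n=cfg.n_outcome_cases + cfg.n_outcome_controls))

    truth = PairTruth(
        config=cfg, variant_ids=variant_ids, maf=maf, gamma=gamma,
        alpha=alpha, Gamma=Gamma, invalid=invalid, gamma_hat=gamma_hat,
        se_gamma=np.asarray(se_gamma), p_gamma=p_gamma, Gamma_hat=Gamma_hat,
        se_Gamma=np.asarray(se_Gamma), p_Gamma=p_Gamma,
        palindromic=palindromic, swapped=swapped, strand_flipped=strand,
        missing_outcome=missing, proxy_ids=proxy_ids, ld=ld)
    return exposure, outcome, truth


def simulate_ld_reference(config: SimulationConfig):
    """Block-AR(1) LD reference plus correlated candidate exposure stats.

    ``n_snps`` candidates fall into consecutive blocks of ``ld_block_size``
    with within-block correlation r(i, j) = ld_rho^|i−j|; blocks are placed
    on alternating chromosomes so they always fit inside the clump window.
    Candidate z-scores are drawn consistently with the LD: the block's lead
    SNP carries a true signal which leaks into neighbours at rate r, and
    the noise shares the same correlation structure.

    Returns (LDReference, SummaryStatSet of candidates).
    """
    cfg = config
    if cfg.ld_block_size < 1:
        raise ValueError("ld_block_size must be >= 1")
    rng_eff, rng_noise, _ = _substreams(cfg.seed)
    J, B = cfg.n_snps, cfg.ld_block_size
    n_blocks = math.ceil(J / B)
    ld = LDReference(window_bp=10_000_000, signed=True)
    cands = SummaryStatSet(f"candidates_{cfg.seed}", "continuous")

    f_mid = (np.mean(cfg.instrument_f_range)
             if cfg.instrument_f_range is not None
             else cfg.gamma_sd ** 2 * cfg.n_exposure * 0.365)
    idx = 0
    for block in range(n_blocks):
        size = min(B, J - idx)
        offs = np.arange(size)
        corr = cfg.ld_rho ** np.abs(offs[:, None] - offs[None, :])
        np.fill_diagonal(corr, 1.0)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(size))
        lead_z = math.sqrt(f_mid)
        z_true = lead_z * cfg.ld_rho ** offs
        z_obs = z_true + chol @ rng_noise.standard_normal(size)
        maf = rng_eff.uniform(cfg.maf_range[0], cfg.maf_range[1])
        se = (2 * maf * (1 - maf) * cfg.n_exposure) ** -0.5
        chrom = str((block % 22) + 1)
        base = 1_000_000 + 50_000_000 * (block // 22)
        for i in range(size):
            vid = f"blk{block}_snp{i}"
            cands.add(SummaryStatRecord(
                variant_id=vid, effect_allele="A", other_allele="G",
                beta=float(z_obs[i] * se), se=float(se),
                pvalue=float(_two_sided_p(np.array([z_obs[i] * se]),
                                          np.array([se]))[0]),
                chromosome=chrom, position=base + 10_000 * i,
                eaf=float(maf), n=cfg.n_exposure))
            ld.positions[vid] = (chrom, base + 10_000 * i)
            for k in range(i):
                ld.add(f"blk{block}_snp{k}", vid,
                       float(cfg.ld_rho ** (i - k)))
        idx += size
    return ld, cands


@dataclass
class ScreenPanel:
    """A simulated exposure panel sharing one outcome GWAS."""

    exposures: list
    outcome: SummaryStatSet
    ld: LDReference
    truth: pd.DataFrame            # exposure_id, true_beta, causal
    pair_truths: dict = field(default_factory=dict)


def simulate_screen_panel(config: SimulationConfig, n_exposures: int,
                          n_causal: int,
                          effect_range: tuple = (0.2, 0.7)) -> ScreenPanel:
    """Simulate a metabolome-panel screen with a known causal subset.

    ``n_causal`` exposures receive a latent causal effect drawn uniformly
    from ±``effect_range`` (the effect-size band a well-powered metabolite
    screen reports); the remainder are null. All exposures share one
    outcome GWAS (disjoint instrument sets, as for independent metabolite
    loci) and one combined LD reference.
    """
    if n_causal > n_exposures:
        raise ValueError("n_causal must not exceed n_exposures")
    master = np.random.SeedSequence(config.seed)
    assign_rng = np.random.default_rng(master.spawn(1)[0])
    causal_idx = set(assign_rng.choice(n_exposures, size=n_causal,
                                       replace=False).tolist())
    betas = assign_rng.uniform(effect_range[0], effect_range[1], n_exposures)
    signs = np.where(assign_rng.random(n_exposures) < 0.5, 1.0, -1.0)

    child_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF)
                   for s in master.spawn(n_exposures + 1)[1:]]

    exposures, rows, pair_truths = [], [], {}
    outcome = SummaryStatSet("outcome", "binary")
    ld = LDReference(window_bp=10_000_000, signed=True)
    for i in range(n_exposures):
        beta_i = float(betas[i] * signs[i]) if i in causal_idx else 0.0
        sub = config.replace(true_beta=beta_i, seed=child_seeds[i])
        exp, out, truth = simulate_pair(sub)
        # prefix ids so instruments from different exposures never collide
        exp = _prefix_ids(exp, f"m{i}_", trait_id=f"metabolite_{i}")
        out = _prefix_ids(out, f"m{i}_", trait_id="outcome")
        for rec in out:
            outcome.add(rec)
        for (a, b), r in truth.ld._entries.items():
            ld.add(f"m{i}_{a}", f"m{i}_{b}", r)
        for vid, (chrom, pos) in truth.ld.positions.items():
            ld.positions[f"m{i}_{vid}"] = (chrom, pos)
        exposures.append(exp)
        pair_truths[exp.trait_id] = truth
        rows.append({"exposure_id": exp.trait_id, "true_beta": beta_i,
                     "causal": i in causal_idx})
    return ScreenPanel(exposures=exposures, outcome=outcome, ld=ld,
                       truth=pd.DataFrame(rows), pair_truths=pair_truths)


def _prefix_ids(sumstats: SummaryStatSet, prefix: str,
                trait_id: str) -> SummaryStatSet:
    out = SummaryStatSet(trait_id, sumstats.trait_type)
    for rec in sumstats:
        out.add(SummaryStatRecord(
            variant_id=prefix + rec.variant_id,
            effect_allele=rec.effect_allele, other_allele=rec.other_allele,
            beta=rec.beta, se=rec.se, pvalue=rec.pvalue,
            chromosome=rec.chromosome, position=rec.position,
            eaf=rec.eaf, n=rec.n))
    return out
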