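"""Screen orchestration: per-exposure pipeline and multiple-testing control.

The per-exposure stage order is fixed: instrument selection → harmonisation
→ pleiotropy p-filter → radial outlier removal → estimator battery →
diagnostics, with every removal logged. The multiplicative random-effects
IVW p-value is the screen's primary test statistic; the robust estimators
are reported but never gate significance. Family-wise control divides
alpha by the number of exposures *attempted*, not the number analysable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from mrscreen.config import ScreenConfig
from mrscreen.diagnostics import (DiagnosticsReport, cochran_q, i2_gx,
                                  leave_one_out, qq_inflation, radial_outliers)
from mrscreen.estimators import (EstimatorResult, MethodUnavailable, egger,
                                 ivw, wald_ratio, weighted_median,
                                 weighted_mode)
from mrscreen.harmonisation import HarmonisedSet, harmonise_set
from mrscreen.instruments import (InstrumentSet, Rejection, f_statistics,
                                  pleiotropy_p_filter, select_threshold)
from mrscreen.sumstats_io import LDReference, SummaryStatSet


@dataclass
class MRBattery:
    """The full per-exposure result block (Table-1 shape)."""

    exposure_id: str
    outcome_id: str
    analysable: bool
    results: dict = field(default_factory=dict)       # method -> EstimatorResult
    unavailable: dict = field(default_factory=dict)   # method -> reason
    diagnostics: DiagnosticsReport = field(default_factory=DiagnosticsReport)
    n_snp_initial: int = 0
    n_snp_final: int = 0
    n_excluded: int = 0
    n_pleiotropy_filtered: int = 0
    n_radial_outliers: int = 0
    rejection_reason: str = ""
    threshold_used: float = float("nan")
    proxies_used: dict = field(default_factory=dict)
    removal_log: dict = field(default_factory=dict)
    config_digest: str = ""
    final_pairs: HarmonisedSet | None = None   # post-filter, post-radial set

    @property
    def primary(self) -> EstimatorResult | None:
        """The screening statistic: ivw_mre, or the Wald ratio at J = 1."""
        return self.results.get("ivw_mre") or self.results.get("wald")


@dataclass
class ScreenResult:
    batteries: list
    correction: str
    alpha_family: float
    threshold: float
    n_tests: int
    significant_ids: list
    lambda_median: float
    lambda_flag: bool
    qq_pairs: np.ndarray | None
    adjusted_p: dict


def bonferroni_threshold(alpha_family: float, n_tests: int) -> float:
    """Family-wise significance cutoff: alpha divided by tests attempted."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha_family / n_tests


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _battery_seed(config_seed: int, exposure_id: str) -> int:
    """Deterministic, order-independent bootstrap seed per exposure."""
    tag = zlib.crc32(exposure_id.encode())
    ss = np.random.SeedSequence([int(config_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_single(exposure: SummaryStatSet, outcome: SummaryStatSet,
               ld: LDReference, config: ScreenConfig | None = None) -> MRBattery:
    """Run the full per-exposure pipeline and assemble the result battery."""
    config = config or ScreenConfig()
    battery = MRBattery(exposure_id=exposure.trait_id,
                        outcome_id=outcome.trait_id, analysable=False,
                        config_digest=config.digest())

    selection = select_threshold(exposure, ld, ladder=config.ladder,
                                 min_instruments=config.min_instruments,
                                 clump_r2=config.clump_r2,
                                 window_bp=config.clump_window_bp)
    if isinstance(selection, Rejection):
        battery.rejection_reason = (
            f"{selection.reason} (best {selection.best_count} < "
            f"{selection.min_instruments})")
        battery.n_snp_initial = selection.best_count
        return battery

    battery.n_snp_initial = len(selection)
    battery.threshold_used = selection.threshold_used

    hset = harmonise_set(selection, exposure, outcome, ld,
                         maf_limit=config.maf_limit,
                         proxy_r2_min=config.proxy_r2_min)
    battery.n_excluded = len(hset.exclusions)
    battery.removal_log["harmonisation_exclusions"] = dict(hset.exclusions)
    battery.proxies_used = {p.variant_id: "proxy" for p in hset
                            if "proxy" in p.flags}

    filtered, pleio_removed = pleiotropy_p_filter(hset)
    battery.n_pleiotropy_filtered = len(pleio_removed)
    battery.removal_log["pleiotropy_filtered"] = list(pleio_removed)

    if len(filtered) >= 3:
        outliers, iters, final = radial_outliers(
            filtered, alpha=config.radial_alpha, iterate=config.radial_iterate,
            bonferroni=config.radial_bonferroni)
    else:
        outliers, iters, final = [], 0, filtered
    battery.n_radial_outliers = len(outliers)
    battery.removal_log["radial_outliers"] = list(outliers)
    battery.n_snp_final = len(final)
    battery.final_pairs = final
    assert battery.n_snp_final == (battery.n_snp_initial - battery.n_excluded
                                   - battery.n_pleiotropy_filtered
                                   - battery.n_radial_outliers)

    if len(final) == 0:
        battery.rejection_reason = "no_instruments_after_filtering"
        return battery

    seed = _battery_seed(config.seed, exposure.trait_id)
    J = len(final)
    if J == 1:
        battery.results["wald"] = wald_ratio(final.pairs[0])
        for m in ("ivw_fe", "ivw_mre", "egger", "weighted_median",
                  "weighted_mode"):
            battery.unavailable[m] = "needs >= 2 instruments"
    else:
        battery.results["ivw_fe"] = ivw(final, mode="fixed")
        battery.results["ivw_mre"] = ivw(final, mode="multiplicative_random")
        battery.unavailable["wald"] = "multiple instruments; see ivw"
        for name, fn in (
                ("egger", lambda s: egger(s)),
                ("weighted_median",
                 lambda s: weighted_median(s, n_boot=config.n_boot, seed=seed)),
                ("weighted_mode",
                 lambda s: weighted_mode(s, bandwidth_factor=config.bandwidth_factor,
                                         n_boot=config.n_boot, seed=seed))):
            try:
                battery.results[name] = fn(final)
            except MethodUnavailable as exc:
                battery.unavailable[name] = str(exc)

    diag = DiagnosticsReport()
    primary = battery.results.get("ivw_mre") or battery.results.get("wald")
    if J >= 2 and primary is not None:
        diag.q, diag.q_df, diag.q_p = cochran_q(final, primary.beta)
        diag.i2_gx = i2_gx(final)
    diag.mean_f = float(np.mean((final.gamma / final.se_gamma) ** 2))
    diag.radial_outliers = list(outliers)
    diag.radial_iterations = iters
    if J >= 3:
        diag.loo, diag.n_loo_nonsig = leave_one_out(
            final, sig_level=config.loo_sig_level)
    if "egger" in battery.results:
        diag.egger_intercept_p = battery.results["egger"].extras[
            "egger_intercept_p"]
    battery.diagnostics = diag
    battery.analysable = True
    return battery


def run_screen(exposure_panel, outcome: SummaryStatSet, ld: LDReference,
               config: ScreenConfig | None = None) -> ScreenResult:
    """Run the screen over a panel of exposures with multiple-testing control.

    Per-exposure failures are recorded in their battery, never fatal.
    Results are deterministic given inputs, config and seed, and invariant
    to panel ordering (batteries are returned in input order but each is
    computed independently with its own derived seed).
    """
    config = config or ScreenConfig()
    exposures = list(exposure_panel)
    if not exposures:
        raise ValueError("screen needs at least one exposure")
    batteries = [run_single(exp, outcome, ld, config) for exp in exposures]
    n_tests = len(exposures)

    primary_p = {}
    for b in batteries:
        if b.analysable and b.primary is not None:
            primary_p[b.exposure_id] = b.primary.pvalue

    ids = list(primary_p)
    pvals = np.array([primary_p[i] for i in ids], dtype=float)
    if config.correction == "bonferroni":
        threshold = bonferroni_threshold(config.alpha_family, n_tests)
        significant = [i for i, p in zip(ids, pvals) if p <= threshold]
        adjusted = {i: min(1.0, p * n_tests) for i, p in zip(ids, pvals)}
    else:
        threshold = config.alpha_family
        adj = bh_fdr(pvals) if len(pvals) else np.array([])
        adjusted = dict(zip(ids, adj))
        significant = [i for i, a in zip(ids, adj) if a <= config.alpha_family]

    lam, flag, qq_pairs = float("nan"), False, None
    if len(pvals) >= 10:
        lam, flag, qq_pairs = qq_inflation(pvals, config.qq_lambda_bound)

    return ScreenResult(batteries=batteries, correction=config.correction,
                        alpha_family=config.alpha_family, threshold=threshold,
                        n_tests=n_tests, significant_ids=significant,
                        lambda_median=lam, lambda_flag=flag, qq_pairs=qq_pairs,
                        adjusted_p=adjusted)


# ---------------------------------------------------------------------------
# Tabular output

_METHOD_COLS = ("wald", "ivw_fe", "ivw_mre", "egger", "weighted_median",
                "weighted_mode")


def battery_frame(batteries) -> pd.DataFrame:
    """Flatten batteries into one row per exposure (Table-1 shape)."""
    rows = []
    for b in batteries:
        row = {
            "exposure_id": b.exposure_id,
            "outcome_id": b.outcome_id,
            "analysable": b.analysable,
            "rejection_reason": b.rejection_reason,
            "threshold_used": b.threshold_used,
            "n_snp_total": b.n_snp_initial,
            "n_excluded": b.n_excluded,
            "n_pleiotropic_snps": b.n_pleiotropy_filtered,
            "n_radial_outlier_snps": b.n_radial_outliers,
            "n_snp_final": b.n_snp_final,
        }
        for m in _METHOD_COLS:
            res = b.results.get(m)
            row[f"{m}_beta"] = res.beta if res else float("nan")
            row[f"{m}_se"] = res.se if res else float("nan")
            row[f"{m}_p"] = res.pvalue if res else float("nan")
        d = b.diagnostics
        row.update({
            "mean_f": d.mean_f, "cochran_q": d.q, "cochran_q_df": d.q_df,
            "cochran_q_p": d.q_p, "i2_gx": d.i2_gx,
            "egger_intercept_p": d.egger_intercept_p,
            "n_loo_nonsig": d.n_loo_nonsig,
            "config_digest": b.config_digest,
        })
        rows.append(row)
    cols = (["exposure_id", "outcome_id", "analysable", "rejection_reason",
             "threshold_used", "n_snp_total", "n_excluded",
             "n_pleiotropic_snps", "n_radial_outlier_snps", "n_snp_final"]
            + [f"{m}_{s}" for m in _METHOD_COLS for s in ("beta", "se", "p")]
            + ["mean_f", "cochran_q", "cochran_q_df", "cochran_q_p", "i2_gx",
               "egger_intercept_p", "n_loo_nonsig", "config_digest"])
    return pd.DataFrame(rows, columns=cols)


def write_screen_outputs(result: ScreenResult, prefix: str,
                         config: ScreenConfig | None = None) -> dict:
    """Write PREFIX.batteries.tsv, PREFIX.screen.tsv, PREFIX.qq.tsv, PREFIX.log.

    Output is byte-stable: fixed float formatting, no timestamps.
    """
    paths = {"batteries": f"{prefix}.batteries.tsv",
             "screen": f"{prefix}.screen.tsv",
             "qq": f"{prefix}.qq.tsv",
             "log": f"{prefix}.log"}
    battery_frame(result.batteries).to_csv(
        paths["batteries"], sep="\t", index=False, float_format="%.12g")

    rows = []
    for b in result.batteries:
        p = b.primary.pvalue if (b.analysable and b.primary) else float("nan")
        rows.append({
            "exposure_id": b.exposure_id,
            "primary_p": p,
            "adjusted_p": result.adjusted_p.get(b.exposure_id, float("nan")),
            "significant": b.exposure_id in result.significant_ids,
        })
    pd.DataFrame(rows).to_csv(paths["screen"], sep="\t", index=False,
                              float_format="%.12g")

    if result.qq_pairs is not None:
        qq = pd.DataFrame(result.qq_pairs,
                          columns=["expected_neglog10_p", "observed_neglog10_p"])
    else:
        qq = pd.DataFrame(columns=["expected_neglog10_p", "observed_neglog10_p"])
    qq.to_csv(paths["qq"], sep="\t", index=False, float_format="%.12g")

    lines = [
        f"n_tests\t{result.n_tests}",
        f"correction\t{result.correction}",
        f"alpha_family\t{result.alpha_family:.12g}",
        f"threshold\t{result.threshold:.12g}",
        f"lambda_median\t{result.lambda_median:.12g}",
        f"significant\t{','.join(result.significant_ids)}",
    ]
    if config is not None:
        lines.append(f"config_digest\t{config.digest()}")
    for b in result.batteries:
        lines.append(
            f"battery\t{b.exposure_id}\tanalysable={b.analysable}"
            f"\tn_initial={b.n_snp_initial}\tn_final={b.n_snp_final}"
            f"\tpleiotropy={b.n_pleiotropy_filtered}"
            f"\tradial={b.n_radial_outliers}\treason={b.rejection_reason}")
    with open(paths["log"], "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return paths
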