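"""Heterogeneity, pleiotropy and influence diagnostics.

These quantify how far the instrument set departs from the MR validity
assumptions: Cochran's Q (excess heterogeneity ⇒ pleiotropy), I²_GX
(instrument-strength heterogeneity; low values mean MR-Egger is diluted
towards the null), radial-MR per-SNP Q contributions (outlier detection
and removal), leave-one-out refits (single-SNP dominance), and the
screen-level q-q median inflation factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mrscreen.harmonisation import HarmonisedSet
from mrscreen.estimators import ivw


@dataclass
class DiagnosticsReport:
    """The sensitivity block of one exposure's result battery."""

    q: float = float("nan")
    q_df: int = 0
    q_p: float = float("nan")
    i2_gx: float = float("nan")
    mean_f: float = float("nan")
    radial_outliers: list = field(default_factory=list)
    radial_iterations: int = 0
    loo: dict = field(default_factory=dict)
    n_loo_nonsig: int = 0
    egger_intercept_p: float = float("nan")


def cochran_q(pairs: HarmonisedSet, beta_ivw: float):
    """Cochran's Q about a given pooled estimate.

    Q = Σ w_j (Γ̂_j − β γ̂_j)², w_j = σ_yj⁻², df = J − 1, upper-tail
    chi-square p.
    """
    J = len(pairs)
    if J < 2:
        raise ValueError("cochran_q needs at least 2 instruments")
    w = pairs.se_Gamma ** -2.0
    q = float(np.sum(w * (pairs.Gamma - beta_ivw * pairs.gamma) ** 2))
    df = J - 1
    return q, df, float(stats.chi2.sf(q, df))


def i2_gx(pairs: HarmonisedSet) -> float:
    """I²_GX: dispersion of exposure effects relative to their precision.

    Values near 1 mean instrument effects are estimated far more precisely
    than they differ, the regime where MR-Egger regression dilution is
    negligible. Scale-invariant in γ.
    """
    J = len(pairs)
    if J < 2:
        raise ValueError("i2_gx needs at least 2 instruments")
    g, sx = pairs.gamma, pairs.se_gamma
    w = sx ** -2.0
    gbar = float(np.sum(w * g) / np.sum(w))
    q_gx = float(np.sum((g - gbar) ** 2 / sx ** 2))
    if q_gx <= 0:
        return 0.0
    return max(0.0, (q_gx - (J - 1)) / q_gx)


def radial_outliers(pairs: HarmonisedSet, alpha: float = 0.05,
                    iterate: bool = True, bonferroni: bool = False):
    """Radial-MR outlier detection and (optionally iterated) removal.

    The radial fit regresses Γ̂/σ_y on γ̂/σ_y through the origin (slope
    identical to IVW); each SNP's contribution Q_j is compared to
    chi-square(1) and SNPs with upper-tail p < alpha are flagged. Removal
    is worst-first: each iteration drops only the largest flagged Q_j and
    refits, because a gross outlier drags the slope and can make sound
    instruments look discrepant. With ``iterate`` this repeats until no
    SNP is flagged or removal would leave fewer than 3 instruments.
    ``bonferroni`` tests each SNP at alpha/J instead.

    Returns (outlier ids in removal order, iterations, surviving pairs).
    """
    if len(pairs) < 3:
        raise ValueError("radial_outliers needs at least 3 instruments")
    current = pairs
    removed: list[str] = []
    iterations = 0
    while True:
        g, G, sy = current.gamma, current.Gamma, current.se_Gamma
        w = sy ** -2.0
        beta = float(np.sum(w * g * G) / np.sum(w * g * g))
        q_j = w * (G - beta * g) ** 2
        thr = alpha / len(current) if bonferroni else alpha
        p_j = stats.chi2.sf(q_j, 1)
        if not np.any(p_j < thr):
            break
        if len(current) - 1 < 3:
            break  # refuse to shrink below the minimum analysable set
        worst = current.variant_ids[int(np.argmax(q_j))]
        removed.append(worst)
        current = current.drop([worst])
        iterations += 1
        if not iterate:
            break
    return removed, iterations, current


def leave_one_out(pairs: HarmonisedSet, sig_level: float = 0.05):
    """Leave-one-out IVW refits; counts refits losing significance.

    Each instrument is removed in turn and the multiplicative
    random-effects IVW recomputed on the remainder. A large
    ``n_loo_nonsig`` means the headline result hinges on few SNPs.
    Returns (mapping variant_id -> (beta, se, p), n_loo_nonsig).
    """
    if len(pairs) < 3:
        raise ValueError("leave_one_out needs at least 3 instruments")
    loo = {}
    n_nonsig = 0
    for vid in pairs.variant_ids:
        res = ivw(pairs.drop([vid]), mode="multiplicative_random")
        loo[vid] = (res.beta, res.se, res.pvalue)
        if res.pvalue > sig_level:
            n_nonsig += 1
    return loo, n_nonsig


#: Median of the chi-square(1) distribution; the q-q reference point.
#: Computed via isf so that a screen of p = 0.5 gives lambda = 1 exactly.
_CHI2_1_MEDIAN = float(stats.chi2.isf(0.5, 1))


def qq_inflation(pvalues, lambda_bound: float = 1.1):
    """Median-based q-q inflation factor over a screen's p-values.

    λ_median = median(χ²₁-quantile(1 − p)) / median(χ²₁). Under a well
    calibrated screen λ ≈ 1; the flag is raised above ``lambda_bound``.
    Also returns (expected, observed) −log10 p quantile pairs for plotting.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size < 10:
        raise ValueError("qq_inflation needs at least 10 p-values")
    chi = stats.chi2.isf(p, 1)
    lam = float(np.median(chi) / _CHI2_1_MEDIAN)
    obs = np.sort(p)
    exp = (np.arange(1, p.size + 1) - 0.5) / p.size
    quantile_pairs = np.column_stack([-np.log10(exp), -np.log10(obs)])
    return lam, bool(lam > lambda_bound), quantile_pairs
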