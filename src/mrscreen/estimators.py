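"""The five causal-effect estimators of the MR battery.

All estimators consume a :class:`~mrscreen.harmonisation.HarmonisedSet`
with J instruments carrying exposure effects γ̂_j (SE σ_xj) and outcome
effects Γ̂_j (SE σ_yj) on a shared allele. Weights throughout are the
first-order inverse-variance weights w_j = σ_yj⁻² (NOME: exposure effects
treated as known for weighting).

* Wald ratio — Γ̂/γ̂ for a single instrument (delta-method SE).
* IVW — weights regression of Γ̂ on γ̂ through the origin; the
  multiplicative random-effects variant scales the SE by
  sqrt(max(1, Q/(J−1))) so overdispersion widens, never shrinks, intervals.
* MR-Egger — same regression with a free intercept after orienting all
  γ̂ ≥ 0; the intercept estimates the average directional pleiotropic
  effect, inference on t with J−2 df.
* Weighted median — consistent when ≥ 50% of the weight is on valid
  instruments; SE by seeded parametric bootstrap.
* Weighted mode — consistent when the largest cluster of per-SNP ratios is
  valid; Gaussian-kernel weighted density argmax, modified Silverman
  bandwidth, bootstrap SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mrscreen.harmonisation import HarmonisedPair, HarmonisedSet

METHODS = ("wald", "ivw_fe", "ivw_mre", "egger", "weighted_median",
           "weighted_mode")


class MethodUnavailable(Exception):
    """Typed refusal: too few instruments for this estimator."""

    def __init__(self, method: str, n_snp: int, required: int):
        self.method, self.n_snp, self.required = method, n_snp, required
        super().__init__(f"{method} needs >= {required} instruments, got {n_snp}")


@dataclass(frozen=True)
class EstimatorResult:
    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def _norm_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def ratio_estimates(pairs: HarmonisedSet, second_order: bool = False):
    """Per-SNP ratio estimates r_j = Γ̂_j/γ̂_j and their SEs.

    First-order delta method by default: se(r_j) = σ_yj/|γ̂_j|. The
    second-order option adds the exposure-noise term
    Γ̂²σ_xj²/γ̂⁴ and matters only for weak instruments.
    """
    gamma = pairs.gamma
    zero = np.flatnonzero(gamma == 0)
    if zero.size:
        raise ValueError(
            f"zero exposure effect for {pairs.variant_ids[zero[0]]}: "
            "ratio undefined")
    r = pairs.Gamma / gamma
    if second_order:
        se = np.sqrt(pairs.se_Gamma ** 2 / gamma ** 2
                     + pairs.Gamma ** 2 * pairs.se_gamma ** 2 / gamma ** 4)
    else:
        se = pairs.se_Gamma / np.abs(gamma)
    return r, se


def wald_ratio(pairs) -> EstimatorResult:
    """Single-instrument causal estimate (delta-method SE, normal p)."""
    if isinstance(pairs, HarmonisedPair):
        pairs = HarmonisedSet("", "", [pairs])
    if len(pairs) != 1:
        raise ValueError(f"wald_ratio needs exactly 1 pair, got {len(pairs)}; "
                         "use ivw for multiple instruments")
    r, se = ratio_estimates(pairs)
    beta, se = float(r[0]), float(se[0])
    return EstimatorResult("wald", beta, se, _norm_p(beta / se), 1)


def ivw(pairs: HarmonisedSet, mode: str = "multiplicative_random",
        truncate_phi: bool = True) -> EstimatorResult:
    """Inverse-variance weighted estimate (fixed or mult. random effects).

    β̂ = Σ w γ̂ Γ̂ / Σ w γ̂² with w = σ_y⁻²; fixed-effect
    SE = (Σ w γ̂²)^{-1/2}. In multiplicative random-effects mode the SE is
    scaled by sqrt(φ), φ = max(1, Q/(J−1)); underdispersion never shrinks
    the SE unless ``truncate_phi`` is disabled.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown ivw mode {mode!r}")
    J = len(pairs)
    if J == 0:
        raise ValueError("empty harmonised set")
    if J == 1:
        res = wald_ratio(pairs.pairs[0])
        method = "ivw_fe" if mode == "fixed" else "ivw_mre"
        return EstimatorResult(method, res.beta, res.se, res.pvalue, 1,
                               extras={"phi": 1.0, "q": 0.0, "delegated": "wald"})
    g, G, sy = pairs.gamma, pairs.Gamma, pairs.se_Gamma
    w = sy ** -2.0
    denom = float(np.sum(w * g * g))
    if denom == 0:
        raise ValueError("all exposure effects are zero; IVW undefined")
    beta = float(np.sum(w * g * G)) / denom
    se_fixed = denom ** -0.5
    q = float(np.sum(w * (G - beta * g) ** 2))
    phi = q / (J - 1)
    if truncate_phi:
        phi = max(1.0, phi)
    if mode == "fixed":
        method, se = "ivw_fe", se_fixed
        extras = {"q": q}
    else:
        method, se = "ivw_mre", se_fixed * np.sqrt(phi)
        extras = {"q": q, "phi": phi}
    return EstimatorResult(method, beta, float(se), _norm_p(beta / se), J,
                           extras=extras)


def egger(pairs: HarmonisedSet, truncate_phi: bool = True) -> EstimatorResult:
    """MR-Egger regression: slope = causal effect, intercept = pleiotropy.

    Pairs are first oriented so every exposure effect is non-negative (both
    effects sign-flipped together); without this the intercept is not
    identified. Weighted least squares with w = σ_y⁻²; both SEs scaled by
    sqrt(max(1, Q_egger/(J−2))); p-values from t with J−2 df.
    """
    J = len(pairs)
    if J < 3:
        raise MethodUnavailable("egger", J, 3)
    g, G, sy = pairs.gamma, pairs.Gamma, pairs.se_Gamma
    s = np.where(g < 0, -1.0, 1.0)
    g, G = s * g, s * G
    w = sy ** -2.0
    # Closed-form 2x2 WLS normal equations.
    sw, swx = float(np.sum(w)), float(np.sum(w * g))
    swxx = float(np.sum(w * g * g))
    swy, swxy = float(np.sum(w * G)), float(np.sum(w * g * G))
    det = sw * swxx - swx * swx
    if det <= 0:
        raise ValueError("degenerate design: exposure effects identical")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = G - intercept - slope * g
    q_e = float(np.sum(w * resid ** 2))
    phi = q_e / (J - 2)
    if truncate_phi:
        phi = max(1.0, phi)
    se_slope = np.sqrt(phi * sw / det)
    se_int = np.sqrt(phi * swxx / det)
    df = J - 2
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), df))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), df))
    return EstimatorResult(
        "egger", float(slope), float(se_slope), p_slope, J,
        extras={"egger_intercept": float(intercept),
                "egger_intercept_se": float(se_int),
                "egger_intercept_p": p_int,
                "phi": float(phi), "q": q_e})


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted empirical 0.5-quantile with midpoint cumulative weights."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, v))


def _bootstrap_draws(pairs: HarmonisedSet, n_boot: int, seed: int):
    """Parametric bootstrap draws of (γ̂, Γ̂) under their normal errors."""
    rng = np.random.default_rng(seed)
    J = len(pairs)
    g = pairs.gamma + pairs.se_gamma * rng.standard_normal((n_boot, J))
    G = pairs.Gamma + pairs.se_Gamma * rng.standard_normal((n_boot, J))
    return g, G


def weighted_median(pairs: HarmonisedSet, n_boot: int = 1000,
                    seed: int = 0) -> EstimatorResult:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-SNP ratios are weighted by their inverse variance; the estimate is
    the weighted empirical median (linear interpolation at probability 0.5
    on midpoint cumulative weights). Identical seed and inputs give
    bit-identical SEs.
    """
    J = len(pairs)
    if J < 3:
        raise MethodUnavailable("weighted_median", J, 3)
    r, se_r = ratio_estimates(pairs)
    beta = _weighted_median(r, se_r ** -2.0)
    g_b, G_b = _bootstrap_draws(pairs, n_boot, seed)
    ests = np.empty(n_boot)
    sy = pairs.se_Gamma
    for b in range(n_boot):
        gb = g_b[b]
        gb = np.where(gb == 0, np.finfo(float).tiny, gb)
        rb = G_b[b] / gb
        wb = (sy / np.abs(gb)) ** -2.0
        ests[b] = _weighted_median(rb, wb)
    se = float(np.std(ests, ddof=1))
    p = _norm_p(beta / se) if se > 0 else 1.0
    return EstimatorResult("weighted_median", float(beta), se, p, J,
                           extras={"n_boot": n_boot, "seed": seed})


def _silverman_bandwidth(r: np.ndarray) -> float:
    """Modified Silverman rule: 0.9·min(sd, 1.4826·MAD)·J^{-1/5}."""
    sd = float(np.std(r, ddof=1))
    mad = 1.4826 * float(np.median(np.abs(r - np.median(r))))
    s = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    return 0.9 * s * len(r) ** (-1 / 5)


def _weighted_mode(r: np.ndarray, w: np.ndarray, bandwidth_factor: float,
                   grid_size: int = 512) -> float:
    """Argmax of the Gaussian-kernel weighted density of the ratios."""
    h = bandwidth_factor * _silverman_bandwidth(r)
    if h <= 0:  # all ratios (numerically) identical
        return float(np.median(r))
    lo, hi = float(r.min()) - 3 * h, float(r.max()) + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ w
    return float(grid[int(np.argmax(dens))])


def weighted_mode(pairs: HarmonisedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0,
                  grid_size: int = 512) -> EstimatorResult:
    """Weighted-mode estimator (simple-mode weighting, NOME assumption).

    The estimate is the mode of the inverse-variance-weighted kernel
    density of per-SNP ratios; bandwidth is ``bandwidth_factor`` times the
    modified Silverman rule. SE by the same seeded parametric bootstrap as
    the weighted median.
    """
    J = len(pairs)
    if J < 3:
        raise MethodUnavailable("weighted_mode", J, 3)
    r, se_r = ratio_estimates(pairs)
    w = se_r ** -2.0
    beta = _weighted_mode(r, w / w.sum(), bandwidth_factor, grid_size)
    g_b, G_b = _bootstrap_draws(pairs, n_boot, seed)
    sy = pairs.se_Gamma
    ests = np.empty(n_boot)
    for b in range(n_boot):
        gb = g_b[b]
        gb = np.where(gb == 0, np.finfo(float).tiny, gb)
        rb = G_b[b] / gb
        wb = (sy / np.abs(gb)) ** -2.0
        ests[b] = _weighted_mode(rb, wb / wb.sum(), bandwidth_factor,
                                 grid_size)
    se = float(np.std(ests, ddof=1))
    p = _norm_p(beta / se) if se > 0 else 1.0
    return EstimatorResult("weighted_mode", float(beta), se, p, J,
                           extras={"n_boot": n_boot, "seed": seed,
                                   "bandwidth_factor": bandwidth_factor})
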