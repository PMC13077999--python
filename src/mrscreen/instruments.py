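"""Instrument selection: p-value ladder, LD clumping, proxies, strength.

The screen selects, per exposure, an LD-independent set of strongly
associated SNPs. Selection walks a p-value ladder from the most stringent
threshold (default 5e-8) towards the most permissive (5e-6) and stops at
the first rung whose post-clump instrument count reaches the minimum
(default 5); exposures that never reach it are rejected, not analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mrscreen.sumstats_io import LDReference, SummaryStatRecord, SummaryStatSet

#: Default p-value ladder; endpoints are the conventional genome-wide and
#: relaxed instrument thresholds.
DEFAULT_LADDER = (5e-8, 1e-7, 5e-7, 1e-6, 5e-6)


class ConfigurationError(ValueError):
    """Operation refused because of an incompatible configuration."""


@dataclass
class InstrumentSet:
    """LD-independent instruments for one exposure, with provenance."""

    exposure_id: str
    variants: list[SummaryStatRecord]
    threshold_used: float
    clump_r2: float
    clump_window_bp: int
    proxies_used: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]


@dataclass
class Rejection:
    """Exposure failed the minimum-instrument rule at every ladder rung."""

    exposure_id: str
    best_count: int
    min_instruments: int
    reason: str = "too_few_independent_instruments"


def _within_window(a: SummaryStatRecord, b: SummaryStatRecord,
                   window_bp: int) -> bool:
    return (a.chromosome == b.chromosome
            and abs(a.position - b.position) <= window_bp)


def certify_independence(records: list[SummaryStatRecord], ld: LDReference,
                         r2_threshold: float, window_bp: int) -> None:
    """Assert pairwise r² < threshold for all retained pairs in-window.

    Run after every clump; a violation is a bug, hence AssertionError.
    """
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            if _within_window(a, b, window_bp):
                r2 = ld.r2(a.variant_id, b.variant_id)
                assert r2 < r2_threshold, (
                    f"clump certification failed: {a.variant_id}/{b.variant_id} "
                    f"r²={r2} ≥ {r2_threshold}")


def clump(candidates, ld: LDReference, r2_threshold: float = 0.001,
          window_bp: int = 10_000_000) -> list[SummaryStatRecord]:
    """Greedy LD clumping: keep the lowest-p SNP, drop correlated neighbours.

    Ties in p are broken by (chromosome, position, variant_id) so the output
    is invariant to input ordering. A pair only competes when it lies within
    ``window_bp`` on the same chromosome AND r² ≥ ``r2_threshold``; absent LD
    entries count as r = 0.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must be in (0, 1]")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    pool = sorted(candidates,
                  key=lambda r: (r.pvalue, r.chromosome, r.position, r.variant_id))
    retained: list[SummaryStatRecord] = []
    while pool:
        best = pool.pop(0)
        retained.append(best)
        pool = [r for r in pool
                if not (_within_window(best, r, window_bp)
                        and ld.r2(best.variant_id, r.variant_id) >= r2_threshold)]
    certify_independence(retained, ld, r2_threshold, window_bp)
    return retained


def select_threshold(exposure: SummaryStatSet, ld: LDReference,
                     ladder=DEFAULT_LADDER, min_instruments: int = 5,
                     clump_r2: float = 0.001,
                     window_bp: int = 10_000_000) -> InstrumentSet | Rejection:
    """Pick instruments at the most stringent ladder rung that yields enough.

    Walks the strictly increasing ladder; the first rung whose post-clump
    count reaches ``min_instruments`` wins. Relaxing the ladder can never
    reduce the count (monotone), so no rung after a success is considered.
    """
    ladder = tuple(ladder)
    if any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("ladder must be strictly increasing")
    if min_instruments < 1:
        raise ValueError("min_instruments must be >= 1")
    best_count = 0
    for thr in ladder:
        cands = [r for r in exposure if r.pvalue <= thr]
        kept = clump(cands, ld, r2_threshold=clump_r2, window_bp=window_bp)
        best_count = max(best_count, len(kept))
        if len(kept) >= min_instruments:
            return InstrumentSet(exposure_id=exposure.trait_id, variants=kept,
                                 threshold_used=thr, clump_r2=clump_r2,
                                 clump_window_bp=window_bp)
    return Rejection(exposure_id=exposure.trait_id, best_count=best_count,
                     min_instruments=min_instruments)


@dataclass(frozen=True)
class ProxyResult:
    record: SummaryStatRecord
    r: float

    @property
    def r2(self) -> float:
        return self.r ** 2


def find_proxy(missing_id: str, outcome: SummaryStatSet, ld: LDReference,
               r2_min: float = 0.9) -> ProxyResult | None:
    """Best LD proxy present in the outcome GWAS, or None.

    Requires a signed LD table: the sign of r is what lets harmonisation map
    the proxy's alleles back onto the instrument.
    """
    if not ld.signed:
        raise ConfigurationError(
            "proxy search needs signed LD correlations; the loaded table is r²")
    best: ProxyResult | None = None
    for vid, r in ld.partners(missing_id).items():
        if r * r <= r2_min:
            continue
        rec = outcome.get(vid)
        if rec is None:
            continue
        if best is None or r * r > best.r2:
            best = ProxyResult(record=rec, r=r)
    return best


@dataclass
class FStatistics:
    per_snp: dict[str, float]
    mean_f: float
    weak: bool   # mean F <= 10: >10% weak-instrument bias plausible


def f_statistics(instruments) -> FStatistics:
    """Per-SNP F = (beta/se)² and the arithmetic mean F.

    The squared z-score approximates the first-stage F when each SNP
    explains little variance; F > 10 is the conventional adequacy bar.
    """
    records = getattr(instruments, "variants", instruments)
    per = {r.variant_id: (r.beta / r.se) ** 2 for r in records}
    mean_f = float(np.mean(list(per.values()))) if per else float("nan")
    return FStatistics(per_snp=per, mean_f=mean_f,
                       weak=(not per) or mean_f <= 10)


def pleiotropy_p_filter(pairs):
    """Drop instruments more strongly associated with the outcome.

    A SNP whose outcome p-value is strictly smaller than its exposure
    p-value likely acts on the outcome through a pathway other than the
    exposure; it is removed before estimation. Order is preserved.
    Returns (filtered HarmonisedSet, removed variant ids).
    """
    from mrscreen.harmonisation import HarmonisedSet

    removed = [p.variant_id for p in pairs if p.p_Gamma < p.p_gamma]
    kept = [p for p in pairs if p.p_Gamma >= p.p_gamma]
    return (HarmonisedSet(pairs.exposure_id, pairs.outcome_id, kept,
                          pairs.exclusions), removed)
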