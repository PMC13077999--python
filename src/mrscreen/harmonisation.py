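"""Allele harmonisation of exposure and outcome associations.

Two-sample MR requires the exposure effect (γ) and outcome effect (Γ) of
each instrument to refer to the same effect allele. Outcome records may be
reported with alleles swapped, on the opposite strand, or both; palindromic
variants (A/T, C/G) cannot be resolved from alleles alone and are resolved
by minor-allele matching when the frequency is informative, or excluded
when the minor allele frequency exceeds ``maf_limit`` (default 0.42) or is
missing on either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mrscreen.sumstats_io import LDReference, SummaryStatRecord, SummaryStatSet

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Exclusion reasons a harmonised set may record.
EXCLUSION_REASONS = (
    "palindromic_ambiguous",
    "allele_mismatch",
    "missing_in_outcome_no_proxy",
)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T or C/G pairs: indistinguishable from their strand complement."""
    return COMPLEMENT[effect_allele] == other_allele


@dataclass(frozen=True)
class HarmonisedPair:
    """One instrument with exposure and outcome effects on a shared allele."""

    variant_id: str
    gamma: float          # exposure beta, aligned
    se_gamma: float
    p_gamma: float
    Gamma: float          # outcome beta, aligned
    se_Gamma: float
    p_Gamma: float
    eaf: float | None = None
    flags: frozenset = frozenset()

    def __post_init__(self):
        if not (self.se_gamma > 0 and self.se_Gamma > 0):
            raise ValueError(f"non-positive SE for {self.variant_id}")


@dataclass(frozen=True)
class Exclusion:
    variant_id: str
    reason: str

    def __post_init__(self):
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")


class HarmonisedSet:
    """Analysis-ready paired set for one exposure against one outcome."""

    def __init__(self, exposure_id: str, outcome_id: str,
                 pairs: list[HarmonisedPair] | None = None,
                 exclusions: dict[str, str] | None = None):
        self.exposure_id = exposure_id
        self.outcome_id = outcome_id
        self.pairs: list[HarmonisedPair] = []
        self.exclusions: dict[str, str] = dict(exclusions or {})
        seen = set()
        for p in pairs or []:
            if p.variant_id in seen:
                raise ValueError(f"duplicate variant {p.variant_id} in harmonised set")
            seen.add(p.variant_id)
            self.pairs.append(p)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def variant_ids(self) -> list[str]:
        return [p.variant_id for p in self.pairs]

    # --- array views used by the estimators -------------------------------
    def _arr(self, name: str) -> np.ndarray:
        return np.array([getattr(p, name) for p in self.pairs], dtype=float)

    @property
    def gamma(self) -> np.ndarray:
        return self._arr("gamma")

    @property
    def se_gamma(self) -> np.ndarray:
        return self._arr("se_gamma")

    @property
    def p_gamma(self) -> np.ndarray:
        return self._arr("p_gamma")

    @property
    def Gamma(self) -> np.ndarray:
        return self._arr("Gamma")

    @property
    def se_Gamma(self) -> np.ndarray:
        return self._arr("se_Gamma")

    @property
    def p_Gamma(self) -> np.ndarray:
        return self._arr("p_Gamma")

    def subset(self, keep_ids) -> "HarmonisedSet":
        keep = set(keep_ids)
        return HarmonisedSet(self.exposure_id, self.outcome_id,
                             [p for p in self.pairs if p.variant_id in keep],
                             self.exclusions)

    def drop(self, drop_ids) -> "HarmonisedSet":
        dropped = set(drop_ids)
        return HarmonisedSet(self.exposure_id, self.outcome_id,
                             [p for p in self.pairs if p.variant_id not in dropped],
                             self.exclusions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            d = {k: getattr(p, k) for k in
                 ("variant_id", "gamma", "se_gamma", "p_gamma",
                  "Gamma", "se_Gamma", "p_Gamma", "eaf")}
            d["flags"] = ";".join(sorted(p.flags))
            rows.append(d)
        return pd.DataFrame(rows, columns=["variant_id", "gamma", "se_gamma",
                                           "p_gamma", "Gamma", "se_Gamma",
                                           "p_Gamma", "eaf", "flags"])


def _pair_from(exp: SummaryStatRecord, out: SummaryStatRecord,
               flip: bool, flags: set) -> HarmonisedPair:
    Gamma = -out.beta if flip else out.beta
    if flip:
        flags = flags | {"flipped"}
    # Aligned frequency: the exposure's where available, else the outcome's
    # mapped onto the shared effect allele.
    if exp.eaf is not None:
        eaf = exp.eaf
    elif out.eaf is not None:
        eaf = 1.0 - out.eaf if flip else out.eaf
    else:
        eaf = None
    return HarmonisedPair(
        variant_id=exp.variant_id,
        gamma=exp.beta, se_gamma=exp.se, p_gamma=exp.pvalue,
        Gamma=Gamma, se_Gamma=out.se, p_Gamma=out.pvalue,
        eaf=eaf, flags=frozenset(flags))


def harmonise_pair(exp: SummaryStatRecord, out: SummaryStatRecord,
                   maf_limit: float = 0.42) -> HarmonisedPair | Exclusion:
    """Align one outcome record to the exposure record's effect allele.

    Returns a :class:`HarmonisedPair`, or a typed :class:`Exclusion` for
    ambiguous palindromes and irreconcilable allele configurations; no
    failure is silent.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    ea_o, oa_o = out.effect_allele, out.other_allele

    if is_palindromic(ea, oa):
        # Letters cannot distinguish swap from strand flip; alleles must at
        # least be the same unordered pair (== its own complement pair).
        if {ea_o, oa_o} != {ea, oa}:
            return Exclusion(exp.variant_id, "allele_mismatch")
        if exp.eaf is None or out.eaf is None:
            return Exclusion(exp.variant_id, "palindromic_ambiguous")
        maf_exp = min(exp.eaf, 1 - exp.eaf)
        maf_out = min(out.eaf, 1 - out.eaf)
        if maf_exp > maf_limit or maf_out > maf_limit:
            return Exclusion(exp.variant_id, "palindromic_ambiguous")
        # Minor-allele matching: the exposure effect allele is minor/major;
        # align the outcome effect to whichever outcome allele matches that
        # frequency side.
        same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
        return _pair_from(exp, out, flip=not same_side,
                          flags={"palindromic_kept"})

    if (ea_o, oa_o) == (ea, oa):
        return _pair_from(exp, out, flip=False, flags=set())
    if (ea_o, oa_o) == (oa, ea):
        return _pair_from(exp, out, flip=True, flags=set())

    # Strand-complement resolution for non-palindromic mismatches.
    cea_o, coa_o = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
    if (cea_o, coa_o) == (ea, oa):
        return _pair_from(exp, out, flip=False, flags={"strand_complement"})
    if (cea_o, coa_o) == (oa, ea):
        return _pair_from(exp, out, flip=True, flags={"strand_complement"})

    return Exclusion(exp.variant_id, "allele_mismatch")


def harmonise_set(instruments, exposure: SummaryStatSet,
                  outcome: SummaryStatSet, ld: LDReference,
                  maf_limit: float = 0.42,
                  proxy_r2_min: float = 0.9) -> HarmonisedSet:
    """Harmonise every instrument against the outcome GWAS.

    Instruments missing from the outcome are substituted by their best LD
    proxy (|r|² > ``proxy_r2_min``) with the outcome effect multiplied by
    sign(r); instruments with no proxy are excluded with reason
    ``missing_in_outcome_no_proxy``. |instruments| = |pairs| + |exclusions|
    always holds.
    """
    from mrscreen.instruments import find_proxy  # late import: cycle

    pairs: list[HarmonisedPair] = []
    exclusions: dict[str, str] = {}
    for inst in instruments.variants:
        out_rec = outcome.get(inst.variant_id)
        if out_rec is not None:
            result = harmonise_pair(inst, out_rec, maf_limit=maf_limit)
            if isinstance(result, Exclusion):
                exclusions[result.variant_id] = result.reason
            else:
                pairs.append(result)
            continue
        proxy = find_proxy(inst.variant_id, outcome, ld, r2_min=proxy_r2_min)
        if proxy is None:
            exclusions[inst.variant_id] = "missing_in_outcome_no_proxy"
            continue
        flags = {"proxy"}
        if proxy.r < 0:
            flags.add("proxy_sign_flipped")
        pairs.append(HarmonisedPair(
            variant_id=inst.variant_id,
            gamma=inst.beta, se_gamma=inst.se, p_gamma=inst.pvalue,
            Gamma=float(np.sign(proxy.r)) * proxy.record.beta,
            se_Gamma=proxy.record.se, p_Gamma=proxy.record.pvalue,
            eaf=inst.eaf, flags=frozenset(flags)))
    hset = HarmonisedSet(instruments.exposure_id, outcome.trait_id,
                         pairs, exclusions)
    assert len(instruments.variants) == len(hset.pairs) + len(hset.exclusions)
    return hset
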