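import numpy as np
import pytest

from mrscreen.harmonisation import HarmonisedPair, HarmonisedSet
from mrscreen.sumstats_io import SummaryStatRecord


def make_record(vid="rs1", ea="A", oa="G", beta=0.1, se=0.02, p=None,
                chrom="1", pos=1000, eaf=0.3, n=8000.0):
    """Build a valid record; p defaults to the value implied by beta/se."""
    from scipy import stats
    if p is None:
        p = float(2 * stats.norm.sf(abs(beta) / se))
    return SummaryStatRecord(variant_id=vid, effect_allele=ea, other_allele=oa,
                             beta=beta, se=se, pvalue=p, chromosome=chrom,
                             position=pos, eaf=eaf, n=n)


def make_hset(gamma, se_gamma, Gamma, se_Gamma, p_gamma=None, p_Gamma=None,
              exposure_id="exp", outcome_id="out"):
    """HarmonisedSet from parallel arrays; p-values implied unless given."""
    from scipy import stats
    gamma = np.asarray(gamma, dtype=float)
    se_gamma = np.broadcast_to(np.asarray(se_gamma, dtype=float), gamma.shape)
    Gamma = np.asarray(Gamma, dtype=float)
    se_Gamma = np.broadcast_to(np.asarray(se_Gamma, dtype=float), gamma.shape)
    if p_gamma is None:
        p_gamma = 2 * stats.norm.sf(np.abs(gamma) / se_gamma)
    if p_Gamma is None:
        p_Gamma = 2 * stats.norm.sf(np.abs(Gamma) / se_Gamma)
    pairs = [HarmonisedPair(variant_id=f"rs{j}", gamma=float(gamma[j]),
                            se_gamma=float(se_gamma[j]),
                            p_gamma=float(np.clip(p_gamma[j], 1e-300, 1.0)),
                            Gamma=float(Gamma[j]), se_Gamma=float(se_Gamma[j]),
                            p_Gamma=float(np.clip(p_Gamma[j], 1e-300, 1.0)))
             for j in range(len(gamma))]
    return HarmonisedSet(exposure_id, outcome_id, pairs)


def random_hset(rng, J=8, beta=0.3):
    """Random but well-conditioned harmonised set for oracle comparisons."""
    gamma = rng.uniform(0.05, 0.5, J) * rng.choice([-1.0, 1.0], J)
    se_gamma = rng.uniform(0.005, 0.03, J)
    se_Gamma = rng.uniform(0.005, 0.05, J)
    Gamma = beta * gamma + rng.normal(0, se_Gamma)
    return make_hset(gamma, se_gamma, Gamma, se_Gamma)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
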