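"""Hardy-Weinberg equilibrium tests for biallelic genotype counts.

Under random mating a biallelic locus with minor-allele frequency ``q``
yields genotype proportions ``q**2 : 2q(1-q) : (1-q)**2``.  Departure in
control arms is the standard red flag for genotyping error in case-control
genetics, so every study arm is screened before meta-analysis.

The default test is the 1-df Pearson chi-square on observed vs expected
genotype counts with the allele frequency estimated from the data and no
continuity correction.  An exact test (conditional on the observed allele
counts; Wigginton, Cutler & Abecasis 2005) is available for sparse tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .studies import GenotypeCounts

__all__ = ["HWEResult", "hwe_chisq", "hwe_exact"]


@dataclass(frozen=True)
class HWEResult:
    """Result of a Hardy-Weinberg test on one study arm.

    ``chi2`` is the Pearson statistic (0 for the exact test and degenerate
    inputs), ``df`` its degrees of freedom, ``p`` the two-sided tail
    probability, ``maf`` the minor-allele frequency estimate and
    ``degenerate`` flags monomorphic input (only one allele observed), for
    which no test is possible and ``p`` is reported as 1.
    """

    chi2: float
    df: int
    p: float
    maf: float
    degenerate: bool = False


def hwe_chisq(counts: GenotypeCounts) -> HWEResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    Expected counts are ``n*q**2``, ``2*n*q*(1-q)``, ``n*(1-q)**2`` with
    ``q`` the observed minor-allele frequency.  Monomorphic arms (q of 0
    or 1) are flagged degenerate with chi2 = 0 and p = 1.
    """
    n = counts.n
    q = counts.maf
    if q == 0.0 or q == 1.0:
        return HWEResult(chi2=0.0, df=1, p=1.0, maf=q, degenerate=True)
    expected = (n * q * q, 2 * n * q * (1 - q), n * (1 - q) * (1 - q))
    observed = (counts.gg, counts.ga, counts.aa)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(chi2=float(chi2), df=1, p=p, maf=q)


def hwe_exact(counts: GenotypeCounts) -> HWEResult:
    """Exact Hardy-Weinberg test conditional on the observed allele counts.

    Sums the probabilities of all heterozygote counts compatible with the
    observed allele totals that are no more likely than the observed one
    (the SNP-HWE formulation of Wigginton et al. 2005).  Preferred over the
    chi-square for very sparse genotype classes; not the package default.
    """
    n = counts.n
    n_minor = counts.minor_allele_count
    if n_minor == 0 or n_minor == 2 * n:
        return HWEResult(chi2=0.0, df=1, p=1.0, maf=counts.maf, degenerate=True)

    # log-probability of each feasible heterozygote count, conditional on
    # the allele margin: P(het) ∝ n! / (gg! ga! aa!) * 2**ga
    rare = min(n_minor, 2 * n - n_minor)
    feasible = range(rare % 2, rare + 1, 2)
    logs = {}
    for het in feasible:
        gg = (rare - het) // 2
        aa = n - gg - het
        logs[het] = (
            het * math.log(2.0)
            - math.lgamma(gg + 1) - math.lgamma(het + 1) - math.lgamma(aa + 1)
        )
    m = max(logs.values())
    total = sum(math.exp(v - m) for v in logs.values())
    probs = {het: math.exp(v - m) / total for het, v in logs.items()}
    p = sum(pr for pr in probs.values() if pr <= probs[counts.ga] * (1 + 1e-12))
    return HWEResult(chi2=0.0, df=1, p=min(1.0, float(p)), maf=counts.maf)
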