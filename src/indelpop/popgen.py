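"""Single-locus summary statistics for a biallelic indel.

Given genotype counts (DD, ID, II) for a population, this module computes
allele and genotype frequencies, observed and expected heterozygosity,
effective allele number, polymorphism information content, and Hardy-Weinberg
equilibrium tests (exact conditional and 1-df chi-square).

Conventions for a fixed locus (one allele absent): He = PIC = 0, Ne = 1, and
both HWE p-values are 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .datamodel import GenotypePanel, ValidationError

__all__ = [
    "LocusSummary", "allele_freqs", "observed_het", "expected_het",
    "effective_alleles", "pic_biallelic", "hwe_exact", "hwe_chisq",
    "summarize", "summarize_from_freq", "classify_polymorphism",
]


@dataclass(frozen=True)
class LocusSummary:
    """One population's row of locus statistics.

    All frequencies are carried at full precision; rounding is applied only
    when rendering reports.
    """

    population: str
    n: int
    freq_DD: float
    freq_ID: float
    freq_II: float
    p_D: float
    p_I: float
    Ho: float
    He: float
    Ne: float
    PIC: float
    hwe_p_exact: float
    hwe_p_chisq: float


def _check_panel(panel: GenotypePanel) -> None:
    if panel.n <= 0:
        raise ValidationError(f"panel {panel.population!r} has no genotyped individuals")


def allele_freqs(panel: GenotypePanel) -> tuple[float, float]:
    """Allele frequencies (p_D, p_I) by direct gene counting.

    p_D = (2 n_DD + n_ID) / 2n; p_I is its complement.
    """
    _check_panel(panel)
    p_d = (2 * panel.n_DD + panel.n_ID) / (2 * panel.n)
    return p_d, 1.0 - p_d


def observed_het(panel: GenotypePanel) -> float:
    """Observed heterozygosity: the heterozygote proportion n_ID / n."""
    _check_panel(panel)
    return panel.n_ID / panel.n


def expected_het(p_d: float) -> float:
    """Expected heterozygosity 2pq under Hardy-Weinberg proportions."""
    if not 0.0 <= p_d <= 1.0:
        raise ValueError(f"allele frequency {p_d} outside [0, 1]")
    return 2.0 * p_d * (1.0 - p_d)


def effective_alleles(p_d: float) -> float:
    """Effective allele number Ne = 1 / (p^2 + q^2).

    Ranges from 1 (fixed) to 2 (p = 0.5) for a biallelic locus.
    """
    if not 0.0 <= p_d <= 1.0:
        raise ValueError(f"allele frequency {p_d} outside [0, 1]")
    q = 1.0 - p_d
    return 1.0 / (p_d * p_d + q * q)


def pic_biallelic(p_d: float) -> float:
    """Polymorphism information content, biallelic Botstein form.

    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2; maximal 0.375 at p = 0.5.
    """
    if not 0.0 <= p_d <= 1.0:
        raise ValueError(f"allele frequency {p_d} outside [0, 1]")
    q = 1.0 - p_d
    homo = p_d * p_d + q * q
    return 1.0 - homo - 2.0 * p_d * p_d * q * q


def _het_log_probs(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of each possible heterozygote count.

    Conditional on sample size ``n`` and rare-allele count ``n_rare``, the
    probability of observing ``h`` heterozygotes under Hardy-Weinberg is

        P(h) = n! / (n_aa! h! n_bb!) * 2^h * n_rare! (2n - n_rare)! / (2n)!

    where n_aa = (n_rare - h)/2.  Feasible h share the parity of n_rare.
    """
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    n_aa = (n_rare - hets) // 2
    n_bb = n - n_aa - hets
    keep = n_bb >= 0
    hets, n_aa, n_bb = hets[keep], n_aa[keep], n_bb[keep]
    logp = (
        gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(hets + 1) - gammaln(n_bb + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1)
    )
    return hets, logp


def hwe_exact(panel: GenotypePanel) -> float:
    """Exact conditional Hardy-Weinberg test for a biallelic locus.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the conditional probabilities of configurations no more
    probable than the observed one (plain two-sided exact tail, no mid-p).

    Returns 1.0 for a fixed locus.
    """
    _check_panel(panel)
    n = panel.n
    n_d = 2 * panel.n_DD + panel.n_ID
    n_rare = min(n_d, 2 * n - n_d)
    if n_rare == 0:
        return 1.0
    hets, logp = _het_log_probs(n, n_rare)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == panel.n_ID][0]
    # relative tolerance guards ties against floating-point noise
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


def hwe_chisq(panel: GenotypePanel) -> float:
    """1-df chi-square goodness-of-fit test against Hardy-Weinberg counts."""
    _check_panel(panel)
    p_d, p_i = allele_freqs(panel)
    if p_d == 0.0 or p_i == 0.0:
        return 1.0
    n = panel.n
    expected = np.array([p_d * p_d, 2 * p_d * p_i, p_i * p_i]) * n
    if np.any(expected == 0):
        raise ValidationError("zero expected genotype count; chi-square undefined")
    observed = np.array(panel.as_counts(), dtype=float)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(statistic, df=1))


def summarize(panel: GenotypePanel) -> LocusSummary:
    """Full locus summary (frequencies, Ho, He, Ne, PIC, HWE) for one panel."""
    _check_panel(panel)
    n = panel.n
    p_d, p_i = allele_freqs(panel)
    return LocusSummary(
        population=panel.population,
        n=n,
        freq_DD=panel.n_DD / n,
        freq_ID=panel.n_ID / n,
        freq_II=panel.n_II / n,
        p_D=p_d,
        p_I=p_i,
        Ho=observed_het(panel),
        He=expected_het(p_d),
        Ne=effective_alleles(p_d),
        PIC=pic_biallelic(p_d),
        hwe_p_exact=hwe_exact(panel),
        hwe_p_chisq=hwe_chisq(panel),
    )


def summarize_from_freq(population: str, p_d: float) -> dict[str, float]:
    """He/Ne/PIC from an allele frequency alone (no genotype counts).

    Useful when only published allele frequencies are available for a breed.
    """
    return {
        "population": population,
        "p_D": p_d,
        "p_I": 1.0 - p_d,
        "He": expected_het(p_d),
        "Ne": effective_alleles(p_d),
        "PIC": pic_biallelic(p_d),
    }


def classify_polymorphism(pic: float) -> str:
    """Botstein marker-informativeness classes: low / moderate / high.

    low: PIC < 0.25; moderate: 0.25 <= PIC < 0.5; high: PIC >= 0.5 (the last
    is unreachable for a biallelic marker, whose PIC tops out at 0.375).
    """
    if pic < 0.25:
        return "low"
    if pic < 0.5:
        return "moderate"
    return "high"
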