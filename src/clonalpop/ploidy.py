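"""Allele-balance ploidy inference.

At a heterozygous SNP the fraction of reads carrying each allele reflects
the allelic dosage: a diploid het concentrates at 1/2, a triploid het at
1/3 or 2/3. Pooling the allele-balance values of all heterozygous calls in
a sample therefore separates diploids (one peak at 1/2) from triploids
(two peaks at 1/3 and 2/3). Visual histogram reading is formalised here as
a binomial likelihood comparison:

    diploid:  logL = sum log Binom(alt_i | n_i, 1/2)
    triploid: logL = sum log[ 1/2 Binom(alt_i | n_i, 1/3)
                            + 1/2 Binom(alt_i | n_i, 2/3) ]

A sample is called only when it has enough usable het sites and the
log-likelihood margin is decisive; otherwise it is left undetermined.
Sites where either allele was sequenced fewer than ``min_allele_depth``
times are excluded, and samples with median read depth below
``min_median_depth`` are skipped, since shallow data make the balance
histogram uninterpretable. A beta-binomial variant is available for data
with mapping-bias overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .core import DepthMatrix, GenotypeMatrix


@dataclass
class AlleleBalanceProfile:
    """Ref/alt depths at the usable heterozygous sites of one sample."""

    sample_id: str
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    median_depth: float  # median total depth over all calls, pre-filter

    @property
    def n_sites(self) -> int:
        return len(self.ref_depth)

    @property
    def balance(self) -> np.ndarray:
        """Alt-read fraction per site."""
        total = self.ref_depth + self.alt_depth
        return self.alt_depth / np.maximum(total, 1)

    def mirrored(self) -> "AlleleBalanceProfile":
        return AlleleBalanceProfile(
            self.sample_id, self.alt_depth, self.ref_depth, self.median_depth
        )


@dataclass
class PloidyCall:
    sample_id: str
    call: str  # diploid | triploid | undetermined
    loglik_diploid: float
    loglik_triploid: float
    n_sites: int
    median_depth: float
    skip_reason: str | None = None


def build_profile(
    sample_id: str,
    gm: GenotypeMatrix,
    depths: DepthMatrix,
    min_allele_depth: int = 10,
    min_median_depth: float = 30.0,
) -> AlleleBalanceProfile | None:
    """Collect allele depths at heterozygous calls of one sample.

    Returns None (sample skipped) when the sample's median total read depth
    is below ``min_median_depth``. Het calls where either allele's depth is
    below ``min_allele_depth`` are excluded from the profile.
    """
    depths.check_aligned(gm)
    i = gm.sample_index(sample_id)
    total = depths.total_depth[i]
    median_depth = float(np.median(total)) if total.size else 0.0
    if median_depth < min_median_depth:
        return None
    dos = gm.dosages[i]
    het = (dos > 0) & (dos < gm.ploidy[i])
    ok = (
        het
        & (depths.ref_depth[i] >= min_allele_depth)
        & (depths.alt_depth[i] >= min_allele_depth)
    )
    return AlleleBalanceProfile(
        sample_id=sample_id,
        ref_depth=depths.ref_depth[i, ok].copy(),
        alt_depth=depths.alt_depth[i, ok].copy(),
        median_depth=median_depth,
    )


def _binom_logpmf(k, n, p, overdispersion: float | None):
    if overdispersion is None:
        return stats.binom.logpmf(k, n, p)
    # beta-binomial with mean p and precision parameter rho
    rho = overdispersion
    return stats.betabinom.logpmf(k, n, p * rho, (1 - p) * rho)


def model_logliks(
    profile: AlleleBalanceProfile, overdispersion: float | None = None
) -> tuple[float, float]:
    """(diploid, triploid) log-likelihoods of the allele-balance data."""
    n = profile.ref_depth + profile.alt_depth
    k = profile.alt_depth
    l_dip = float(np.sum(_binom_logpmf(k, n, 0.5, overdispersion)))
    comp = np.stack(
        [
            _binom_logpmf(k, n, 1.0 / 3.0, overdispersion),
            _binom_logpmf(k, n, 2.0 / 3.0, overdispersion),
        ]
    )
    l_trip = float(np.sum(logsumexp(comp, axis=0) - np.log(2.0)))
    return l_dip, l_trip


def classify_ploidy(
    profile: AlleleBalanceProfile | None,
    min_sites: int = 50,
    margin: float = 10.0,
    overdispersion: float | None = None,
    sample_id: str = "",
    median_depth: float = float("nan"),
) -> PloidyCall:
    """Call diploid vs triploid from an allele-balance profile.

    The better model is called only when it leads by at least ``margin``
    log-units and the profile holds at least ``min_sites`` sites; otherwise
    the sample is left undetermined. A None profile (skipped sample) is
    undetermined with the skip reason recorded.
    """
    if profile is None:
        return PloidyCall(
            sample_id, "undetermined", np.nan, np.nan, 0, median_depth,
            skip_reason="median depth below threshold",
        )
    if profile.n_sites == 0:
        return PloidyCall(
            profile.sample_id, "undetermined", np.nan, np.nan, 0,
            profile.median_depth, skip_reason="no usable heterozygous sites",
        )
    l_dip, l_trip = model_logliks(profile, overdispersion)
    call = "undetermined"
    if profile.n_sites >= min_sites and abs(l_dip - l_trip) >= margin:
        call = "diploid" if l_dip > l_trip else "triploid"
    return PloidyCall(
        profile.sample_id, call, l_dip, l_trip, profile.n_sites,
        profile.median_depth,
    )


def classify_all(
    gm: GenotypeMatrix,
    depths: DepthMatrix,
    min_allele_depth: int = 10,
    min_median_depth: float = 30.0,
    min_sites: int = 50,
    margin: float = 10.0,
    overdispersion: float | None = None,
) -> list[PloidyCall]:
    calls = []
    for sid in gm.sample_ids:
        prof = build_profile(sid, gm, depths, min_allele_depth, min_median_depth)
        calls.append(
            classify_ploidy(
                prof, min_sites, margin, overdispersion, sample_id=sid
            )
        )
    return calls


def allele_balance_histogram(
    profile: AlleleBalanceProfile, bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Binned allele-balance counts over [0, 1] for reporting; counts sum to
    the number of profile sites."""
    counts, edges = np.histogram(profile.balance, bins=bins, range=(0.0, 1.0))
    return counts, edges
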