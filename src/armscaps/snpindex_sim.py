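"""Confidence intervals of the SNP-index under binomial read sampling.

At a heterozygous position with variant-allele dosage *d* in a sample of
ploidy *k*, each read carries the variant allele with probability
p = d/k, so the variant read count at coverage depth *n* is
X ~ Binomial(n, p) and the observed SNP-index is X/n. The central
confidence interval of X/n tells us which observed indices are
compatible with a given dosage — and, conversely, at which depths
heterozygous genotypes can be told apart from homozygous ones (index
0 or 1), or dosage classes from each other.

The primary construction is exact binomial quantiles; a seeded
Monte-Carlo version exists purely as a stochastic cross-check.

Quantile convention (fixed so results are bit-reproducible): the lower
endpoint is q/n with q the smallest integer k such that
P(X <= k) >= (1-confidence)/2, the upper endpoint r/n with r the
smallest k such that P(X <= k) >= 1-(1-confidence)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom


@dataclass(frozen=True)
class SnpIndexInterval:
    """Central confidence interval of the SNP-index X/depth."""

    depth: int
    ploidy: int
    dosage: int
    confidence: float
    lo: float
    hi: float

    def contains(self, index: float) -> bool:
        return self.lo <= index <= self.hi

    @property
    def width(self) -> float:
        return self.hi - self.lo


def _validate(depth: int, dosage: int, ploidy: int, confidence: float) -> None:
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if ploidy < 2:
        raise ValueError(f"ploidy must be >= 2, got {ploidy}")
    if not 1 <= dosage <= ploidy - 1:
        raise ValueError(
            f"dosage must be in [1, ploidy-1]=[1, {ploidy - 1}], got {dosage}"
        )
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")


def snp_index_interval(
    depth: int, dosage: int, ploidy: int, confidence: float = 0.95
) -> SnpIndexInterval:
    """Exact central binomial confidence interval of the SNP-index.

    Endpoints are multiples of 1/depth and always bracket dosage/ploidy.
    """
    _validate(depth, dosage, ploidy, confidence)
    p = dosage / ploidy
    alpha = (1.0 - confidence) / 2.0
    ks = np.arange(depth + 1)
    cdf = binom.cdf(ks, depth, p)
    # smallest k with CDF >= target; tiny epsilon guards float round-off on
    # exact ties (e.g. CDF exactly 0.025)
    eps = 1e-12
    q = int(np.argmax(cdf >= alpha - eps))
    r = int(np.argmax(cdf >= 1.0 - alpha - eps))
    return SnpIndexInterval(
        depth=depth,
        ploidy=ploidy,
        dosage=dosage,
        confidence=confidence,
        lo=q / depth,
        hi=r / depth,
    )


MIN_MC_REPLICATES = 10_000


def monte_carlo_interval(
    depth: int,
    dosage: int,
    ploidy: int,
    confidence: float = 0.95,
    replicates: int = 100_000,
    seed: int = 0,
) -> SnpIndexInterval:
    """Empirical SNP-index interval from simulated read draws.

    Applies the same smallest-k-with-CDF>=target convention to the
    empirical CDF, so for large ``replicates`` it reproduces
    :func:`snp_index_interval` exactly on the 1/depth grid. Retained as a
    stochastic oracle for the exact construction.
    """
    _validate(depth, dosage, ploidy, confidence)
    if replicates < MIN_MC_REPLICATES:
        raise ValueError(
            f"replicates must be >= {MIN_MC_REPLICATES}, got {replicates}"
        )
    rng = np.random.default_rng(seed)
    draws = rng.binomial(depth, dosage / ploidy, size=replicates)
    counts = np.bincount(draws, minlength=depth + 1)
    ecdf = np.cumsum(counts) / replicates
    alpha = (1.0 - confidence) / 2.0
    q = int(np.argmax(ecdf >= alpha))
    r = int(np.argmax(ecdf >= 1.0 - alpha))
    return SnpIndexInterval(
        depth=depth,
        ploidy=ploidy,
        dosage=dosage,
        confidence=confidence,
        lo=q / depth,
        hi=r / depth,
    )


_MAX_SCAN_DEPTH = 100_000


def min_depth_excluding_homozygous(
    ploidy: int = 2, dosage: int = 1, confidence: float = 0.95
) -> int:
    """Smallest depth whose heterozygous interval excludes indices 0 and 1.

    Below this depth an observed index of 0 or 1 (a homozygote) is still
    inside the heterozygous confidence interval, so the genotypes cannot
    be distinguished from coverage alone.
    """
    _validate(1, dosage, ploidy, confidence)
    for depth in range(1, _MAX_SCAN_DEPTH + 1):
        iv = snp_index_interval(depth, dosage, ploidy, confidence)
        if iv.lo > 0.0 and iv.hi < 1.0:
            return depth
    raise RuntimeError("no qualifying depth found")  # pragma: no cover


def min_discernible_depth(ploidy: int = 4, confidence: float = 0.95) -> int:
    """Smallest depth at which all heterozygous dosage classes separate.

    Dosage classes 1..ploidy-1 are *discernible* when their closed
    confidence intervals are pairwise disjoint (hi of each dosage strictly
    below lo of the next). For an autotetraploid this is the depth at
    which simplex, duplex and triplex calls stop overlapping.
    """
    if ploidy < 3:
        raise ValueError(
            "discernibility needs >= 2 heterozygous classes (ploidy >= 3); "
            "for diploids use min_depth_excluding_homozygous"
        )
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    for depth in range(1, _MAX_SCAN_DEPTH + 1):
        ivs = [
            snp_index_interval(depth, d, ploidy, confidence)
            for d in range(1, ploidy)
        ]
        if all(ivs[i].hi < ivs[i + 1].lo for i in range(len(ivs) - 1)):
            return depth
    raise RuntimeError("no qualifying depth found")  # pragma: no cover


def interval_table(
    depths: range | list,
    ploidy: int,
    confidence: float = 0.95,
):
    """TSV-ready rows of (depth, dosage, ploidy, lo, hi) over a depth range."""
    import pandas as pd

    rows = []
    for depth in depths:
        for dosage in range(1, ploidy):
            iv = snp_index_interval(depth, dosage, ploidy, confidence)
            rows.append(
                {
                    "depth": depth,
                    "dosage": dosage,
                    "ploidy": ploidy,
                    "lo": iv.lo,
                    "hi": iv.hi,
                }
            )
    return pd.DataFrame(rows, columns=["depth", "dosage", "ploidy", "lo", "hi"])
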