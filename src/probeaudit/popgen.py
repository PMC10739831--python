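"""Per-site two-population Weir–Cockerham Fst from genotype counts.

The estimator decomposes allelic variance into among-population (a),
among-individual-within-population (b), and within-individual (c)
components and reports theta = a / (a + b + c).  Heterozygosity enters as
the *observed* heterozygote fraction, not a Hardy–Weinberg expectation.
Negative estimates are reported as-is; a site monomorphic in both
populations has no defined theta (``None``), never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .variants import SNPRecord, allele_frequency

__all__ = [
    "FstComponents",
    "wc_fst",
    "wc_fst_from_snp",
    "fst_table",
    "multilocus_theta",
    "strongly_differentiated",
]


@dataclass(frozen=True)
class FstComponents:
    """Weir–Cockerham variance components for one site, two populations.

    ``theta`` is ``None`` when a + b + c == 0 (site monomorphic in both
    populations with no heterozygotes), in which case differentiation is
    undefined.
    """

    a: float
    b: float
    c: float
    theta: float | None
    n1: int
    n2: int
    p1: float
    p2: float
    h1: float
    h2: float


def wc_fst(n1: int, p1: float, h1: float, n2: int, p2: float, h2: float) -> FstComponents:
    """Weir–Cockerham per-site estimator for two populations (r = 2).

    Parameters are per population: ``n`` diploid individuals with called
    genotypes, ``p`` the (alternate) allele frequency, ``h`` the observed
    heterozygote *fraction* (heterozygotes / n).

    With r = 2 populations::

        n_bar = (n1 + n2) / 2
        n_c   = (r*n_bar - (n1^2 + n2^2)/(r*n_bar)) / (r - 1)
        p_bar = (n1*p1 + n2*p2) / (r*n_bar)
        s2    = (n1*(p1-p_bar)^2 + n2*(p2-p_bar)^2) / ((r-1)*n_bar)
        h_bar = (n1*h1 + n2*h2) / (r*n_bar)
        a = (n_bar/n_c) * (s2 - (p_bar*(1-p_bar) - s2*(r-1)/r - h_bar/4) / (n_bar-1))
        b = (n_bar/(n_bar-1)) * (p_bar*(1-p_bar) - s2*(r-1)/r - h_bar*(2*n_bar-1)/(4*n_bar))
        c = h_bar / 2
        theta = a / (a + b + c)
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"need >= 2 diploids per population, got {n1}, {n2}")
    for tag, p, h in (("1", p1, h1), ("2", p2, h2)):
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"p{tag}={p} outside [0, 1]")
        if not (0.0 <= h <= 1.0):
            raise ValidationError(f"h{tag}={h} outside [0, 1]")
        # each heterozygote carries one copy of each allele
        if h > 2.0 * min(p, 1.0 - p) + 1e-12:
            raise ValidationError(
                f"h{tag}={h} inconsistent with p{tag}={p} (h must be <= 2*min(p, 1-p))"
            )

    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    denom = a + b + c
    theta = None if denom == 0.0 else a / denom
    return FstComponents(a=a, b=b, c=c, theta=theta,
                         n1=n1, n2=n2, p1=p1, p2=p2, h1=h1, h2=h2)


def wc_fst_from_snp(snp: SNPRecord, pop1: str, pop2: str) -> FstComponents:
    """Estimator applied to one :class:`SNPRecord`'s genotype counts."""
    c1, c2 = snp.counts.get(pop1), snp.counts.get(pop2)
    if c1 is None or c2 is None:
        raise ValidationError(f"{snp.snp_id}: missing counts for {pop1} or {pop2}")
    return wc_fst(
        c1.n_called, allele_frequency(snp, pop1), c1.het_count / c1.n_called,
        c2.n_called, allele_frequency(snp, pop2), c2.het_count / c2.n_called,
    )


def fst_table(snps: Sequence[SNPRecord], pop1: str, pop2: str) -> pd.DataFrame:
    """Per-site components and theta for a list of SNPs.

    Undefined theta (monomorphic in both populations) appears as NaN in
    the table; the components are still reported.
    """
    rows = []
    for snp in snps:
        comp = wc_fst_from_snp(snp, pop1, pop2)
        rows.append(
            {
                "snp_id": snp.snp_id, "chrom": snp.chrom, "pos": snp.pos,
                "n1": comp.n1, "n2": comp.n2, "p1": comp.p1, "p2": comp.p2,
                "a": comp.a, "b": comp.b, "c": comp.c,
                "theta": np.nan if comp.theta is None else comp.theta,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "n1", "n2", "p1", "p2", "a", "b", "c", "theta"],
    )


def multilocus_theta(components: Sequence[FstComponents]) -> float:
    """Multi-locus theta: summed components, one ratio.

    Averaging per-site theta values underestimates the true divergence
    (each per-site value is a ratio of noisy components, and the ratio of
    means is not the mean of ratios); the standard combined estimator sums
    a and a + b + c across loci first and divides once.  Use this when a
    single genome-wide (or SNP-set-wide) differentiation parameter is
    wanted; use the per-site table when the distribution is the object of
    interest.
    """
    if not components:
        raise ValidationError("no components supplied")
    num = sum(c.a for c in components)
    denom = sum(c.a + c.b + c.c for c in components)
    if denom == 0.0:
        raise DataError("all sites monomorphic: multilocus theta undefined")
    return num / denom


def strongly_differentiated(theta: float | None, threshold: float = 0.1) -> bool:
    """True when theta >= threshold (default 0.1, inclusive)."""
    if theta is None or (isinstance(theta, float) and np.isnan(theta)):
        raise DataError("theta undefined: differentiation cannot be classified")
    return theta >= threshold
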