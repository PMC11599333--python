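"""Cellwise ecological suitability from pairwise species co-occurrence.

For each species pair (i, j) with site occupancies n_i, n_j over N sites,
the observed co-occurrence count C_ij is compared with the hypergeometric
expectation under random, independent placement:

    mu      = n_i * n_j / N
    sigma^2 = n_i * n_j * (N - n_i) * (N - n_j) / (N^2 * (N - 1))
    SES_ij  = (C_ij - mu) / sigma        (0 whenever sigma^2 = 0)

The standardized effect size (SES) is the pair's indicator value: how far the
realized co-occurrence departs from a random association.  A species' raw
suitability score at a site is the mean SES against the species present
there (itself excluded), and a monotone map — per-metacommunity min-max by
default, or the standard-normal CDF — rescales raw scores into [0, 1].
Suitability is computed for every cell, present or absent, so it estimates
how appropriate a site is for a species independently of the species'
observed occurrence there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data import MetacommunityMatrix

__all__ = [
    "CooccurrenceIndicators",
    "SuitabilityMatrix",
    "pairwise_cooccurrence_ses",
    "suitability_matrix",
]

DIALECTS = ("minmax", "normcdf")


@dataclass(frozen=True)
class CooccurrenceIndicators:
    """Pairwise SES matrix plus the marginals it was computed from."""

    ses: np.ndarray          # (S, S), symmetric, diagonal ignored by consumers
    occupancy: np.ndarray    # (S,) per-species site counts
    n_sites: int


@dataclass(frozen=True)
class SuitabilityMatrix:
    """Per-cell suitability in [0, 1], same shape/order as the prab matrix."""

    values: np.ndarray
    species_ids: tuple[str, ...]
    site_ids: tuple[str, ...]
    dialect: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any() or (v > 1).any():
            raise ValueError("suitability values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


def pairwise_cooccurrence_ses(m: MetacommunityMatrix) -> CooccurrenceIndicators:
    """Standardized effect sizes of all pairwise co-occurrences."""
    prab = m.prab.astype(float)
    n_sites = m.n_sites
    if n_sites < 2:
        raise ValueError("need at least 2 sites for co-occurrence moments")
    occ = prab.sum(axis=1)
    C = prab @ prab.T
    mu = np.outer(occ, occ) / n_sites
    var = (
        np.outer(occ, occ)
        * np.outer(n_sites - occ, n_sites - occ)
        / (n_sites**2 * (n_sites - 1))
    )
    ses = np.zeros_like(C)
    nz = var > 0
    ses[nz] = (C[nz] - mu[nz]) / np.sqrt(var[nz])
    return CooccurrenceIndicators(ses=ses, occupancy=occ.astype(int), n_sites=n_sites)


def _raw_scores(m: MetacommunityMatrix, c: CooccurrenceIndicators) -> np.ndarray:
    """Mean SES of each species against the other species present per site."""
    prab = m.prab.astype(float)
    ses = c.ses.copy()
    np.fill_diagonal(ses, 0.0)
    # numerator: sum of SES_ij over j present at the site, minus nothing on the
    # diagonal; denominator: count of co-occurring species excluding i itself
    num = ses @ prab
    counts = prab.sum(axis=0)[None, :] - prab  # others present at site s
    raw = np.zeros_like(num)
    nz = counts > 0
    raw[nz] = num[nz] / counts[nz]
    return raw


def suitability_matrix(
    m: MetacommunityMatrix,
    c: CooccurrenceIndicators | None = None,
    dialect: str = "minmax",
) -> SuitabilityMatrix:
    """Map raw co-occurrence scores into a [0, 1] suitability per cell.

    dialect "minmax" rescales by the metacommunity-wide min and max (the full
    documented 0-1 range is attained); "normcdf" applies the standard-normal
    CDF (an empty average maps to 0.5).  Both are monotone in the raw score,
    so cell rank order is dialect-invariant.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown suitability dialect {dialect!r}; choose from {DIALECTS}")
    if c is None:
        c = pairwise_cooccurrence_ses(m)
    raw = _raw_scores(m, c)
    if dialect == "normcdf":
        suit = norm.cdf(raw)
    else:
        lo, hi = raw.min(), raw.max()
        if hi == lo:
            suit = np.full_like(raw, 0.5)
        else:
            suit = (raw - lo) / (hi - lo)
    return SuitabilityMatrix(
        values=suit, species_ids=m.species_ids, site_ids=m.site_ids, dialect=dialect
    )
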