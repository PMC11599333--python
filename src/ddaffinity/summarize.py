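"""Posterior summaries, 0.5-threshold classification, and subset comparisons.

Entities (species/sites) and cells are summarized by the empirical median
and central credible interval of their posterior draws (type-7 linear
interpolation quantiles, default 95%).  An entity is *dark-affine* when its
whole credible interval lies above 0.5, *presence-affine* when it lies below,
and *unresolved* otherwise.  Coefficients are reported by posterior mean and
flagged significant when the credible interval excludes 0.

The metacommunity is split into absent (prab = 0) and present (prab = 1)
cell subsets and each model quantity (p, suit, DDA, dda_sp, dda_site) is
compared between them with a Kruskal-Wallis rank test (tie-corrected H,
chi-squared approximation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .data import MetacommunityMatrix

__all__ = [
    "summarize_quantity",
    "classify_affinity",
    "coefficient_significance",
    "split_subsets",
    "kruskal_wallis",
    "compare_subsets",
    "SubsetComparisonResult",
]

DARK = "dark-affine"
PRESENT = "presence-affine"
UNRESOLVED = "unresolved"


def summarize_quantity(draws: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """(median, lower, upper) central credible summary of one scalar's draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot summarize empty draws")
    alpha = (1.0 - level) / 2.0
    med, lo, hi = np.quantile(draws, [0.5, alpha, 1.0 - alpha])
    return float(med), float(lo), float(hi)


def classify_affinity(summary: tuple[float, float, float]) -> str:
    """Label an affinity summary against the 0.5 neutral threshold."""
    med, lo, hi = summary
    if not (lo <= med <= hi):
        raise ValueError("summary must satisfy lower <= median <= upper")
    if lo > 0.5:
        return DARK
    if hi < 0.5:
        return PRESENT
    return UNRESOLVED


def coefficient_significance(
    draws: np.ndarray, names: Sequence[str], level: float = 0.95
) -> pd.DataFrame:
    """Posterior mean, credible bounds and a CI-excludes-zero flag per coefficient."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[1] != len(names):
        raise ValueError("draws must be (n_draws, n_coefficients)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha], axis=0)
    mean = draws.mean(axis=0)
    return pd.DataFrame(
        {
            "mean": mean,
            "lower": lo,
            "upper": hi,
            "significant": (lo > 0) | (hi < 0),
        },
        index=list(names),
    )


def split_subsets(m: MetacommunityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Flat cell indices of the absent (prab=0) and present (prab=1) subsets."""
    flat = m.prab.ravel()
    return np.flatnonzero(flat == 0), np.flatnonzero(flat == 1)


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value.

    H = 12/(N(N+1)) * sum(R_g^2/n_g) - 3(N+1), divided by the tie correction
    1 - sum(t^3 - t)/(N^3 - N).  All-tied data returns H = 0 (p = 1) rather
    than erroring, so degenerate posteriors compare as "no difference".
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    sizes = np.array([g.size for g in groups])
    n = int(sizes.sum())
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g, sz in zip(groups, sizes):
        r = ranks[start : start + sz]
        h += r.sum() ** 2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if correction == 0.0:
        return 0.0, 1.0  # every observation tied
    h /= correction
    df = len(groups) - 1
    return float(h), float(chi2.sf(h, df))


@dataclass
class SubsetComparisonResult:
    """Absent/present medians plus Kruskal-Wallis H and p, one row per quantity."""

    table: pd.DataFrame
    n_absent: int
    n_present: int

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")


def compare_subsets(
    m: MetacommunityMatrix,
    cell_values: dict[str, np.ndarray],
    pool_draws: bool = False,
    draw_values: dict[str, np.ndarray] | None = None,
) -> SubsetComparisonResult:
    """Compare each quantity between absent and present cell subsets.

    ``cell_values`` maps quantity name -> (n_species, n_sites) array of one
    observation per cell (posterior medians for fitted quantities; suit as
    computed).  With ``pool_draws``, ``draw_values`` supplies
    (n_draws, n_species, n_sites) arrays and every draw enters the rank test
    (the sensitivity alternative; it inflates the sample size).
    """
    absent, present = split_subsets(m)
    if absent.size == 0 or present.size == 0:
        raise ValueError("one subset is empty; comparison is undefined")
    rows = []
    for name, values in cell_values.items():
        flat = np.asarray(values, dtype=float).reshape(-1)
        if flat.size != m.prab.size:
            raise ValueError(f"{name}: expected one value per cell")
        if pool_draws and draw_values and name in draw_values:
            dv = np.asarray(draw_values[name], dtype=float).reshape(-1, m.prab.size)
            ga, gp = dv[:, absent].ravel(), dv[:, present].ravel()
        else:
            ga, gp = flat[absent], flat[present]
        h, p = kruskal_wallis([ga, gp])
        rows.append(
            {
                "quantity": name,
                "median_absent": float(np.median(ga)),
                "median_present": float(np.median(gp)),
                "H": h,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows).set_index("quantity")
    return SubsetComparisonResult(table=table, n_absent=absent.size, n_present=present.size)
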