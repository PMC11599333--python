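"""Data selection, predictor standardization, and design-matrix construction.

Quantitative predictors are standardized to mean 0 and sample standard
deviation 0.5 (the Gelman scaling that puts logistic coefficients of binary
and continuous predictors on a comparable footing).  Categorical predictors
are expanded to a full set of level indicators — one column per level, no
dropped reference — with identifiability provided downstream by shrinkage
priors, so per-level deviations from the intercept are directly estimable.

Blocks of related environmental variables (e.g. mean/max/min temperature)
are summarized by the scores of the first principal component of their
correlation matrix, sign-aligned to correlate positively with the originals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data import EmptyDatasetError, MetacommunityMatrix, SiteAttributeTable, TraitTable

logger = logging.getLogger("ddaffinity")

__all__ = [
    "DesignMatrix",
    "SelectionThresholds",
    "DegeneratePredictorError",
    "apply_selection_thresholds",
    "standardize_quantitative",
    "first_pc_scores",
    "build_design_matrix",
]


class DegeneratePredictorError(ValueError):
    """A predictor (or block) is constant and carries no information."""


@dataclass(frozen=True)
class SelectionThresholds:
    """Inclusion filters applied before matrix assembly.

    min_examined: minimum parasitologically examined host individuals for a
    host-in-region record to count at all (guards against absences that are
    artefacts of low sampling effort given parasite aggregation).
    min_sites_per_species / min_species_per_site: occupancy thresholds on the
    assembled matrix.
    """

    min_examined: int = 15
    min_sites_per_species: int = 1
    min_species_per_site: int = 1

    def __post_init__(self) -> None:
        if min(self.min_examined, self.min_sites_per_species, self.min_species_per_site) < 1:
            raise ValueError("all selection thresholds must be >= 1")


def apply_selection_thresholds(
    records: pd.DataFrame, thresholds: SelectionThresholds
) -> MetacommunityMatrix:
    """Filter sampling records and assemble a binary presence-absence matrix.

    Parameters
    ----------
    records : DataFrame with columns ``site``, ``host``, ``n_examined`` and
        ``species``; one row per parasite species observed in one
        (site, host) sampling record.  ``species`` may be NA for a record
        with no parasites (the record still certifies sampling effort).
    thresholds : SelectionThresholds

    Records with fewer than ``min_examined`` examined individuals are dropped
    first; then species occupying fewer than ``min_sites_per_species`` sites
    and sites holding fewer than ``min_species_per_site`` species are dropped
    (a single pass, in that order).
    """
    required = {"site", "host", "n_examined", "species"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    n0 = len(records)
    kept = records[records["n_examined"] >= thresholds.min_examined]
    if kept.empty:
        raise EmptyDatasetError(
            f"all {n0} records fall below min_examined={thresholds.min_examined}"
        )
    obs = kept.dropna(subset=["species"])
    if obs.empty:
        raise EmptyDatasetError("no parasite observations survive the effort filter")
    table = pd.crosstab(obs["species"].astype(str), obs["site"].astype(str))
    prab = (table > 0).astype(int)

    sp_keep = prab.sum(axis=1) >= thresholds.min_sites_per_species
    prab = prab.loc[sp_keep]
    site_keep = prab.sum(axis=0) >= thresholds.min_species_per_site
    prab = prab.loc[:, site_keep]
    if prab.empty or prab.shape[1] == 0:
        raise EmptyDatasetError(
            "occupancy thresholds removed everything "
            f"(records kept {len(kept)}/{n0}, species kept {int(sp_keep.sum())}, "
            f"sites kept {int(site_keep.sum())})"
        )
    return MetacommunityMatrix.from_frame(prab)


def standardize_quantitative(values: np.ndarray | pd.Series) -> np.ndarray:
    """Center to mean 0 and rescale to sample (n-1) standard deviation 0.5."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegeneratePredictorError("need at least 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegeneratePredictorError("constant predictor cannot be standardized")
    return (x - x.mean()) / sd * 0.5


def first_pc_scores(block: pd.DataFrame | np.ndarray) -> np.ndarray:
    """First-principal-component scores of a block of related variables.

    PCA is run on the correlation matrix (each variable z-scored first), so
    the result is invariant to per-variable affine rescaling.  The score sign
    is chosen so that scores correlate positively with the block variables
    (positive sum of score-variable correlations).
    """
    X = np.asarray(block, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise DegeneratePredictorError("need at least 2 entities for PCA")
    sds = X.std(axis=0, ddof=1)
    if (sds == 0).all():
        raise DegeneratePredictorError("constant block")
    keep = sds > 0
    if not keep.all():
        logger.warning("dropping %d constant variable(s) from PCA block", (~keep).sum())
        X = X[:, keep]
        sds = sds[keep]
    Z = (X - X.mean(axis=0)) / sds
    scores = PCA(n_components=1).fit_transform(Z)[:, 0]
    corr_sum = sum(
        np.corrcoef(scores, Z[:, j])[0, 1] for j in range(Z.shape[1]) if Z[:, j].std() > 0
    )
    if corr_sum < 0:
        scores = -scores
    return scores


@dataclass(frozen=True)
class DesignColumn:
    name: str
    source: str
    kind: str  # "quantitative" | "indicator"
    level: str | None = None


@dataclass(frozen=True)
class DesignMatrix:
    """Numeric predictor matrix with column provenance.

    Quantitative columns are standardized (mean 0, sd 0.5); each categorical
    trait with L declared levels contributes exactly L 0/1 indicator columns
    whose row sums are 1.
    """

    entity_ids: tuple[str, ...]
    columns: tuple[DesignColumn, ...]
    values: np.ndarray

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.entity_ids), columns=list(self.column_names))


def build_design_matrix(
    table: TraitTable | SiteAttributeTable,
    levels: dict[str, list[str]] | None = None,
) -> DesignMatrix:
    """Expand a trait/attribute table into a model design matrix.

    ``levels`` optionally declares the exhaustive level set per categorical
    column (defaults to the observed levels, sorted).  An observed level
    absent from a declared set raises a schema error.  Constant quantitative
    predictors are dropped with a warning rather than failing the run.
    """
    levels = dict(levels or {})
    cols: list[DesignColumn] = []
    data: list[np.ndarray] = []
    for name in table.quantitative:
        raw = table.frame[name].to_numpy(dtype=float)
        try:
            std = standardize_quantitative(raw)
        except DegeneratePredictorError:
            logger.warning("dropping constant predictor %r", name)
            continue
        cols.append(DesignColumn(name=name, source=name, kind="quantitative"))
        data.append(std)
    for name in table.categorical:
        observed = table.frame[name].astype(str)
        declared = [str(v) for v in levels.get(name, sorted(observed.unique()))]
        extra = sorted(set(observed) - set(declared))
        if extra:
            raise ValueError(
                f"categorical {name!r} has observed level(s) {extra} outside the declared set {declared}"
            )
        for lv in declared:
            cols.append(
                DesignColumn(name=f"{name}[{lv}]", source=name, kind="indicator", level=lv)
            )
            data.append((observed == lv).to_numpy(dtype=float))
    if not cols:
        values = np.empty((len(table), 0))
    else:
        values = np.column_stack(data)
    return DesignMatrix(entity_ids=table.ids, columns=tuple(cols), values=values)
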