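"""Core data containers, delimited-file I/O, and run configuration.

The central object is the :class:`MetacommunityMatrix`: a binary species x
site presence-absence table (``prab``).  "Sites" are regions when the
metacommunity is *component* (one host species surveyed across regions) and
host species when it is *compound* (many hosts within one region).  Species
traits and site attributes travel in :class:`TraitTable` and
:class:`SiteAttributeTable`, thin wrappers over pandas DataFrames that
enforce alignment with the matrix.

All tables are read and written as UTF-8 CSV with a mandatory header row and
the entity label in the first column, so that ``load(write(x)) == x`` to full
stored precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("ddaffinity")

__all__ = [
    "MetacommunityMatrix",
    "TraitTable",
    "SiteAttributeTable",
    "AnalysisConfig",
    "ResultBundle",
    "ValidationReport",
    "AlignmentError",
    "ParseError",
    "EmptyDatasetError",
    "load_metacommunity",
    "load_matrix",
    "load_traits",
    "load_site_attributes",
    "validate_dataset",
    "write_results",
]


class AlignmentError(ValueError):
    """Species/site labels of two tables do not line up."""


class ParseError(ValueError):
    """A file cell failed to parse under the declared contract."""


class EmptyDatasetError(ValueError):
    """Filtering or validation removed every species or site."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class MetacommunityMatrix:
    """Binary species x site occupancy matrix.

    Parameters
    ----------
    species_ids : list of str
        Row labels, unique, in canonical order.
    site_ids : list of str
        Column labels, unique, in canonical order.
    prab : ndarray of shape (n_species, n_sites)
        Presence (1) / absence (0) per cell.
    """

    species_ids: tuple[str, ...]
    site_ids: tuple[str, ...]
    prab: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "species_ids", tuple(str(s) for s in self.species_ids))
        object.__setattr__(self, "site_ids", tuple(str(s) for s in self.site_ids))
        arr = np.asarray(self.prab)
        if arr.ndim != 2 or arr.shape != (len(self.species_ids), len(self.site_ids)):
            raise ParseError(
                f"matrix shape {arr.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.site_ids)} sites"
            )
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"non-binary cell at species {self.species_ids[i]!r}, "
                f"site {self.site_ids[j]!r}: {arr[i, j]!r}"
            )
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ParseError("duplicate species labels")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ParseError("duplicate site labels")
        object.__setattr__(self, "prab", arr.astype(np.int8))

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def prevalence(self) -> np.ndarray:
        """Per-species occupied fraction (row means)."""
        return self.prab.mean(axis=1)

    @property
    def richness(self) -> np.ndarray:
        """Per-site species count (column sums)."""
        return self.prab.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.prab, index=list(self.species_ids), columns=list(self.site_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MetacommunityMatrix":
        values = df.to_numpy()
        if values.dtype.kind not in "iuf" or not np.isin(values, (0, 1)).all():
            # locate the first offender for the error message
            for i, sp in enumerate(df.index):
                for j, st in enumerate(df.columns):
                    v = df.iat[i, j]
                    if v not in (0, 1):
                        raise ParseError(
                            f"non-binary cell at species {sp!r}, site {st!r}: {v!r}"
                        )
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), values)


class _AlignedTable:
    """Base for per-entity attribute tables (one row per species or site)."""

    entity_kind = "entity"

    def __init__(self, frame: pd.DataFrame, categorical: Iterable[str] | None = None):
        if frame.index.duplicated().any():
            raise ParseError(f"duplicate {self.entity_kind} labels in table")
        if frame.isna().any().any():
            cols = frame.columns[frame.isna().any()].tolist()
            raise ParseError(f"missing values in columns {cols}")
        self.frame = frame.copy()
        self.frame.index = self.frame.index.astype(str)
        if categorical is None:
            categorical = [c for c in frame.columns if frame[c].dtype == object]
        self.categorical = tuple(categorical)
        for c in self.categorical:
            if c not in frame.columns:
                raise ParseError(f"declared categorical column {c!r} absent from table")
        self.quantitative = tuple(c for c in frame.columns if c not in self.categorical)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    def align_to(self, labels: Iterable[str]) -> "_AlignedTable":
        """Reindex to ``labels`` (canonical matrix order); error on missing."""
        labels = [str(x) for x in labels]
        missing = sorted(set(labels) - set(self.frame.index))
        if missing:
            raise AlignmentError(
                f"{self.entity_kind} table missing entries for: {', '.join(missing)}"
            )
        out = type(self)(self.frame.loc[labels], categorical=self.categorical)
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, _AlignedTable)
            and self.frame.equals(other.frame)
            and self.categorical == other.categorical
        )

    def __len__(self) -> int:
        return len(self.frame)


class TraitTable(_AlignedTable):
    """Species traits: quantitative columns plus declared categorical columns."""

    entity_kind = "species"


class SiteAttributeTable(_AlignedTable):
    """Site attributes (environmental variables or host traits)."""

    entity_kind = "site"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class AnalysisConfig:
    """All knobs of the pipeline, mirrored one-to-one by config files.

    MCMC defaults follow the component-metacommunity schedule: 3 chains of
    333 retained draws each (999 posterior samples), burn-in 4000 and
    thinning 12, escalated by doubling up to burn-in 25000 / thinning 75
    whenever any R-hat exceeds 1.1.
    """

    kind: str = "component"
    min_examined: int = 15
    min_sites_per_species: int = 1
    min_species_per_site: int = 1
    prior_mean: float = 0.0
    prior_scale_a: float = 0.5
    prior_scale_b: float = 2.5
    chains: int = 3
    samples_per_chain: int = 333
    burn_in: int = 4000
    thinning: int = 12
    max_burn_in: int = 25000
    max_thinning: int = 75
    escalation_factor: int = 2
    shared_intercept: bool = False
    epsilon: float = 1e-6
    ci_level: float = 0.95
    suitability_dialect: str = "minmax"
    rhat_threshold: float = 1.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("component", "compound"):
            raise ValueError(f"kind must be 'component' or 'compound', got {self.kind!r}")
        if self.chains < 2:
            raise ValueError("chains must be >= 2")
        if self.samples_per_chain < 1:
            raise ValueError("samples_per_chain must be >= 1")
        if not (0.0 < self.epsilon < 0.01):
            raise ValueError("epsilon must lie in (0, 0.01)")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must lie in (0, 1)")
        if self.suitability_dialect not in ("minmax", "normcdf"):
            raise ValueError(f"unknown suitability dialect {self.suitability_dialect!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    all_zero_species: list[str]
    all_zero_sites: list[str]
    duplicate_species: list[str]
    duplicate_sites: list[str]
    prevalence: pd.Series
    richness: pd.Series
    degenerate_no_absences: bool
    matrix: MetacommunityMatrix

    @property
    def clean(self) -> bool:
        return not (self.all_zero_species or self.all_zero_sites or self.degenerate_no_absences)


def validate_dataset(m: MetacommunityMatrix, strict: bool = False) -> ValidationReport:
    """Report (and in strict mode remove) degenerate rows/columns.

    A never-observed species has undefined hypergeometric co-occurrence
    moments, so strict validation drops all-zero rows (and all-zero site
    columns) before suitability estimation, logging every removal.
    """
    prab = m.prab
    zero_sp = [m.species_ids[i] for i in np.flatnonzero(prab.sum(axis=1) == 0)]
    zero_site = [m.site_ids[j] for j in np.flatnonzero(prab.sum(axis=0) == 0)]
    out = m
    if strict and (zero_sp or zero_site):
        keep_sp = [s for s in m.species_ids if s not in set(zero_sp)]
        keep_site = [s for s in m.site_ids if s not in set(zero_site)]
        if not keep_sp or not keep_site:
            raise EmptyDatasetError("strict validation removed every species or site")
        for s in zero_sp:
            logger.warning("dropping never-observed species %r", s)
        for s in zero_site:
            logger.warning("dropping empty site %r", s)
        df = m.to_frame().loc[keep_sp, keep_site]
        out = MetacommunityMatrix.from_frame(df)
    return ValidationReport(
        all_zero_species=zero_sp,
        all_zero_sites=zero_site,
        duplicate_species=[],
        duplicate_sites=[],
        prevalence=pd.Series(out.prevalence, index=list(out.species_ids), name="prevalence"),
        richness=pd.Series(out.richness, index=list(out.site_ids), name="richness"),
        degenerate_no_absences=bool((out.prab == 1).all()),
        matrix=out,
    )


# ---------------------------------------------------------------------------
# file I/O


def load_matrix(path: str | Path) -> MetacommunityMatrix:
    df = pd.read_csv(path, index_col=0)
    return MetacommunityMatrix.from_frame(df)


def _load_table(path: str | Path, cls: type[_AlignedTable], categorical=None) -> _AlignedTable:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return cls(df, categorical=categorical)


def load_traits(path: str | Path, categorical: Iterable[str] | None = None) -> TraitTable:
    return _load_table(path, TraitTable, categorical)


def load_site_attributes(
    path: str | Path, categorical: Iterable[str] | None = None
) -> SiteAttributeTable:
    return _load_table(path, SiteAttributeTable, categorical)


def load_metacommunity(
    matrix_path: str | Path,
    traits_path: str | Path,
    sites_path: str | Path,
    trait_categorical: Iterable[str] | None = None,
    site_categorical: Iterable[str] | None = None,
) -> tuple[MetacommunityMatrix, TraitTable, SiteAttributeTable]:
    """Load and align the three input tables.

    The matrix row/column order defines the canonical entity order; trait and
    attribute tables are reindexed to it.  Missing entries raise
    :class:`AlignmentError` naming the offending labels.
    """
    m = load_matrix(matrix_path)
    traits = load_traits(traits_path, trait_categorical).align_to(m.species_ids)
    sites = load_site_attributes(sites_path, site_categorical).align_to(m.site_ids)
    return m, traits, sites


# ---------------------------------------------------------------------------
# result bundle


@dataclass
class ResultBundle:
    """Serializable results: one DataFrame per quantity plus run metadata."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)


def write_results(bundle: ResultBundle, out_dir: str | Path) -> list[str]:
    """Write each table as CSV plus a ``run_metadata.json`` record.

    Floats are serialized with ``repr`` round-trip precision, so re-running a
    seeded pipeline writes byte-identical numeric tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    for name, df in bundle.tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, float_format=lambda v: repr(float(v)))
        manifest.append(path.name)
    meta_path = out / "run_metadata.json"
    meta = dict(bundle.metadata)
    meta.setdefault("package", "ddaffinity")
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    manifest.append(meta_path.name)
    return manifest
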