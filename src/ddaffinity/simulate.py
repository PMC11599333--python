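"""Synthetic metacommunities with known dark-diversity-affinity structure.

The generator inverts the model: it draws species traits and site attributes,
maps them through logit-linear submodels with *known* coefficients to true
dda_sp / dda_site / unified DDA, combines them with a suitability surface
(i.i.d. Beta draws, or a Gaussian niche kernel along a latent gradient) and a
configured balancing constant delta, and samples the presence-absence matrix
cellwise from Bernoulli(p).  Every latent quantity is recorded in a
:class:`SyntheticTruth` so fitted posteriors can be scored against the
generating process (sign recovery, credible-interval coverage,
classification accuracy).

Delta is an *input* here (default 0) rather than the data-derived constant,
so closed-form checks exist (e.g. all-zero coefficients with suit = 0.5
give p = 0.25 in every cell); the analysis path always recomputes delta from
the data, and that mismatch is part of what recovery quantifies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import AnalysisConfig, MetacommunityMatrix, SiteAttributeTable, TraitTable
from .model import DDAModel, presence_likelihood, unified_dda
from .preprocess import build_design_matrix
from .suitability import SuitabilityMatrix

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "RecoveryReport",
    "generate_traits_and_sites",
    "generate_suitability",
    "simulate_metacommunity",
    "recovery_experiment",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything a synthetic scenario needs: sizes, predictors, truth, suit.

    ``b_sp`` / ``b_site`` give the true coefficient per design column (in
    design order: quantitative traits first, then one indicator per declared
    categorical level); unspecified coefficients default to 0.
    """

    n_species: int = 60
    n_sites: int = 40
    n_quant_traits: int = 3
    n_quant_attrs: int = 2
    cat_trait_levels: tuple[int, ...] = ()   # e.g. (3,) = one 3-level trait
    cat_attr_levels: tuple[int, ...] = ()
    a_sp: float = 0.0
    a_site: float = 0.0
    b_sp: tuple[float, ...] = ()
    b_site: tuple[float, ...] = ()
    delta: float = 0.0
    suit_source: str = "beta"        # "beta" | "niche"
    beta_params: tuple[float, float] = (2.0, 2.0)
    niche_breadth: float = 1.0
    retry_cap: int = 20

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.n_sites < 2:
            raise ValueError("need at least 2 species and 2 sites")
        if self.suit_source not in ("beta", "niche"):
            raise ValueError(f"unknown suit source {self.suit_source!r}")
        if min(self.beta_params) <= 0:
            raise ValueError("beta parameters must be positive")

    @property
    def n_trait_columns(self) -> int:
        return self.n_quant_traits + sum(self.cat_trait_levels)

    @property
    def n_attr_columns(self) -> int:
        return self.n_quant_attrs + sum(self.cat_attr_levels)

    def full_b_sp(self) -> np.ndarray:
        out = np.zeros(self.n_trait_columns)
        out[: len(self.b_sp)] = self.b_sp
        return out

    def full_b_site(self) -> np.ndarray:
        out = np.zeros(self.n_attr_columns)
        out[: len(self.b_site)] = self.b_site
        return out

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: dict[str, Any]) -> "ScenarioConfig":
        data = dict(mapping)
        for key in ("cat_trait_levels", "cat_attr_levels", "b_sp", "b_site", "beta_params"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class SyntheticTruth:
    """Generating coefficients and every latent quantity of one draw."""

    a_sp: float
    a_site: float
    b_sp: np.ndarray
    b_site: np.ndarray
    dda_sp: np.ndarray
    dda_site: np.ndarray
    dda_cell: np.ndarray
    p_cell: np.ndarray
    delta: float
    seed: int
    scenario: ScenarioConfig = field(repr=False)

    def coefficients(self, shared_intercept: bool = False) -> np.ndarray:
        a = (self.a_sp,) if shared_intercept else (self.a_sp, self.a_site)
        return np.concatenate([a, self.b_sp, self.b_site])


def _entity_table(rng, n, n_quant, cat_levels, prefix, cls):
    data: dict[str, Any] = {}
    for k in range(n_quant):
        data[f"{prefix}q{k + 1}"] = rng.standard_normal(n)
    categorical = []
    for k, n_levels in enumerate(cat_levels):
        name = f"{prefix}c{k + 1}"
        levels = [f"L{j + 1}" for j in range(n_levels)]
        data[name] = rng.choice(levels, size=n)
        categorical.append(name)
    ids = [f"{prefix}{i + 1:03d}" for i in range(n)]
    frame = pd.DataFrame(data, index=ids)
    return cls(frame, categorical=categorical)


def generate_traits_and_sites(
    cfg: ScenarioConfig, seed: int
) -> tuple[TraitTable, SiteAttributeTable]:
    """Draw species traits (std-normal / uniform-categorical) and site attributes."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 1])))
    traits = _entity_table(rng, cfg.n_species, cfg.n_quant_traits, cfg.cat_trait_levels, "sp_", TraitTable)
    sites = _entity_table(rng, cfg.n_sites, cfg.n_quant_attrs, cfg.cat_attr_levels, "site_", SiteAttributeTable)
    return traits, sites


def generate_suitability(cfg: ScenarioConfig, seed: int) -> SuitabilityMatrix:
    """Suitability surface: i.i.d. Beta cells, or a Gaussian niche kernel."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 2])))
    shape = (cfg.n_species, cfg.n_sites)
    if cfg.suit_source == "beta":
        suit = rng.beta(*cfg.beta_params, size=shape)
    else:
        sp_pos = rng.uniform(0, 1, size=cfg.n_species)
        site_pos = rng.uniform(0, 1, size=cfg.n_sites)
        d = sp_pos[:, None] - site_pos[None, :]
        suit = np.exp(-(d**2) / (2.0 * cfg.niche_breadth**2))
    species = tuple(f"sp_{i + 1:03d}" for i in range(cfg.n_species))
    sites = tuple(f"site_{j + 1:03d}" for j in range(cfg.n_sites))
    return SuitabilityMatrix(values=suit, species_ids=species, site_ids=sites, dialect="given")


def simulate_metacommunity(
    cfg: ScenarioConfig, seed: int
) -> tuple[MetacommunityMatrix, TraitTable, SiteAttributeTable, SuitabilityMatrix, SyntheticTruth]:
    """One full synthetic metacommunity plus its generating truth.

    Degenerate draws (all-present or all-absent matrices) are resampled up to
    the scenario's retry cap, then error.
    """
    traits, sites = generate_traits_and_sites(cfg, seed)
    suit = generate_suitability(cfg, seed)
    design_sp = build_design_matrix(traits)
    design_site = build_design_matrix(sites)
    b_sp = cfg.full_b_sp()[: design_sp.n_columns]
    b_site = cfg.full_b_site()[: design_site.n_columns]
    dda_sp = np.asarray(expit(cfg.a_sp + design_sp.values @ b_sp))
    dda_site = np.asarray(expit(cfg.a_site + design_site.values @ b_site))
    dda_cell = unified_dda(dda_sp[:, None], dda_site[None, :])
    p_cell = presence_likelihood(dda_cell, suit.values, cfg.delta)

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 3])))
    for _ in range(cfg.retry_cap):
        prab = (rng.random(p_cell.shape) < p_cell).astype(int)
        if 0 < prab.mean() < 1:
            break
    else:
        raise RuntimeError(f"degenerate matrix after {cfg.retry_cap} retries")
    matrix = MetacommunityMatrix(suit.species_ids, suit.site_ids, prab)
    truth = SyntheticTruth(
        a_sp=cfg.a_sp,
        a_site=cfg.a_site,
        b_sp=b_sp,
        b_site=b_site,
        dda_sp=dda_sp,
        dda_site=dda_site,
        dda_cell=dda_cell,
        p_cell=p_cell,
        delta=cfg.delta,
        seed=seed,
        scenario=cfg,
    )
    return matrix, traits, sites, suit, truth


@dataclass
class RecoveryReport:
    """Per-coefficient recovery scores plus per-replicate subset comparisons."""

    coefficients: pd.DataFrame
    subset_comparisons: pd.DataFrame

    def aggregate(self) -> dict[str, float | bool]:
        coef = self.coefficients
        injected = coef[coef["truth"] != 0]
        out: dict[str, float | bool] = {
            "pooled_coverage": float(coef["covered"].mean()),
            "null_false_significance_rate": float(
                coef.loc[coef["truth"] == 0, "significant"].mean()
            ),
            "mean_dark_classification_accuracy": float(
                coef.groupby("replicate")["dark_classification_accuracy"].first().mean()
            ),
            "all_converged": bool(coef["converged"].all()),
        }
        if len(injected):
            out["injected_sign_significance_rate"] = float(
                (injected["significant"] & injected["sign_correct"]).mean()
            )
        return out


def recovery_experiment(
    cfg: ScenarioConfig,
    n_replicates: int,
    seed: int,
    analysis: AnalysisConfig | None = None,
    use_true_suitability: bool = True,
) -> RecoveryReport:
    """Simulate-and-refit replicates; score posterior against generating truth.

    The coefficient table holds one row per (replicate, coefficient) with the
    truth, posterior mean and credible bounds, significance, sign
    correctness, CI coverage, convergence flag, and the replicate's
    dark-affine species classification accuracy (true dda_sp > 0.5 scored
    against the fitted labels).  The subset table holds each replicate's
    absent/present medians and Kruskal-Wallis tests for every model quantity.
    ``use_true_suitability=False`` runs the harder end-to-end variant where
    suitability is re-estimated from the simulated matrix.
    """
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    analysis = analysis or AnalysisConfig(burn_in=2000, thinning=6)
    root = np.random.SeedSequence(seed)
    rows: list[dict[str, Any]] = []
    subset_rows: list[pd.DataFrame] = []
    for rep in range(n_replicates):
        child = root.spawn(1)[0]
        sim_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        matrix, traits, sites, suit, truth = simulate_metacommunity(cfg, sim_seed)
        model = DDAModel(
            matrix,
            traits,
            sites,
            suitability=suit if use_true_suitability else None,
            config=analysis,
        )
        res = model.fit(seed=sim_seed + 1)
        # species whose row survived strict validation, in model order
        kept = [truth.dda_sp[suit.species_ids.index(s)] for s in model.matrix.species_ids]
        labels = res.species_affinity()["label"]
        truly_dark = np.asarray(kept) > 0.5
        accuracy = float(np.mean((labels == "dark-affine").to_numpy() == truly_dark))
        comparison = res.compare_subsets().table.reset_index()
        comparison.insert(0, "replicate", rep)
        subset_rows.append(comparison)
        true_vec = truth.coefficients(shared_intercept=analysis.shared_intercept)
        table = res.coefficient_table()
        for name, tv in zip(res.param_names, true_vec):
            r = table.loc[name]
            rows.append(
                {
                    "replicate": rep,
                    "coefficient": name,
                    "truth": float(tv),
                    "mean": float(r["mean"]),
                    "lower": float(r["lower"]),
                    "upper": float(r["upper"]),
                    "significant": bool(r["significant"]),
                    "sign_correct": bool(np.sign(r["mean"]) == np.sign(tv)) if tv != 0 else True,
                    "covered": bool(r["lower"] <= tv <= r["upper"]),
                    "converged": res.diagnostics.converged,
                    "max_rhat": res.diagnostics.max_rhat,
                    "dark_classification_accuracy": accuracy,
                }
            )
    return RecoveryReport(
        coefficients=pd.DataFrame(rows),
        subset_comparisons=pd.concat(subset_rows, ignore_index=True),
    )
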