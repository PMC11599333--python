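"""Results object returned by :meth:`DDAModel.fit`.

Carries the retained coefficient draws (chains x samples-per-chain, 999 by
default), recomputes the derived quantities (dda_sp, dda_site, DDA, presence
likelihood p) deterministically per draw, and exposes the reporting surface:
coefficient significance tables, per-entity affinity classifications,
absent/present subset comparisons, and a serializable result bundle.
"""

from __future__ import annotations

from functools import cached_property
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import ResultBundle, write_results
from .model import presence_likelihood
from .summarize import (
    SubsetComparisonResult,
    classify_affinity,
    coefficient_significance,
    compare_subsets,
    summarize_quantity,
)

if TYPE_CHECKING:  # pragma: no cover
    from .model import DDAModel, FitDiagnostics

__all__ = ["DDAResults"]


class DDAResults:
    """Posterior of one fitted species-site unified DDA model."""

    def __init__(
        self,
        model: "DDAModel",
        chain_draws: np.ndarray,
        diagnostics: "FitDiagnostics",
        seed: int,
    ):
        self.model = model
        self.chain_draws = chain_draws  # (chains, samples_per_chain, n_params)
        self.diagnostics = diagnostics
        self.seed = seed
        self.param_names = model.param_names
        self.delta = model.delta
        self.ci_level = model.config.ci_level

    # -- coefficient surface -------------------------------------------------

    @cached_property
    def draws(self) -> np.ndarray:
        """All retained draws pooled over chains, (n_draws, n_params)."""
        return self.chain_draws.reshape(-1, self.chain_draws.shape[-1])

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @cached_property
    def params(self) -> pd.Series:
        """Posterior mean per coefficient."""
        return pd.Series(self.draws.mean(axis=0), index=list(self.param_names))

    def conf_int(self, level: float | None = None) -> pd.DataFrame:
        level = self.ci_level if level is None else level
        alpha = (1 - level) / 2
        lo, hi = np.quantile(self.draws, [alpha, 1 - alpha], axis=0)
        return pd.DataFrame({"lower": lo, "upper": hi}, index=list(self.param_names))

    def coefficient_table(self, level: float | None = None) -> pd.DataFrame:
        level = self.ci_level if level is None else level
        return coefficient_significance(self.draws, self.param_names, level=level)

    # -- derived quantities --------------------------------------------------

    @cached_property
    def _linear_predictors(self) -> tuple[np.ndarray, np.ndarray]:
        a_sp, a_site, b_sp, b_site = self.model.split_params(self.draws)
        # (n_draws, n_species) and (n_draws, n_sites)
        eta_sp = a_sp[:, None] + b_sp @ self.model.design_sp.values.T
        eta_site = a_site[:, None] + b_site @ self.model.design_site.values.T
        return eta_sp, eta_site

    @cached_property
    def dda_sp_draws(self) -> np.ndarray:
        """(n_draws, n_species) posterior draws of species-side affinity."""
        return expit(self._linear_predictors[0])

    @cached_property
    def dda_site_draws(self) -> np.ndarray:
        """(n_draws, n_sites) posterior draws of site-side affinity."""
        return expit(self._linear_predictors[1])

    @cached_property
    def dda_cell_draws(self) -> np.ndarray:
        """(n_draws, n_species, n_sites) unified DDA per draw and cell."""
        eta_sp, eta_site = self._linear_predictors
        return expit(0.5 * (eta_sp[:, :, None] + eta_site[:, None, :]))

    @cached_property
    def p_cell_draws(self) -> np.ndarray:
        """(n_draws, n_species, n_sites) presence likelihood per draw and cell."""
        return presence_likelihood(
            self.dda_cell_draws,
            self.model.suitability.values[None, :, :],
            self.delta,
            eps=self.model.config.epsilon,
        )

    # -- affinity classification ---------------------------------------------

    def _affinity_frame(self, draws: np.ndarray, ids) -> pd.DataFrame:
        rows = []
        for k, label in enumerate(ids):
            med, lo, hi = summarize_quantity(draws[:, k], level=self.ci_level)
            rows.append(
                {"median": med, "lower": lo, "upper": hi, "label": classify_affinity((med, lo, hi))}
            )
        return pd.DataFrame(rows, index=list(ids))

    def species_affinity(self) -> pd.DataFrame:
        """Median/CI/label of dda_sp per species (dark-affine iff CI > 0.5)."""
        return self._affinity_frame(self.dda_sp_draws, self.model.matrix.species_ids)

    def site_affinity(self) -> pd.DataFrame:
        """Median/CI/label of dda_site per site."""
        return self._affinity_frame(self.dda_site_draws, self.model.matrix.site_ids)

    # -- subset comparison -----------------------------------------------------

    def cell_medians(self) -> dict[str, np.ndarray]:
        """Per-cell observation for each model quantity.

        suit as computed; p and DDA as per-cell posterior medians; dda_sp and
        dda_site as entity posterior medians broadcast over the entity's cells.
        """
        m = self.model.matrix
        med_sp = np.median(self.dda_sp_draws, axis=0)
        med_site = np.median(self.dda_site_draws, axis=0)
        return {
            "p": np.median(self.p_cell_draws, axis=0),
            "suit": self.model.suitability.values,
            "DDA": np.median(self.dda_cell_draws, axis=0),
            "dda_sp": np.broadcast_to(med_sp[:, None], m.prab.shape).copy(),
            "dda_site": np.broadcast_to(med_site[None, :], m.prab.shape).copy(),
        }

    def compare_subsets(self, pool_draws: bool = False) -> SubsetComparisonResult:
        draw_values = None
        if pool_draws:
            n = self.n_draws
            m = self.model.matrix
            draw_values = {
                "p": self.p_cell_draws,
                "suit": np.broadcast_to(self.model.suitability.values, (n, *m.prab.shape)),
                "DDA": self.dda_cell_draws,
                "dda_sp": np.broadcast_to(
                    self.dda_sp_draws[:, :, None], (n, *m.prab.shape)
                ),
                "dda_site": np.broadcast_to(
                    self.dda_site_draws[:, None, :], (n, *m.prab.shape)
                ),
            }
        return compare_subsets(
            self.model.matrix, self.cell_medians(), pool_draws=pool_draws, draw_values=draw_values
        )

    # -- reporting -------------------------------------------------------------

    def draws_frame(self) -> pd.DataFrame:
        """Tidy draws: chain, draw index, one column per coefficient."""
        chains, samples, dim = self.chain_draws.shape
        idx = pd.MultiIndex.from_product(
            [range(chains), range(samples)], names=["chain", "draw"]
        )
        return pd.DataFrame(
            self.chain_draws.reshape(-1, dim), index=idx, columns=list(self.param_names)
        ).reset_index()

    def summary(self) -> str:
        cfg = self.model.config
        coef = self.coefficient_table()
        lines = [
            "Species-site unified dark-diversity-affinity model",
            "=" * 58,
            f"species: {self.model.matrix.n_species}   sites: {self.model.matrix.n_sites}"
            f"   cells: {self.model.matrix.prab.size}",
            f"delta: {self.delta:.4f}   prevalence: {self.model.matrix.prab.mean():.4f}",
            f"draws: {self.n_draws} ({self.chain_draws.shape[0]} chains x "
            f"{self.chain_draws.shape[1]})   burn-in: {self.diagnostics.burn_in}"
            f"   thinning: {self.diagnostics.thinning}",
            f"max R-hat: {self.diagnostics.max_rhat:.4f}   converged: "
            f"{self.diagnostics.converged}   seed: {self.seed}",
            "-" * 58,
            coef.to_string(float_format=lambda v: f"{v: .4f}"),
            "-" * 58,
            f"priors: N({cfg.prior_mean}, {cfg.prior_scale_a}^2) on a, "
            f"N({cfg.prior_mean}, {cfg.prior_scale_b}^2) on b; CI level {cfg.ci_level}",
        ]
        return "\n".join(lines)

    def to_bundle(self) -> ResultBundle:
        tables = {
            "coefficients": self.coefficient_table(),
            "species_affinity": self.species_affinity(),
            "site_affinity": self.site_affinity(),
            "subset_comparison": self.compare_subsets().table,
            "posterior_draws": self.draws_frame(),
            "diagnostics": pd.DataFrame(
                {"rhat": pd.Series(self.diagnostics.rhat)}
            ),
        }
        metadata = {
            "seed": self.seed,
            "delta": self.delta,
            "burn_in": self.diagnostics.burn_in,
            "thinning": self.diagnostics.thinning,
            "escalations": self.diagnostics.escalations,
            "converged": self.diagnostics.converged,
            "config": self.model.config.to_dict(),
        }
        return ResultBundle(tables=tables, metadata=metadata)

    def save(self, out_dir: str | Path) -> list[str]:
        return write_results(self.to_bundle(), out_dir)
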