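"""The species-site unified dark-diversity-affinity model.

Per species-site cell, dark diversity affinity (DDA, in (0, 1) with 0.5 the
neutral threshold) combines a species-side and a site-side tendency, each a
logit-linear function of traits or attributes:

    logit(dda_sp)   = a_sp   + b_sp   . T        (species traits T)
    logit(dda_site) = a_site + b_site . E        (site attributes E)
    logit(DDA)      = [logit(dda_sp) + logit(dda_site)] / 2

so DDA odds are the geometric mean of the two component odds.  The observed
presence-absence cell prab is Bernoulli with presence likelihood

    logit(p) = logit((1 - DDA) * suit) + delta,
    delta    = logit(mean(prab)) - logit(0.5 * mean(suit)),

where suit is the co-occurrence-based suitability of the cell and delta is a
metacommunity constant balancing p to the observed prevalence: when DDA is
neutral (0.5 everywhere) and suit is constant, p equals the observed
prevalence exactly.  Coefficients get independent normal priors, mean 0,
standard deviation 0.5 for intercepts (a) and 2.5 for slopes (b); posterior
sampling is by seeded adaptive Metropolis with Gelman-Rubin gating (R-hat
<= 1.1, escalating burn-in and thinning on failure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy.special import expit, log_expit, logit

from .data import (
    AnalysisConfig,
    MetacommunityMatrix,
    SiteAttributeTable,
    TraitTable,
    load_metacommunity,
    validate_dataset,
)
from .mcmc import gelman_rubin_rhat, run_chains
from .preprocess import DesignMatrix, build_design_matrix
from .suitability import SuitabilityMatrix, suitability_matrix

logger = logging.getLogger("ddaffinity")

__all__ = [
    "PriorSpec",
    "FitDiagnostics",
    "DDAModel",
    "dda_from_design",
    "unified_dda",
    "compute_delta",
    "presence_likelihood",
    "log_joint_density",
]


def _clamp(x: np.ndarray | float, eps: float) -> np.ndarray:
    return np.clip(x, eps, 1.0 - eps)


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors: mean 0; sd 0.5 for a, 2.5 for b."""

    mean: float = 0.0
    scale_a: float = 0.5
    scale_b: float = 2.5

    def __post_init__(self) -> None:
        if self.scale_a <= 0 or self.scale_b <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class FitDiagnostics:
    rhat: dict[str, float]
    burn_in: int
    thinning: int
    escalations: int
    converged: bool

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


# ---------------------------------------------------------------------------
# elementary model operations


def dda_from_design(row: np.ndarray, a: float, b: np.ndarray) -> float | np.ndarray:
    """Inverse-logit of the linear predictor a + row . b."""
    row = np.atleast_1d(np.asarray(row, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if row.shape[-1] != b.shape[-1]:
        raise ValueError(f"design row has {row.shape[-1]} columns but b has {b.shape[-1]}")
    out = expit(a + row @ b)
    return float(out) if np.isscalar(a) and out.ndim == 0 else out


def unified_dda(
    dda_sp: np.ndarray | float, dda_site: np.ndarray | float, eps: float = 1e-6
) -> np.ndarray | float:
    """Combine the two affinities on the logit scale (geometric mean of odds)."""
    sp = _clamp(np.asarray(dda_sp, dtype=float), eps)
    site = _clamp(np.asarray(dda_site, dtype=float), eps)
    out = expit((logit(sp) + logit(site)) / 2.0)
    return float(out) if out.ndim == 0 else out


def compute_delta(prab: np.ndarray, suit: np.ndarray) -> float:
    """Metacommunity balancing constant logit(mean prab) - logit(0.5 mean suit)."""
    prab = np.asarray(prab, dtype=float).ravel()
    suit = np.asarray(suit, dtype=float).ravel()
    prev = prab.mean()
    if not (0.0 < prev < 1.0):
        raise ValueError("delta is undefined for an all-present or all-absent matrix")
    ms = suit.mean()
    if ms <= 0:
        raise ValueError("delta is undefined when mean suitability is 0")
    return float(logit(prev) - logit(0.5 * ms))


def presence_likelihood(
    dda: np.ndarray | float,
    suit: np.ndarray | float,
    delta: float,
    eps: float = 1e-6,
) -> np.ndarray | float:
    """Presence probability logit^-1(logit((1 - DDA) * suit) + delta)."""
    q = _clamp(np.asarray((1.0 - np.asarray(dda, dtype=float)) * suit, dtype=float), eps)
    out = expit(logit(q) + delta)
    return float(out) if out.ndim == 0 else out


def log_joint_density(
    params: np.ndarray,
    prab: np.ndarray,
    suit: np.ndarray,
    design_sp: np.ndarray,
    design_site: np.ndarray,
    delta: float,
    priors: PriorSpec = PriorSpec(),
    eps: float = 1e-6,
    shared_intercept: bool = False,
) -> float:
    """Normal log-priors plus the Bernoulli cellwise log-likelihood.

    ``params`` packs [a_sp, a_site, b_sp..., b_site...] (a single shared
    intercept when ``shared_intercept``).  The likelihood composes the full
    model: design rows -> dda_sp/dda_site -> unified DDA -> presence
    likelihood with the data-fixed delta -> Bernoulli(prab | p).
    """
    params = np.asarray(params, dtype=float)
    k_sp = design_sp.shape[1]
    k_site = design_site.shape[1]
    n_a = 1 if shared_intercept else 2
    if params.size != n_a + k_sp + k_site:
        raise ValueError(
            f"expected {n_a + k_sp + k_site} parameters, got {params.size}"
        )
    if shared_intercept:
        a_sp = a_site = params[0]
    else:
        a_sp, a_site = params[0], params[1]
    b_sp = params[n_a : n_a + k_sp]
    b_site = params[n_a + k_sp :]

    eta_sp = a_sp + design_sp @ b_sp          # logit(dda_sp) per species
    eta_site = a_site + design_site @ b_site  # logit(dda_site) per site
    logit_dda = 0.5 * (eta_sp[:, None] + eta_site[None, :])
    dda = expit(logit_dda)
    q = _clamp((1.0 - dda) * suit, eps)
    logit_p = logit(q) + delta
    loglik = float(
        np.sum(prab * log_expit(logit_p) + (1.0 - prab) * log_expit(-logit_p))
    )
    a_vals = params[:n_a]
    logprior = float(
        -0.5 * np.sum(((a_vals - priors.mean) / priors.scale_a) ** 2)
        - a_vals.size * np.log(priors.scale_a * np.sqrt(2 * np.pi))
        - 0.5 * np.sum(((params[n_a:] - priors.mean) / priors.scale_b) ** 2)
        - (k_sp + k_site) * np.log(priors.scale_b * np.sqrt(2 * np.pi))
    )
    out = logprior + loglik
    if not np.isfinite(out):
        raise FloatingPointError("non-finite log joint density")
    return out


# ---------------------------------------------------------------------------
# model object


class DDAModel:
    """Species-site unified DDA model bound to one metacommunity.

    Parameters
    ----------
    matrix : MetacommunityMatrix
        Binary presence-absence matrix.  All-zero rows/columns are removed
        (with a logged warning) before anything else.
    traits, site_attributes : TraitTable / SiteAttributeTable or None
        Predictor tables; ``None`` fits an intercept-only submodel on that
        side.
    suitability : SuitabilityMatrix, ndarray or None
        Cellwise suitability; estimated from the matrix co-occurrence
        structure when not supplied.
    config : AnalysisConfig
        Priors, MCMC schedule, clamp epsilon, CI level, dialect.
    """

    def __init__(
        self,
        matrix: MetacommunityMatrix,
        traits: TraitTable | None = None,
        site_attributes: SiteAttributeTable | None = None,
        suitability: SuitabilityMatrix | np.ndarray | None = None,
        config: AnalysisConfig | None = None,
        trait_levels: dict[str, list[str]] | None = None,
        site_levels: dict[str, list[str]] | None = None,
    ):
        self.config = config or AnalysisConfig()
        report = validate_dataset(matrix, strict=True)
        self.matrix = report.matrix
        if report.degenerate_no_absences:
            raise ValueError("matrix has no absences; the model is undefined")

        if suitability is None:
            self.suitability = suitability_matrix(
                self.matrix, dialect=self.config.suitability_dialect
            )
        elif isinstance(suitability, SuitabilityMatrix):
            if suitability.species_ids != matrix.species_ids or suitability.site_ids != matrix.site_ids:
                raise ValueError("suitability matrix entity order differs from prab matrix")
            if self.matrix.species_ids != matrix.species_ids or self.matrix.site_ids != matrix.site_ids:
                # strict validation dropped entities: subset the given suit
                sp_idx = [matrix.species_ids.index(s) for s in self.matrix.species_ids]
                site_idx = [matrix.site_ids.index(s) for s in self.matrix.site_ids]
                suitability = SuitabilityMatrix(
                    values=suitability.values[np.ix_(sp_idx, site_idx)],
                    species_ids=self.matrix.species_ids,
                    site_ids=self.matrix.site_ids,
                    dialect=suitability.dialect,
                )
            self.suitability = suitability
        else:
            values = np.asarray(suitability, dtype=float)
            if values.shape != self.matrix.prab.shape:
                raise ValueError("suitability array shape differs from prab matrix")
            self.suitability = SuitabilityMatrix(
                values=values,
                species_ids=self.matrix.species_ids,
                site_ids=self.matrix.site_ids,
                dialect="given",
            )

        self.traits = traits.align_to(self.matrix.species_ids) if traits is not None else None
        self.site_attributes = (
            site_attributes.align_to(self.matrix.site_ids) if site_attributes is not None else None
        )
        self.design_sp = self._design(self.traits, self.matrix.species_ids, trait_levels)
        self.design_site = self._design(
            self.site_attributes, self.matrix.site_ids, site_levels
        )
        self.priors = PriorSpec(
            mean=self.config.prior_mean,
            scale_a=self.config.prior_scale_a,
            scale_b=self.config.prior_scale_b,
        )
        self.delta = compute_delta(self.matrix.prab, self.suitability.values)

    @staticmethod
    def _design(table, ids, levels) -> DesignMatrix:
        if table is None:
            return DesignMatrix(entity_ids=tuple(ids), columns=(), values=np.empty((len(ids), 0)))
        return build_design_matrix(table, levels=levels)

    @classmethod
    def from_files(
        cls,
        matrix_path: str | Path,
        traits_path: str | Path | None = None,
        sites_path: str | Path | None = None,
        config: AnalysisConfig | None = None,
        **kwargs: Any,
    ) -> "DDAModel":
        from .data import load_matrix, load_site_attributes, load_traits

        if traits_path is not None and sites_path is not None:
            m, traits, sites = load_metacommunity(matrix_path, traits_path, sites_path)
        else:
            m = load_matrix(matrix_path)
            traits = load_traits(traits_path) if traits_path else None
            sites = load_site_attributes(sites_path) if sites_path else None
        return cls(m, traits, sites, config=config, **kwargs)

    # -- parameter bookkeeping ---------------------------------------------

    @property
    def param_names(self) -> tuple[str, ...]:
        a = ("a",) if self.config.shared_intercept else ("a_sp", "a_site")
        return (
            a
            + tuple(f"b_sp:{c}" for c in self.design_sp.column_names)
            + tuple(f"b_site:{c}" for c in self.design_site.column_names)
        )

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def split_params(self, params: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
        params = np.asarray(params, dtype=float)
        n_a = 1 if self.config.shared_intercept else 2
        a_sp = params[..., 0]
        a_site = params[..., 0] if self.config.shared_intercept else params[..., 1]
        k_sp = self.design_sp.n_columns
        return (
            a_sp,
            a_site,
            params[..., n_a : n_a + k_sp],
            params[..., n_a + k_sp :],
        )

    def log_joint(self, params: np.ndarray) -> float:
        return log_joint_density(
            params,
            prab=self.matrix.prab,
            suit=self.suitability.values,
            design_sp=self.design_sp.values,
            design_site=self.design_site.values,
            delta=self.delta,
            priors=self.priors,
            eps=self.config.epsilon,
            shared_intercept=self.config.shared_intercept,
        )

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int | None = None) -> "DDAResults":
        """Sample the posterior; escalate the schedule until R-hat <= 1.1.

        On R-hat failure the burn-in and thinning are multiplied by the
        configured escalation factor, capped at ``max_burn_in`` /
        ``max_thinning``; if the capped schedule still fails, the results are
        returned with ``diagnostics.converged = False`` (never silently).
        """
        from .results import DDAResults

        if seed is None:
            seed = self.config.seed
        if seed is None:
            raise ValueError("fit() needs a seed (argument or config.seed)")
        cfg = self.config
        burn, thin = cfg.burn_in, cfg.thinning
        root = np.random.SeedSequence(seed)
        escalations = 0
        converged = False
        while True:
            attempt_seed = root.spawn(1)[0]  # fresh, deterministic child per attempt
            draws = run_chains(
                self.log_joint,
                dim=self.n_params,
                n_chains=cfg.chains,
                n_samples=cfg.samples_per_chain,
                burn_in=burn,
                thinning=thin,
                seed=attempt_seed,
            )
            rhat = {
                name: gelman_rubin_rhat(draws[:, :, k])
                for k, name in enumerate(self.param_names)
            }
            if max(rhat.values()) <= cfg.rhat_threshold:
                converged = True
                break
            new_burn = min(burn * cfg.escalation_factor, cfg.max_burn_in)
            new_thin = min(thin * cfg.escalation_factor, cfg.max_thinning)
            if (new_burn, new_thin) == (burn, thin):
                logger.error(
                    "MCMC failed to converge at the schedule ceiling "
                    "(burn-in %d, thinning %d, max R-hat %.3f)",
                    burn, thin, max(rhat.values()),
                )
                break
            burn, thin = new_burn, new_thin
            escalations += 1
            logger.warning(
                "R-hat %.3f > %.2f; escalating to burn-in %d, thinning %d",
                max(rhat.values()), cfg.rhat_threshold, burn, thin,
            )
        diagnostics = FitDiagnostics(
            rhat=rhat, burn_in=burn, thinning=thin,
            escalations=escalations, converged=converged,
        )
        return DDAResults(model=self, chain_draws=draws, diagnostics=diagnostics, seed=seed)
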