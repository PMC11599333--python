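"""Suitability: hypergeometric SES against an exhaustive-enumeration oracle,
and the cellwise aggregation against a direct double-loop implementation."""

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import norm

from ddaffinity import (
    MetacommunityMatrix,
    pairwise_cooccurrence_ses,
    suitability_matrix,
)
from conftest import random_binary_matrix


def enumerated_cooccurrence_moments(n_sites, n_i, n_j):
    """Mean/variance of overlap over all placements of two occupancy sets."""
    overlaps = [
        len(set(a) & set(b))
        for a in combinations(range(n_sites), n_i)
        for b in combinations(range(n_sites), n_j)
    ]
    arr = np.array(overlaps, dtype=float)
    return arr.mean(), arr.var()  # population variance over the uniform ensemble


def brute_force_suitability(m, dialect="minmax"):
    """Direct double loop over pairs and cells; the independent oracle."""
    prab = m.prab
    S, N = prab.shape
    occ = prab.sum(axis=1)
    ses = np.zeros((S, S))
    for i in range(S):
        for j in range(S):
            mu = occ[i] * occ[j] / N
            var = occ[i] * occ[j] * (N - occ[i]) * (N - occ[j]) / (N**2 * (N - 1))
            c = int(np.sum(prab[i] & prab[j]))
            ses[i, j] = 0.0 if var == 0 else (c - mu) / np.sqrt(var)
    raw = np.zeros((S, N))
    for i in range(S):
        for s in range(N):
            vals = [ses[i, j] for j in range(S) if j != i and prab[j, s] == 1]
            raw[i, s] = np.mean(vals) if vals else 0.0
    if dialect == "normcdf":
        return norm.cdf(raw)
    lo, hi = raw.min(), raw.max()
    return np.full_like(raw, 0.5) if hi == lo else (raw - lo) / (hi - lo)


class TestPairwiseSES:
    def test_ses_matches_exhaustive_enumeration_moments(self):
        # N=4 sites, both species in 2 sites, co-occurring in both
        prab = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        m = MetacommunityMatrix(("a", "b", "c"), ("s1", "s2", "s3", "s4"), prab)
        mu, var = enumerated_cooccurrence_moments(4, 2, 2)
        assert mu == pytest.approx(1.0)
        assert var == pytest.approx(1 / 3)
        ses = pairwise_cooccurrence_ses(m).ses
        assert ses[0, 1] == pytest.approx((2 - mu) / np.sqrt(var))
        assert ses[0, 1] == pytest.approx(np.sqrt(3), abs=1e-4)

    def test_observed_equal_to_mean_gives_zero(self):
        prab = np.array([[1, 1, 0, 0], [1, 0, 1, 0]])
        m = MetacommunityMatrix(("a", "b"), ("s1", "s2", "s3", "s4"), prab)
        assert pairwise_cooccurrence_ses(m).ses[0, 1] == 0.0

    def test_full_occupancy_has_zero_variance_and_zero_ses(self):
        prab = np.array([[1, 1, 1, 1], [1, 0, 1, 0]])
        m = MetacommunityMatrix(("a", "b"), ("s1", "s2", "s3", "s4"), prab)
        assert pairwise_cooccurrence_ses(m).ses[0, 1] == 0.0

    def test_moment_formulas_match_enumeration_for_all_small_margins(self):
        N = 5
        for n_i in range(1, N + 1):
            for n_j in range(1, N + 1):
                mu, var = enumerated_cooccurrence_moments(N, n_i, n_j)
                assert mu == pytest.approx(n_i * n_j / N, abs=1e-12)
                expected_var = n_i * n_j * (N - n_i) * (N - n_j) / (N**2 * (N - 1))
                assert var == pytest.approx(expected_var, abs=1e-12)

    def test_symmetry(self, rng):
        m = random_binary_matrix(rng, 6, 6)
        ses = pairwise_cooccurrence_ses(m).ses
        np.testing.assert_allclose(ses, ses.T, atol=1e-12)

    def test_occupancy_complement_negates_ses(self, rng):
        """Complementing one species' occupancy vector flips the sign of its
        pairwise SES: the centered co-occurrence negates while the variance
        is unchanged (n_i -> N - n_i)."""
        for _ in range(10):
            m = random_binary_matrix(rng, 6, 6)
            ses = pairwise_cooccurrence_ses(m).ses
            prab = m.prab.copy()
            prab[0] = 1 - prab[0]
            flipped = MetacommunityMatrix(m.species_ids, m.site_ids, prab)
            ses_f = pairwise_cooccurrence_ses(flipped).ses
            np.testing.assert_allclose(ses_f[0, 1:], -ses[0, 1:], atol=1e-10)


class TestSuitabilityMatrix:
    def test_lonely_species_site_gives_phi_zero(self):
        # site s3 contains only species a itself -> raw score 0 -> CDF 0.5
        prab = np.array([[1, 1, 1], [1, 1, 0], [0, 1, 0]])
        m = MetacommunityMatrix(("a", "b", "c"), ("s1", "s2", "s3"), prab)
        suit = suitability_matrix(m, dialect="normcdf")
        assert suit.values[0, 2] == pytest.approx(0.5)

    @pytest.mark.parametrize("dialect", ["minmax", "normcdf"])
    def test_matches_brute_force_oracle(self, rng, dialect):
        for _ in range(20):
            m = random_binary_matrix(rng, 5, 5)
            ours = suitability_matrix(m, dialect=dialect).values
            np.testing.assert_allclose(ours, brute_force_suitability(m, dialect), atol=1e-10)

    def test_dialects_are_rank_equivalent(self, rng):
        m = random_binary_matrix(rng, 7, 6)
        a = suitability_matrix(m, dialect="minmax").values.ravel()
        b = suitability_matrix(m, dialect="normcdf").values.ravel()
        order = np.argsort(a, kind="stable")
        assert np.all(np.diff(b[order]) >= -1e-12)  # same ordering up to FP ties

    def test_unknown_dialect_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="dialect"):
            suitability_matrix(small_matrix, dialect="bogus")

    def test_values_in_unit_interval(self, rng):
        for _ in range(5):
            m = random_binary_matrix(rng, 8, 7)
            v = suitability_matrix(m).values
            assert v.min() >= 0 and v.max() <= 1

    def test_niche_structure_raises_present_cell_suitability(self, rng):
        # strong positive cell-wise structure: present cells should be the
        # more suitable ones on average (the qualitative field pattern)
        from ddaffinity import ScenarioConfig, simulate_metacommunity

        cfg = ScenarioConfig(
            n_species=30, n_sites=20, n_quant_traits=0, n_quant_attrs=0,
            suit_source="niche", niche_breadth=0.15, delta=1.0,
        )
        m, *_ = simulate_metacommunity(cfg, 11)
        from ddaffinity import validate_dataset

        m = validate_dataset(m, strict=True).matrix
        suit = suitability_matrix(m).values
        present = suit[m.prab == 1].mean()
        absent = suit[m.prab == 0].mean()
        assert present > absent
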