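import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import epiwalsh as ew
from epiwalsh import fit_additive, partition_variance, reconstruct, walsh_encode
from epiwalsh.gpmap import EncodedGenotypes
from epiwalsh.linear import decompose

from conftest import binary_map


def random_binary_map(L, rng, **kwargs):
    return binary_map(L, rng.normal(size=2**L), **kwargs)


class TestAdditiveModel:
    def test_toy_map_average_effects(self, toy_map):
        # brute force: site 1 effect = ((P10-P00)+(P11-P01))/2, etc.
        add = fit_additive(toy_map)
        np.testing.assert_allclose(add.avg_effects, [0.5, 1.5])
        assert add.intercept == 0.0
        np.testing.assert_allclose(add.p_add, [0.0, 1.5, 0.5, 2.0])

    def test_purely_additive_map_recovers_effects_exactly(self):
        a, b, c = 0.7, -1.3, 0.4
        genotypes = ["".join(g) for g in itertools.product("01", repeat=3)]
        phen = [a * int(g[0]) + b * int(g[1]) + c * int(g[2]) + 2.0 for g in genotypes]
        add = fit_additive(binary_map(3, phen))
        np.testing.assert_allclose(add.avg_effects, [a, b, c], atol=1e-12)
        np.testing.assert_allclose(add.p_add, phen, atol=1e-12)

    def test_constant_map_has_zero_effects(self):
        add = fit_additive(binary_map(3, np.full(8, 5.0)))
        np.testing.assert_array_equal(add.avg_effects, 0.0)

    def test_wildtype_prediction_equals_intercept(self, rng):
        m = random_binary_map(4, rng)
        add = fit_additive(m)
        wt_idx = m.genotypes.index(m.wildtype)
        assert add.p_add[wt_idx] == add.intercept == m.phenotypes[wt_idx]


class TestDecompose:
    def test_toy_map_walsh_coefficients(self, toy_map):
        # brute force: beta = X^T P / 4 for the 4x4 Hadamard design
        coefs = decompose(toy_map.phenotypes, walsh_encode(toy_map))
        np.testing.assert_allclose(coefs.values, [1.25, 0.25, 0.75, -0.25])
        assert coefs.values[-1] < 0  # negative epistasis
        assert list(coefs.orders) == [0, 1, 1, 2]

    @pytest.mark.parametrize("L", [3, 4, 5])
    def test_decompose_reconstruct_identity(self, L, rng):
        m = random_binary_map(L, rng)
        design = walsh_encode(m)
        coefs = decompose(m.phenotypes, design)
        back = reconstruct(coefs, design)
        span = np.ptp(m.phenotypes)
        assert np.max(np.abs(back - m.phenotypes)) <= 1e-9 * span

    @pytest.mark.parametrize("L", [3, 4, 5])
    def test_first_order_walsh_equals_half_average_effect(self, L, rng):
        m = random_binary_map(L, rng)
        coefs = decompose(m.phenotypes, walsh_encode(m))
        add = fit_additive(m)
        np.testing.assert_allclose(
            coefs.values[coefs.orders == 1], add.avg_effects / 2, atol=1e-12
        )

    def test_known_coefficients_round_trip_exactly(self, rng):
        m = binary_map(4, np.zeros(16))
        design = walsh_encode(m)
        beta = rng.normal(size=design.n_columns)
        phen = design.matrix @ beta
        np.testing.assert_allclose(
            decompose(phen, design).values, beta, atol=1e-12
        )

    def test_truncated_design_uses_least_squares(self, rng):
        m = random_binary_map(4, rng)
        design = walsh_encode(m, max_order=2)
        coefs = decompose(m.phenotypes, design)
        # OLS on an orthogonal sub-design equals the full-design projection
        full = decompose(m.phenotypes, walsh_encode(m))
        np.testing.assert_allclose(coefs.values, full.values[full.orders <= 2], atol=1e-10)

    def test_rank_deficient_design_reports_collinear_columns(self, rng):
        m = random_binary_map(3, rng)
        enc = walsh_encode(m, max_order=1)
        dup = EncodedGenotypes(
            matrix=np.column_stack([enc.matrix, enc.matrix[:, -1]]),
            labels=enc.labels + (enc.labels[-1],),
            orders=np.append(enc.orders, enc.orders[-1]),
            site_arity=enc.site_arity,
        )
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            decompose(m.phenotypes, dup)

    def test_reconstruct_dimension_mismatch(self, toy_map, rng):
        coefs = decompose(toy_map.phenotypes, walsh_encode(toy_map))
        other = walsh_encode(binary_map(3, np.zeros(8)))
        with pytest.raises(ValueError, match="coefficients"):
            reconstruct(coefs, other)


class TestVariancePartition:
    def test_purely_additive_map(self):
        genotypes = ["".join(g) for g in itertools.product("01", repeat=5)]
        phen = [sum(int(x) * w for x, w in zip(g, [1, 2, -1, 0.5, 3])) for g in genotypes]
        part = partition_variance(np.array(phen), binary_map(5, phen))
        np.testing.assert_allclose(part.contributions[0], 1.0, atol=1e-9)
        np.testing.assert_allclose(part.contributions[1:], 0.0, atol=1e-9)

    def test_three_way_only_map_against_truncated_oracle(self, rng):
        m = binary_map(5, np.zeros(32))
        design = walsh_encode(m)
        beta = np.zeros(design.n_columns)
        beta[0] = 1.0
        three_way = np.nonzero(design.orders == 3)[0]
        beta[three_way[rng.integers(len(three_way))]] = 0.8
        phen = design.matrix @ beta
        part = partition_variance(phen, m)
        np.testing.assert_allclose(part.contributions[:2], 0.0, atol=1e-9)
        assert part.contributions[2] > 0.99
        np.testing.assert_allclose(part.contributions[3:], 0.0, atol=1e-9)
        # independent oracle: explicit truncated least-squares fits
        X = design.matrix.astype(float)
        fits = [0.0]
        for k in range(1, 6):
            Xk = X[:, design.orders <= k]
            bk, *_ = np.linalg.lstsq(Xk, phen, rcond=None)
            fitted = Xk @ bk
            sst = np.sum((phen - phen.mean()) ** 2)
            fits.append(1.0 - np.sum((phen - fitted) ** 2) / sst)
        np.testing.assert_allclose(part.contributions, np.diff(fits), atol=1e-9)

    def test_full_model_fit_is_one(self, rng):
        m = random_binary_map(4, rng)
        part = partition_variance(m.phenotypes, m)
        np.testing.assert_allclose(part.cumulative[-1], 1.0, atol=1e-9)
        np.testing.assert_allclose(part.contributions.sum(), 1.0, atol=1e-9)

    def test_constant_shift_invariance(self, rng):
        m = random_binary_map(4, rng)
        p1 = partition_variance(m.phenotypes, m)
        p2 = partition_variance(m.phenotypes + 100.0, m)
        np.testing.assert_allclose(p1.contributions, p2.contributions, atol=1e-8)

    def test_cumulative_fit_monotone(self, rng):
        for seed in range(5):
            m = random_binary_map(5, np.random.default_rng(seed))
            part = partition_variance(m.phenotypes, m)
            assert np.all(np.diff(part.cumulative) >= -1e-12)
            assert np.all(part.contributions >= -1e-12)
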