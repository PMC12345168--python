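import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ptrkit.correlation import (
    PairMatrix,
    binned_scatter,
    compare_protein_vs_mrna_conservation,
    fit_r_squared,
    pairwise_ortholog_matrix,
    spearman,
)
from ptrkit.errors import FitError, UndefinedCorrelationError
from ptrkit.io_tables import OrthologMap

from conftest import make_pair


def oracle_spearman(x, y):
    """Naive rank-then-Pearson with explicit average ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks
    rx, ry = avg_ranks(x), avg_ranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def oracle_ols_r2(x, y):
    """Normal-equations OLS of y on x."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sst = ((y - y.mean()) ** 2).sum()
    return beta, 1.0 - (resid**2).sum() / sst


class TestSpearman:
    def test_perfect_positive(self):
        assert spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_tied_example(self):
        # average ranks [1, 2.5, 2.5, 4] vs [1, 2, 3, 4]
        res = spearman([1, 2, 2, 3], [1, 2, 3, 4])
        assert res.rho == pytest.approx(4.5 / np.sqrt(4.5 * 5.0), abs=1e-12)

    def test_too_short(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 2], [3, 4])

    def test_constant_vector(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman(x, sps.rankdata(y)).rho == pytest.approx(base, abs=1e-12)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(3, 51)
            x = rng.integers(0, 10, size=n).astype(float)  # ties likely
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                x[0] += 1
            assert spearman(x, y).rho == pytest.approx(oracle_spearman(x, y), abs=1e-12)


class TestFitRSquared:
    def test_exact_line(self):
        x = np.arange(5.0)
        assert fit_r_squared(x, 2 * x + 1).r_squared == pytest.approx(1.0)

    def test_three_point_hand_ols(self):
        res = fit_r_squared([0.0, 1.0, 2.0], [0.0, 1.0, 1.0])
        assert res.r_squared == pytest.approx(0.75, abs=1e-12)

    def test_independent_noise_r2_near_zero(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=10_000)
            y = rng.normal(size=10_000)
            vals.append(fit_r_squared(x, y).r_squared)
        assert np.mean(vals) < 0.02

    def test_zero_variance_x(self):
        with pytest.raises(FitError):
            fit_r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(3, 51)
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            _, r2 = oracle_ols_r2(x, y)
            assert fit_r_squared(x, y).r_squared == pytest.approx(r2, abs=1e-12)


class TestBinnedScatter:
    def test_single_cell(self):
        grid = binned_scatter([0.5] * 4, [0.5] * 4, [0, 1, 2], [0, 1, 2])
        assert grid[0, 0] == 4
        assert grid.sum() == 4

    def test_conservation_with_out_of_range_points(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 5, 500)
        y = rng.normal(0, 5, 500)
        grid = binned_scatter(x, y, np.linspace(-2, 2, 5), np.linspace(-2, 2, 5))
        assert grid.sum() == 500

    def test_translation_equivariance(self):
        x = np.array([0.5, 1.5, 2.5])
        y = np.array([0.5, 0.5, 0.5])
        edges = np.arange(0.0, 5.0)
        g1 = binned_scatter(x, y, edges, edges)
        g2 = binned_scatter(x + 1, y, edges, edges)
        assert np.array_equal(g1[:-1, :], g2[1:, :])

    def test_non_monotone_edges(self):
        with pytest.raises(ValueError):
            binned_scatter([1.0], [1.0], [0, 2, 1], [0, 1, 2])


class TestPairwiseOrthologMatrix:
    def _three_condition_setup(self):
        # nested ortholog sets: c1 has OG1-6, c2 has OG1-4, c3 has OG1-2
        groups = {}
        for j in range(1, 7):
            members = {"c1": [f"c1_g{j}"]}
            if j <= 4:
                members["c2"] = [f"c2_g{j}"]
            if j <= 2:
                members["c3"] = [f"c3_g{j}"]
            groups[f"OG{j}"] = members
        omap = OrthologMap(groups, condition_ids=["c1", "c2", "c3"])
        rng = np.random.default_rng(2)
        pairs = {}
        for cond, n in (("c1", 6), ("c2", 4), ("c3", 2)):
            ids = [f"{cond}_g{j}" for j in range(1, n + 1)]
            pairs[cond] = make_pair(cond, ids, rng.normal(size=n), rng.normal(size=n))
        return pairs, omap

    def test_counts_match_brute_force_intersections(self):
        pairs, omap = self._three_condition_setup()
        counts, _ = pairwise_ortholog_matrix(pairs, omap, "mrna")
        assert counts.values.loc["c1", "c2"] == 4
        assert counts.values.loc["c1", "c3"] == 2
        assert counts.values.loc["c2", "c3"] == 2

    def test_symmetry_and_undefined_marker(self):
        pairs, omap = self._three_condition_setup()
        counts, rho = pairwise_ortholog_matrix(pairs, omap, "protein")
        assert np.array_equal(counts.values.values, counts.values.values.T)
        # c3 shares only 2 orthologs with anyone -> NaN rho, not an exception
        assert np.isnan(rho.values.loc["c1", "c3"])
        assert np.isnan(rho.values.loc["c2", "c3"])

    def test_identical_vectors_give_rho_one(self):
        omap = OrthologMap(
            {f"OG{j}": {"c1": [f"c1_g{j}"], "c2": [f"c2_g{j}"]} for j in range(5)},
            condition_ids=["c1", "c2"],
        )
        vals = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        pairs = {
            "c1": make_pair("c1", [f"c1_g{j}" for j in range(5)], vals, vals),
            "c2": make_pair("c2", [f"c2_g{j}" for j in range(5)], vals, vals),
        }
        _, rho = pairwise_ortholog_matrix(pairs, omap, "mrna")
        assert rho.values.loc["c1", "c2"] == pytest.approx(1.0)

    def test_multi_copy_excluded(self, tiny_orthomap):
        pairs = {
            "cA": make_pair("cA", ["a1", "a2", "a3"], [1, 2, 3], [1, 2, 3]),
            "cB": make_pair("cB", ["b1", "b2", "b3"], [1, 2, 3], [1, 2, 3]),
        }
        counts, _ = pairwise_ortholog_matrix(pairs, tiny_orthomap, "mrna")
        # OG2 is multi-copy in cA, OG3 absent from cA -> only OG1 shared
        assert counts.values.loc["cA", "cB"] == 1


def _matrix(labels, values):
    df = pd.DataFrame(values, index=labels, columns=labels)
    return PairMatrix(labels, df, "mrna", "rho")


class TestConservationComparison:
    def test_identical_matrices_degenerate(self):
        labels = ["a", "b", "c"]
        m = _matrix(labels, np.ones((3, 3)) * 0.5)
        wins, res = compare_protein_vs_mrna_conservation(m, _matrix(labels, np.ones((3, 3)) * 0.5))
        assert wins == 0
        assert res.degenerate

    def test_uniform_improvement_nine_conditions(self):
        labels = [f"c{i}" for i in range(9)]
        rng = np.random.default_rng(3)
        base = rng.uniform(0.3, 0.6, size=(9, 9))
        base = (base + base.T) / 2
        mrna = _matrix(labels, base)
        prot = _matrix(labels, base + 0.1)
        wins, res = compare_protein_vs_mrna_conservation(mrna, prot)
        assert wins == 36
        assert res.p_value == pytest.approx(2.0**-36)

    def test_34_of_36_wins_counted(self):
        labels = [f"c{i}" for i in range(9)]
        rng = np.random.default_rng(4)
        base = rng.uniform(0.3, 0.6, size=(9, 9))
        base = (base + base.T) / 2
        delta = np.full((9, 9), 0.1)
        # make exactly two off-diagonal pairs lose
        delta[0, 1] = delta[1, 0] = -0.05
        delta[2, 3] = delta[3, 2] = -0.05
        wins, _ = compare_protein_vs_mrna_conservation(
            _matrix(labels, base), _matrix(labels, base + delta)
        )
        assert wins == 34

    def test_label_mismatch(self):
        with pytest.raises(ValueError):
            compare_protein_vs_mrna_conservation(
                _matrix(["a", "b", "c"], np.eye(3)), _matrix(["a", "b", "d"], np.eye(3))
            )
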