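"""PRCC sensitivity: sampling, the coefficient itself, rankings."""

import numpy as np
import pytest
from scipy import stats

from vegfnet.params import ParameterSet
from vegfnet.sensitivity import (ConstantColumnError, PrccResult,
                                 SensitivitySpec, prcc, rank_report,
                                 run_prcc, sample_parameters)


@pytest.fixture()
def ps3():
    p = ParameterSet()
    p.exprs.update({"a": "1.0", "b": "10.0", "c": "0.5"})
    return p


def brute_force_prcc(design, y):
    """Independent small-scale implementation built from explicit rank
    regressions (numpy polyfit-style normal equations)."""
    n, k = design.shape
    R = np.column_stack([stats.rankdata(design[:, j]) for j in range(k)])
    ry = stats.rankdata(y)
    out = []
    for j in range(k):
        X = np.column_stack([np.ones(n), np.delete(R, j, axis=1)])
        px = X @ np.linalg.solve(X.T @ X, X.T @ R[:, j])
        py = X @ np.linalg.solve(X.T @ X, X.T @ ry)
        ex, ey = R[:, j] - px, ry - py
        out.append(np.sum(ex * ey) / np.sqrt(np.sum(ex**2) * np.sum(ey**2)))
    return np.array(out)


class TestSampling:
    def test_range_and_reproducibility(self, ps3):
        spec = SensitivitySpec(["a", "b", "c"], n_samples=500, seed=42)
        d1 = sample_parameters(spec, ps3)
        d2 = sample_parameters(spec, ps3)
        assert np.array_equal(d1, d2)
        for j, name in enumerate(spec.parameters):
            v = ps3.get(name)
            assert d1[:, j].min() >= 0.01 * v
            assert d1[:, j].max() <= 50.0 * v

    def test_different_seeds_differ(self, ps3):
        a = sample_parameters(SensitivitySpec(["a"], n_samples=50, seed=1), ps3)
        b = sample_parameters(SensitivitySpec(["a"], n_samples=50, seed=2), ps3)
        assert not np.array_equal(a, b)

    def test_marginals_uniform_by_ks(self, ps3):
        spec = SensitivitySpec(["a", "b"], n_samples=1000, seed=7)
        d = sample_parameters(spec, ps3)
        for j, name in enumerate(spec.parameters):
            v = ps3.get(name)
            u = (d[:, j] - 0.01 * v) / (50.0 * v - 0.01 * v)
            p = stats.kstest(u, "uniform").pvalue
            assert p > 0.01

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SensitivitySpec(["a"], low_factor=2, high_factor=1)
        with pytest.raises(ValueError):
            SensitivitySpec(["a", "b", "c"], n_samples=3)


class TestPrcc:
    def test_perfect_positive_dependence(self, rng):
        X = rng.random((200, 3))
        y = X[:, 0]
        vals, pv = prcc(X, y)
        assert vals[0] == pytest.approx(1.0, abs=1e-9)
        assert abs(vals[1]) < 0.2 and abs(vals[2]) < 0.2
        assert pv[0] < 1e-10

    def test_sign_symmetry_under_negation(self, rng):
        X = rng.random((200, 3))
        y = np.exp(X[:, 0])          # monotone transform
        v_pos, _ = prcc(X, y)
        v_neg, _ = prcc(X, -y)
        assert v_pos[0] == pytest.approx(1.0, abs=1e-9)
        assert v_neg[0] == pytest.approx(-1.0, abs=1e-9)

    def test_matches_brute_force_at_n50(self, rng):
        X = rng.random((50, 4))
        y = 2 * X[:, 0] - 3 * X[:, 2] + 0.3 * rng.random(50)
        vals, _ = prcc(X, y)
        expect = brute_force_prcc(X, y)
        assert np.allclose(vals, expect, atol=1e-10)

    def test_monotone_transform_invariance(self, rng):
        X = rng.random((120, 3))
        y = X[:, 0] + 0.2 * X[:, 1] + 0.05 * rng.random(120)
        v1, _ = prcc(X, y)
        v2, _ = prcc(np.exp(3 * X), y ** 3)      # monotone on both sides
        assert np.allclose(v1, v2, atol=1e-12)

    def test_constant_column_flagged(self, rng):
        X = rng.random((30, 2))
        X[:, 1] = 4.2
        with pytest.raises(ConstantColumnError):
            prcc(X, X[:, 0])
        with pytest.raises(ConstantColumnError):
            prcc(rng.random((30, 2)), np.full(30, 1.0))

    def test_bounded_by_one(self, rng):
        for _ in range(10):
            X = rng.random((40, 5))
            y = X @ rng.normal(size=5) + 0.1 * rng.random(40)
            vals, _ = prcc(X, y)
            assert np.all(np.abs(vals) <= 1.0)

    def test_dummy_parameter_within_null_interval(self, rng):
        """A parameter with no effect stays inside the null 95% band in at
        least 90% of repeated seeds."""
        n, hits, reps = 60, 0, 30
        crit = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        for _ in range(reps):
            X = rng.random((n, 3))
            y = X[:, 0] + 0.3 * X[:, 1]
            vals, _ = prcc(X, y)
            if abs(vals[2]) <= crit * 1.5:
                hits += 1
        assert hits >= 0.9 * reps


class TestRanking:
    def test_ranking_order_and_permutation_invariance(self, rng):
        X = rng.random((150, 3))
        y = 3 * X[:, 1] - X[:, 0] + 0.1 * rng.random(150)
        vals, pv = prcc(X, y)
        res = PrccResult(["p0", "p1", "p2"], "m", vals, pv, 150)
        ranked = [name for name, _, _ in res.ranking()]
        assert ranked[0] == "p1"
        # permuting parameter order leaves the ranking invariant
        perm = [2, 0, 1]
        v2, p2 = prcc(X[:, perm], y)
        res2 = PrccResult([f"p{i}" for i in perm], "m", v2, p2, 150)
        assert [n for n, _, _ in res2.ranking()] == ranked

    def test_rank_report_format(self, rng):
        X = rng.random((50, 2))
        vals, pv = prcc(X, X[:, 0])
        res = PrccResult(["alpha", "beta"], "max_pR2", vals, pv, 50)
        text = rank_report(res)
        assert "max_pR2" in text and "alpha" in text


def test_run_prcc_on_analytic_model(ps3):
    """End-to-end driver against a cheap analytic 'simulator'."""
    spec = SensitivitySpec(["a", "b"], n_samples=80, seed=3,
                           metrics=("out",))
    def evaluate(ps):
        return {"out": ps.get("a") ** 2 / (1 + ps.get("b"))}
    results = run_prcc(spec, ps3, evaluate)
    res = results["out"]
    assert res.prcc[0] > 0.85         # increasing in a
    assert res.prcc[1] < -0.8         # decreasing in b
    assert np.all(res.p_value < 1e-10)
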