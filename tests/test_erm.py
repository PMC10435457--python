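import numpy as np
import pytest

from cmcqspr.erm import (
    SelectionConfig,
    erm_search,
    exhaustive_best_subset,
    rm_pass,
    scan_to_csv,
    subset_size_scan,
)
from cmcqspr.metrics import rsd
from cmcqspr.mlr import fit_ols, predict_linear


def test_exhaustive_finds_planted_pair(rng):
    X = rng.standard_normal((40, 6))
    y = X[:, 0] + X[:, 4]
    res = exhaustive_best_subset(X, y, 2)
    assert set(res.indices) == {0, 4}
    assert res.rsd == pytest.approx(0.0, abs=1e-10)


def test_exhaustive_rejects_oversized_subset(rng):
    X = rng.standard_normal((20, 4))
    with pytest.raises(ValueError):
        exhaustive_best_subset(X, X[:, 0], 5)


def test_exhaustive_cap():
    X = np.random.default_rng(0).standard_normal((30, 25))
    with pytest.raises(ValueError, match="combinations"):
        exhaustive_best_subset(X, X[:, 0], 10, max_combinations=100)


def test_exhaustive_matches_independent_enumeration(rng):
    """Cross-check against a plain loop over all C(12,3) subsets."""
    from itertools import combinations

    X = rng.standard_normal((50, 12))
    y = X[:, 1] + 0.8 * X[:, 6] - 1.2 * X[:, 9] + rng.normal(0, 0.4, 50)
    best, best_rsd = None, np.inf
    for idx in combinations(range(12), 3):
        m = fit_ols(X[:, idx], y)
        v = rsd(y, predict_linear(m, X[:, idx]), 3)
        if v < best_rsd:
            best, best_rsd = idx, v
    res = exhaustive_best_subset(X, y, 3)
    assert res.indices == best
    assert res.rsd == pytest.approx(best_rsd, abs=1e-12)


def test_rm_pass_fixed_point_at_optimum(planted_pool):
    X, y, truth = planted_pool
    res = rm_pass(truth, X, y)
    assert set(res.indices) == set(truth)


def test_rm_pass_monotone_from_bad_start(planted_pool):
    X, y, truth = planted_pool
    start = (0, 1)
    start_rsd = rsd(y, predict_linear(fit_ols(X[:, start], y), X[:, start]), 2)
    res = rm_pass(start, X, y)
    assert res.rsd <= start_rsd + 1e-12


def test_rm_pass_rsd_consistent_with_metrics(rng):
    X = rng.standard_normal((50, 10))
    y = X[:, 2] - X[:, 7] + rng.normal(0, 0.5, 50)
    res = rm_pass((0, 1), X, y)
    m = fit_ols(X[:, list(res.indices)], y)
    recomputed = rsd(y, predict_linear(m, X[:, list(res.indices)]), 2)
    assert res.rsd == pytest.approx(recomputed, abs=1e-12)


def test_erm_recovers_planted_pair(planted_pool):
    X, y, truth = planted_pool
    res = erm_search(X, y, SelectionConfig(d=2, seed=1, n_restarts=5))
    assert set(res.indices) == set(truth)
    assert res.rsd == pytest.approx(0.0, abs=1e-8)


def test_erm_deterministic(planted_pool):
    X, y, _ = planted_pool
    cfg = SelectionConfig(d=2, seed=9, n_restarts=3)
    a = erm_search(X, y, cfg)
    b = erm_search(X, y, cfg)
    assert a.indices == b.indices and a.rsd == b.rsd
    assert a.trace == b.trace


def test_erm_best_not_worse_than_any_initial_subset(planted_pool):
    X, y, _ = planted_pool
    res = erm_search(X, y, SelectionConfig(d=2, seed=4, n_restarts=4))
    inits = [v for lbl, _, v in res.trace if lbl.startswith("init")]
    assert inits and res.rsd <= min(inits) + 1e-12


def test_erm_attains_exhaustive_optimum_small_pools(rng):
    for seed in (0, 1, 2):
        local = np.random.default_rng(seed)
        X = local.standard_normal((60, 12))
        y = X[:, 1] + 0.8 * X[:, 6] - 1.2 * X[:, 9] + local.normal(0, 0.3, 60)
        exact = exhaustive_best_subset(X, y, 3)
        heur = erm_search(X, y, SelectionConfig(d=3, seed=seed, n_restarts=10))
        assert heur.rsd <= exact.rsd + 1e-10
        assert set(heur.indices) == set(exact.indices)


def test_scan_chooses_planted_size(rng):
    X = rng.standard_normal((100, 12))
    y = X[:, 1] + 0.8 * X[:, 6] - 1.2 * X[:, 9] + rng.normal(0, 0.15, 100)
    results, chosen = subset_size_scan(X, y, 2, 5, SelectionConfig(d=2, seed=3, n_restarts=5))
    assert chosen == 3
    text = scan_to_csv(results)
    assert text.splitlines()[0] == "d,rsd,r2"


def test_scan_argument_validation(rng):
    X = rng.standard_normal((30, 6))
    y = X[:, 0]
    with pytest.raises(ValueError):
        subset_size_scan(X, y, 2, 1, SelectionConfig(d=2))
    with pytest.raises(ValueError):
        subset_size_scan(X, y, 1, 3, SelectionConfig(d=2))


def test_exhaustive_r2_non_decreasing_in_d(rng):
    X = rng.standard_normal((40, 6))
    y = X @ [1, 0.5, 0.2, 0, 0, 0] + rng.normal(0, 0.5, 40)
    r2s = [exhaustive_best_subset(X, y, d).r2 for d in (1, 2, 3)]
    assert r2s == sorted(r2s)


def test_selection_ignores_physical_variables_unless_pooled(rng):
    """The pool is exactly what the caller passes; selection cannot invent
    temperature/pH/salinity columns on its own."""
    X = rng.standard_normal((50, 8))
    y = X[:, 2] + rng.normal(0, 0.1, 50)
    names = [f"D{j}" for j in range(8)]
    res = erm_search(X, y, SelectionConfig(d=2, seed=0, n_restarts=3), pool_names=names)
    assert all(s in names for s in res.subset)
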