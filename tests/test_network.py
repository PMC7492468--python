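"""Correlation-network machinery: Spearman, BH step-up, graph construction,
network comparison, and the analytic power computation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from discnet.network import (
    NetworkError,
    assemble_trait_table,
    bh_adjust,
    build_network,
    compare_networks,
    correlation_power,
    network_from_table,
    spearman_matrix,
)


# ---------------------------------------------------------------------------
# Spearman

def _tbl(**cols):
    return pd.DataFrame(cols)


def test_spearman_monotone_and_antimonotone():
    rho, p, n = spearman_matrix(_tbl(x=[1, 2, 3, 4], y=[1, 2, 3, 4],
                                     z=[4, 3, 2, 1]))
    assert rho.loc["x", "y"] == pytest.approx(1.0)
    assert rho.loc["x", "z"] == pytest.approx(-1.0)
    assert n.loc["x", "y"] == 4


def test_spearman_ties_match_midrank_pearson_oracle():
    x = np.array([1, 2, 2, 3, 5, 5, 5, 8])
    y = np.array([2, 1, 3, 3, 4, 6, 5, 5])
    rho, _, _ = spearman_matrix(_tbl(x=x, y=y))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert rho.loc["x", "y"] == pytest.approx(oracle, rel=1e-12)


def test_spearman_tie_free_p_matches_r_cor_test_reference():
    """Tie-free pairs at n=24: p-values agree with R cor.test (exact-tail)
    reference values to within permutation-table resolution."""
    x = np.array([-0.5496, 1.0911, 0.6398, 1.0426, 0.1697, 1.1378, -0.9706,
                  -0.1318, 0.1462, 1.4413, -2.9414, -0.2428, -0.1406, -0.0327,
                  0.2798, 0.5901, 1.0243, 2.1073, 0.1546, 0.9131, -0.2542,
                  1.5194, 1.7813, -0.8788])
    cases = [  # (y, rho from R, p from R cor.test)
        (np.array([-0.151, 1.1749, -0.5828, 1.4049, -1.4051, 0.4678, -0.3584,
                   0.151, 0.2534, 0.9945, -1.7506, -0.7061, -1.175, -0.8419,
                   0.0501, 0.3585, 0.7063, 1.7507, 0.5828, -0.4678, -0.9946,
                   -0.0502, 0.8415, -0.2534]), 0.70521739, 1.77414182e-04),
        (np.array([-0.5828, -0.4677, 0.151, 0.9945, 0.05, -0.1509, -0.9945,
                   -0.8416, -0.0502, -0.3585, -1.7506, -1.175, -0.2534, 0.8418,
                   -1.405, 0.3586, 0.7064, 1.7507, 1.1749, 0.4676, 0.2534,
                   0.583, 1.405, -0.7062]), 0.60956522, 1.93779493e-03),
        (np.array([0.1509, 0.9944, -0.4676, -0.7063, 1.4051, -0.3586, 0.7062,
                   0.4676, -0.151, -0.5829, -1.7506, -0.9943, 0.2534, -0.8417,
                   -1.175, 1.7507, 0.8416, -0.0502, 1.1751, -1.405, 0.0502,
                   -0.2533, 0.3585, 0.5828]), -0.01826087, 9.33558598e-01),
    ]
    for y, r_ref, p_ref in cases:
        rho, p, _ = spearman_matrix(_tbl(x=x, y=y))
        assert rho.loc["x", "y"] == pytest.approx(r_ref, abs=1e-6)
        assert 0.75 < p.loc["x", "y"] / p_ref < 1.35
    # forcing the plain t approximation recovers scipy's p
    rho, p, _ = spearman_matrix(_tbl(x=x, y=cases[0][0]), p_method="t")
    assert p.loc["x", "y"] == pytest.approx(
        stats.spearmanr(x, cases[0][0]).pvalue, rel=1e-12)


def test_spearman_constant_column_and_min_n():
    rho, p, n = spearman_matrix(_tbl(x=[1, 2, 3, 4], c=[5, 5, 5, 5]))
    assert np.isnan(rho.loc["x", "c"]) and np.isnan(p.loc["x", "c"])
    rho, p, n = spearman_matrix(
        _tbl(x=[1, 2, 3, np.nan, np.nan], y=[1, 2, 3, 4, 5]), min_pairwise_n=4)
    assert n.loc["x", "y"] == 3 and np.isnan(rho.loc["x", "y"])


# ---------------------------------------------------------------------------
# BH

def _bh_oracle(p):
    """Literal step-up definition, coded independently."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p[i] / rank)
        q[i] = min(prev, 1.0)
    return q


def test_bh_trivial_cases():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])


def test_bh_hand_worked_example():
    q = bh_adjust([0.005, 0.01, 0.03, 0.04])
    assert q == pytest.approx([0.02, 0.02, 0.04, 0.04])


def test_bh_rejects_out_of_range():
    with pytest.raises(NetworkError):
        bh_adjust([0.5, 1.5])


def test_bh_preserves_missing_and_order():
    q = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(q[1]) and q[0] == pytest.approx(0.02)


def test_bh_matches_brute_force_oracle_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests
    for _ in range(100):
        p = rng.random(rng.integers(1, 40))
        q = bh_adjust(p)
        assert np.allclose(q, _bh_oracle(p), rtol=0, atol=1e-12)
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=15), st.data())
def test_bh_monotone_under_p_decrease(ps, data):
    """Decreasing any single p never increases any q."""
    i = data.draw(st.integers(0, len(ps) - 1))
    lowered = list(ps)
    lowered[i] = data.draw(st.floats(0.0, ps[i]))
    q0, q1 = bh_adjust(ps), bh_adjust(lowered)
    assert (q1 <= q0 + 1e-12).all()


# ---------------------------------------------------------------------------
# graph building / comparison

def _q_frame(names, entries):
    q = pd.DataFrame(np.full((len(names), len(names)), np.nan),
                     index=names, columns=names)
    for a, b, v in entries:
        q.loc[a, b] = q.loc[b, a] = v
    return q


def test_build_network_threshold_and_signs():
    names = list("abcd")
    rho = _q_frame(names, [("a", "b", 0.9), ("a", "c", -0.8), ("b", "c", 0.7),
                           ("c", "d", 0.5)])
    q = _q_frame(names, [("a", "b", 0.01), ("a", "c", 0.02), ("b", "c", 0.04),
                         ("c", "d", 0.2)])
    g = build_network(rho, q, alpha=0.05)
    assert set(map(frozenset, g.edges)) == {frozenset("ab"), frozenset("ac"),
                                            frozenset("bc")}
    assert g.edges["a", "c"]["sign"] == -1 and g.edges["a", "b"]["sign"] == 1
    assert g.number_of_edges() <= len(names) * (len(names) - 1) / 2
    empty = build_network(rho, q, alpha=0.001)
    assert empty.number_of_edges() == 0


def test_compare_networks_jaccard():
    names = list("abcde")
    rho = _q_frame(names, [(a, b, 0.9) for a in names for b in names if a < b])
    qa = _q_frame(names, [("a", "b", 0.01), ("a", "c", 0.01), ("a", "d", 0.01)])
    qb = _q_frame(names, [("a", "b", 0.01), ("a", "c", 0.01), ("d", "e", 0.01)])
    ga, gb = build_network(rho, qa), build_network(rho, qb)
    rep = compare_networks(ga, gb)
    assert rep["jaccard"] == pytest.approx(2 / 4)
    assert compare_networks(ga, ga)["jaccard"] == 1.0
    qc = _q_frame(names, [("b", "c", 0.01)])
    assert compare_networks(ga, build_network(rho, qc))["jaccard"] == 0.0


def test_compare_networks_disjoint_nodes_rejected():
    import networkx as nx
    g1, g2 = nx.Graph(), nx.Graph()
    g1.add_node("a")
    g2.add_node("b")
    with pytest.raises(NetworkError):
        compare_networks(g1, g2)


# ---------------------------------------------------------------------------
# power

def test_power_at_study_sample_size():
    assert 0.71 <= correlation_power(24, 0.5, 0.05) <= 0.74


def test_power_null_limit_equals_alpha():
    assert correlation_power(200, 1e-8, 0.05) == pytest.approx(0.05, abs=0.003)


def test_power_monte_carlo_check(rng):
    """10^4 bivariate-normal draws at n=24, rho=0.5: empirical rejection of
    the two-sided correlation t-test within 0.02 of the analytic power."""
    n, reps, rho = 24, 10000, 0.5
    x = rng.normal(size=(reps, n))
    y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=(reps, n))
    xm = x - x.mean(1, keepdims=True)
    ym = y - y.mean(1, keepdims=True)
    r = (xm * ym).sum(1) / np.sqrt((xm ** 2).sum(1) * (ym ** 2).sum(1))
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    crit = stats.t.ppf(0.975, n - 2)
    emp = np.mean(np.abs(t) > crit)
    assert emp == pytest.approx(correlation_power(n, rho, 0.05), abs=0.02)


def test_power_domain_errors():
    with pytest.raises(NetworkError):
        correlation_power(3, 0.5, 0.05)
    with pytest.raises(NetworkError):
        correlation_power(24, 1.5, 0.05)


# ---------------------------------------------------------------------------
# trait tables (uses the session-wide default study)

def test_trait_table_shapes_and_estrous_rule(default_tables):
    male, female = default_tables["male"], default_tables["female"]
    assert len(male) == 23  # 24 males minus the one lost to attrition
    assert "estrous" not in male.columns
    assert "estrous" in female.columns
    assert male.index.is_unique


def test_trait_table_row_order_keyed_by_id(default_dataset, default_reduced):
    shuffled = default_dataset.animals.sample(frac=1, random_state=3)
    t1 = assemble_trait_table(default_dataset.animals, default_reduced, "male")
    t2 = assemble_trait_table(shuffled, default_reduced, "male")
    pd.testing.assert_frame_equal(t1, t2.loc[t1.index])


def test_trait_table_missing_reduction_is_an_error(default_dataset, default_reduced):
    broken = dict(default_reduced)
    broken["biomech"] = default_reduced["biomech"].drop(
        columns=["torsional_stiffness"])
    with pytest.raises(NetworkError, match="torsional_stiffness"):
        assemble_trait_table(default_dataset.animals, broken, "male")


def test_alpha_one_gives_complete_graph_over_testable_pairs(default_tables):
    tbl = default_tables["male"]
    g, rho, p, q = network_from_table(tbl, alpha=1.0)
    testable = int(np.isfinite(q.to_numpy()[np.triu_indices(len(q), 1)]).sum())
    assert g.number_of_edges() == testable > 0
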