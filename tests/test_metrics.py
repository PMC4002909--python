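"""Validation measures: classical indices and the biological ones."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pathsom as ps
from pathsom.metrics import coherence, flatness


def _make(data, weights, labels):
    """Assemble (ExpressionMatrix, SomModel, Partition) from raw arrays."""
    data = np.asarray(data, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ids = [f"p{i}" for i in range(data.shape[0])]
    expr = ps.ExpressionMatrix(ids, data)
    cfg = ps.SomConfig(rows=1, cols=weights.shape[0], alpha=0.0, epochs=1)
    model = ps.SomModel(cfg, weights)
    part = ps.Partition(ids, np.asarray(labels), weights.shape[0])
    return expr, model, part


# ----------------------------------------------------- independent oracles

def brute_compactness(data, weights, labels):
    vals = []
    for m in set(labels):
        members = [i for i, l in enumerate(labels) if l == m]
        vals.append(np.mean([np.linalg.norm(data[i] - weights[m])
                             for i in members]))
    return np.mean(vals)


def brute_separation(weights, labels):
    units = sorted(set(labels))
    k = len(units)
    tot = sum(np.linalg.norm(weights[units[i]] - weights[units[j]])
              for i in range(k) for j in range(i + 1, k))
    return 2.0 * tot / (k * k - k)


def brute_db(data, weights, labels):
    units = sorted(set(labels))
    scat = {m: np.mean([np.linalg.norm(data[i] - weights[m])
                        for i in range(len(labels)) if labels[i] == m])
            for m in units}
    total = 0.0
    for m in units:
        total += max((scat[m] + scat[o])
                     / np.linalg.norm(weights[m] - weights[o])
                     for o in units if o != m)
    return total / len(units)


def brute_dunn(data, labels):
    units = sorted(set(labels))
    groups = {m: [data[i] for i in range(len(labels)) if labels[i] == m]
              for m in units}
    diam = max((np.linalg.norm(a - b)
                for g in groups.values()
                for a, b in itertools.combinations(g, 2)), default=0.0)
    inter = min(np.linalg.norm(a - b)
                for x, y in itertools.combinations(units, 2)
                for a in groups[x] for b in groups[y])
    return inter / diam


def brute_bio_connectivity(rho, labels, log_base=10.0):
    """Eq.-style enumeration: p_m over ordered in-cluster pairs, p_m* over
    ordered pairs from members to the whole dataset."""
    n = len(labels)
    annotated = [any(rho[i][j] > 0 for j in range(n) if j != i)
                 for i in range(n)]
    ratios = []
    for m in sorted(set(labels)):
        members = [i for i in range(n) if labels[i] == m]
        if not any(annotated[i] for i in members):
            continue
        p = 1 + sum(rho[i][j] for i in members for j in members if j != i)
        p_star = 1 + sum(rho[i][j] for i in members
                         for j in range(n) if j != i)
        ratios.append(p / p_star)
    if not ratios:
        return 0.0
    return -np.log(np.mean(ratios)) / np.log(log_base)


# --------------------------------------------------------------- examples

def test_compactness_zero_when_members_on_centroids():
    expr, model, part = _make([[1., 1.], [3., 3.]],
                              [[1., 1.], [3., 3.]], [0, 1])
    assert ps.compactness(expr, model, part) == 0.0


def test_compactness_symmetric_pair():
    expr, model, part = _make([[-1.], [1.]], [[0.], [9.]], [0, 0])
    assert ps.compactness(expr, model, part) == 1.0


def test_separation_two_and_three_clusters():
    expr, model, part = _make([[0.], [1.]], [[0.], [1.]], [0, 1])
    assert ps.separation(model, part) == 1.0
    s = 2.0
    eq = np.array([[0., 0.], [s, 0.], [s / 2, s * np.sqrt(3) / 2]])
    expr, model, part = _make(eq, eq, [0, 1, 2])
    assert ps.separation(model, part) == pytest.approx(s)


def test_separation_identical_centroids_zero_and_k1_error():
    expr, model, part = _make([[0.], [0.]], [[5.], [5.]], [0, 1])
    assert ps.separation(model, part) == 0.0
    expr, model, part = _make([[0.], [0.]], [[5.], [5.]], [0, 0])
    with pytest.raises(ValueError):
        ps.separation(model, part)


def test_davies_bouldin_hand_case():
    # two 1-D clusters, scatters 1 and 1, centroid gap 4 -> (1+1)/4
    expr, model, part = _make([[-1.], [1.], [3.], [5.]],
                              [[0.], [4.]], [0, 0, 1, 1])
    assert ps.davies_bouldin(expr, model, part) == pytest.approx(0.5)


def test_davies_bouldin_zero_scatter():
    expr, model, part = _make([[0., 0.], [4., 0.]],
                              [[0., 0.], [4., 0.]], [0, 1])
    assert ps.davies_bouldin(expr, model, part) == 0.0


def test_davies_bouldin_coincident_centroids_error():
    expr, model, part = _make([[0.], [1.]], [[2.], [2.]], [0, 1])
    with pytest.raises(ValueError, match="coincident"):
        ps.davies_bouldin(expr, model, part)


def test_dunn_hand_case_and_invariances():
    expr, model, part = _make([[0.], [1.], [5.], [6.]],
                              [[0.5], [5.5]], [0, 0, 1, 1])
    assert ps.dunn(expr, part) == pytest.approx(4.0)
    # global scaling leaves Dunn unchanged
    expr2, _, part2 = _make(10 * np.array([[0.], [1.], [5.], [6.]]),
                            [[5.], [55.]], [0, 0, 1, 1])
    assert ps.dunn(expr2, part2) == pytest.approx(4.0)
    # shrinking the gap strictly decreases it
    expr3, _, part3 = _make([[0.], [1.], [3.], [4.]],
                            [[0.5], [3.5]], [0, 0, 1, 1])
    assert ps.dunn(expr3, part3) < ps.dunn(expr, part)


def test_dunn_zero_diameter_error():
    expr, model, part = _make([[0.], [5.]], [[0.], [5.]], [0, 1])
    with pytest.raises(ValueError, match="diameter"):
        ps.dunn(expr, part)


def test_classical_indices_match_bruteforce():
    """C, S, DB and Dunn agree with independent loop-based evaluations on
    random instances."""
    rng = np.random.default_rng(7)
    for _ in range(40):
        n = int(rng.integers(6, 30))
        k = int(rng.integers(2, 6))
        d = int(rng.integers(1, 4))
        data = rng.normal(size=(n, d))
        weights = rng.normal(size=(k, d))
        labels = rng.integers(0, k, size=n)
        labels[:k] = np.arange(k)      # every cluster non-empty
        expr, model, part = _make(data, weights, labels)
        assert ps.compactness(expr, model, part) == pytest.approx(
            brute_compactness(data, weights, labels), rel=1e-12)
        assert ps.separation(model, part) == pytest.approx(
            brute_separation(weights, labels), rel=1e-12)
        assert ps.davies_bouldin(expr, model, part) == pytest.approx(
            brute_db(data, weights, labels), rel=1e-12)
        assert ps.dunn(expr, part) == pytest.approx(
            brute_dunn(data, labels), rel=1e-12)


# ------------------------------------------------- biological connectivity

def _conn(rho):
    rho = np.asarray(rho)
    ids = [f"p{i}" for i in range(rho.shape[0])]
    return ps.ConnectivityMatrix(ids, rho), ids


def test_bio_connectivity_single_cluster_is_zero():
    rho = np.array([[0, 2, 1], [2, 0, 0], [1, 0, 0]])
    conn, ids = _conn(rho)
    part = ps.Partition(ids, np.zeros(3, dtype=int), 1)
    assert ps.bio_connectivity(part, conn) == 0.0


def test_bio_connectivity_zero_rho_is_zero():
    conn, ids = _conn(np.zeros((4, 4), dtype=int))
    part = ps.Partition(ids, np.array([0, 0, 1, 1]), 2)
    assert ps.bio_connectivity(part, conn) == 0.0


def test_bio_connectivity_cross_pair_fixture():
    """Pairs (p0,p1) and (p2,p3) share pathways; splitting each pair across
    clusters gives ratio 1/4 per cluster, P = -log10(0.25)."""
    rho = np.zeros((4, 4), dtype=int)
    rho[0, 1] = rho[1, 0] = 2
    rho[2, 3] = rho[3, 2] = 1
    conn, ids = _conn(rho)
    perfect = ps.Partition(ids, np.array([0, 0, 1, 1]), 2)
    assert ps.bio_connectivity(perfect, conn) == 0.0
    split = ps.Partition(ids, np.array([0, 1, 0, 1]), 2)
    # cluster {p0,p2}: p=1, p*=1+(2+1)=4 ; same for {p1,p3}
    assert ps.bio_connectivity(split, conn) == pytest.approx(
        -np.log10(0.25))


def test_bio_connectivity_ten_pattern_fixture_matches_enumeration():
    rng = np.random.default_rng(0)
    A = rng.integers(0, 4, size=(10, 10))
    rho = A + A.T
    np.fill_diagonal(rho, 0)
    labels = np.array([0, 0, 0, 1, 1, 2, 2, 2, 3, 3])
    conn, ids = _conn(rho)
    part = ps.Partition(ids, labels, 4)
    assert ps.bio_connectivity(part, conn) == pytest.approx(
        brute_bio_connectivity(rho, labels), rel=1e-12)


def test_bio_connectivity_ignores_unannotated_clusters():
    """Clusters containing only zero-rho patterns do not enter the mean."""
    rho = np.zeros((4, 4), dtype=int)
    rho[0, 1] = rho[1, 0] = 3
    conn, ids = _conn(rho)
    part = ps.Partition(ids, np.array([0, 1, 2, 2]), 3)
    # only clusters {p0} and {p1} are annotated; each ratio = 1/4
    assert ps.bio_connectivity(part, conn) == pytest.approx(-np.log10(0.25))


@given(st.data())
def test_bio_connectivity_nonnegative(data):
    n = data.draw(st.integers(2, 10))
    k = data.draw(st.integers(1, 4))
    tri = data.draw(st.lists(st.integers(0, 4),
                             min_size=n * (n - 1) // 2,
                             max_size=n * (n - 1) // 2))
    rho = np.zeros((n, n), dtype=int)
    rho[np.triu_indices(n, 1)] = tri
    rho = rho + rho.T
    labels = data.draw(st.lists(st.integers(0, k - 1),
                                min_size=n, max_size=n))
    conn, ids = _conn(rho)
    part = ps.Partition(ids, np.array(labels), k)
    p = ps.bio_connectivity(part, conn)
    assert p >= 0.0
    assert p == pytest.approx(brute_bio_connectivity(rho, labels),
                              rel=1e-12, abs=1e-12)


def test_merging_mutually_linked_clusters_never_increases_p():
    """Two clusters whose members share pathways only with each other:
    merging them can only improve (never worsen) P."""
    rho = np.zeros((6, 6), dtype=int)
    rho[0, 2] = rho[2, 0] = 2      # links cross the {p0,p1} / {p2,p3} split
    rho[1, 3] = rho[3, 1] = 1
    rho[4, 5] = rho[5, 4] = 3      # an unrelated, self-contained cluster
    conn, ids = _conn(rho)
    split = ps.Partition(ids, np.array([0, 0, 1, 1, 2, 2]), 3)
    merged = ps.Partition(ids, np.array([0, 0, 0, 0, 2, 2]), 3)
    assert (ps.bio_connectivity(merged, conn)
            <= ps.bio_connectivity(split, conn))


# ------------------------------------------------------------------- GMLC

def test_flatness_flat_and_degenerate():
    ids = ["a", "b", "c", "d"]
    flat = ps.Partition(ids, np.array([0, 0, 1, 1]), 2)
    assert flatness(flat) == pytest.approx(0.0)
    skew = ps.Partition(ids, np.array([0, 0, 0, 1]), 2)
    assert flatness(skew) > 0.0
    single = ps.Partition(ids, np.zeros(4, dtype=int), 1)
    assert flatness(single) == 0.0


def test_coherence_perfect_profiles():
    data = np.array([[1., 2., 3.], [2., 4., 6.], [3., 2., 1.]])
    weights = np.array([[1., 2., 3.], [3., 2., 1.]])
    expr, model, part = _make(data, weights, [0, 0, 1])
    assert coherence(expr, model, part) == pytest.approx(1.0)


def test_gmlc_is_sum_of_components():
    rng = np.random.default_rng(3)
    data = rng.normal(size=(12, 4))
    weights = rng.normal(size=(3, 4))
    labels = rng.integers(0, 3, size=12)
    labels[:3] = [0, 1, 2]
    A = rng.integers(0, 3, size=(12, 12))
    rho = A + A.T
    np.fill_diagonal(rho, 0)
    conn, _ = _conn(rho)
    expr, model, part = _make(data, weights, labels)
    g = ps.gmlc(expr, model, part, conn)
    assert g == pytest.approx(flatness(part) - coherence(expr, model, part)
                              + ps.bio_connectivity(part, conn), rel=1e-12)
    # changing only rho moves G by exactly the change in P
    rho2 = rho.copy()
    rho2[0, 1] += 5
    rho2[1, 0] += 5
    conn2, _ = _conn(rho2)
    g2 = ps.gmlc(expr, model, part, conn2)
    assert g2 - g == pytest.approx(
        ps.bio_connectivity(part, conn2) - ps.bio_connectivity(part, conn),
        rel=1e-12)


def test_best_possible_partition_hits_component_optima():
    """Flat, perfectly coherent, fully connected clusters: every component
    is at its optimum, so G = 0 - 1 + 0 = -1."""
    data = np.array([[1., 2.], [2., 4.], [4., 2.], [2., 1.]])
    weights = np.array([[1., 2.], [4., 2.]])
    rho = np.zeros((4, 4), dtype=int)
    rho[0, 1] = rho[1, 0] = 2
    rho[2, 3] = rho[3, 2] = 2
    conn, ids = _conn(rho)
    expr, model, part = _make(data, weights, [0, 0, 1, 1])
    assert flatness(part) == pytest.approx(0.0)
    assert coherence(expr, model, part) == pytest.approx(1.0)
    assert ps.bio_connectivity(part, conn) == 0.0
    assert ps.gmlc(expr, model, part, conn) == pytest.approx(-1.0)


# ----------------------------------------------------------- invariances

def test_metrics_invariant_to_pattern_and_cluster_relabeling():
    rng = np.random.default_rng(11)
    n, k, d = 20, 3, 3
    data = rng.normal(size=(n, d))
    weights = rng.normal(size=(k, d))
    labels = rng.integers(0, k, size=n)
    labels[:k] = np.arange(k)
    A = rng.integers(0, 3, size=(n, n))
    rho = A + A.T
    np.fill_diagonal(rho, 0)

    def report(data, weights, labels, rho):
        expr, model, part = _make(data, weights, labels)
        ids = expr.pattern_ids
        conn = ps.ConnectivityMatrix(list(ids), rho)
        return ps.validation_report(expr, model, part, conn)

    base = report(data, weights, labels, rho).to_series()
    # permute pattern order
    perm = rng.permutation(n)
    shuffled = report(data[perm], weights, labels[perm],
                      rho[np.ix_(perm, perm)]).to_series()
    assert np.allclose(base.values, shuffled.values)
    # relabel clusters (permute unit indices and weights together)
    cperm = np.array([2, 0, 1])
    relabeled = report(data, weights[np.argsort(cperm)], cperm[labels],
                       rho).to_series()
    assert np.allclose(base.values, relabeled.values)


# ------------------------------------------------------------ report I/O

def test_validation_report_serialization(tmp_path):
    rep = ps.ValidationReport(0.5, 1.2, 0.8, 2.0, 0.3, -0.1, 4)
    import json
    d = json.loads(rep.to_json(tmp_path / "r.json"))
    assert d["bio_connectivity"] == 0.3
    tsv = rep.to_tsv(tmp_path / "r.tsv")
    header, row = tsv.strip().split("\n")
    assert header.split("\t")[:6] == ["compactness", "separation",
                                     "davies_bouldin", "dunn",
                                     "bio_connectivity", "gmlc"]
    assert row.split("\t")[-1] == "4"


# ------------------------------------------------------------- resampling

def test_resampling_argument_validation(small_toy):
    expr, conn, _ = small_toy
    cfg = ps.SomConfig(rows=2, cols=2, epochs=5)
    with pytest.raises(ValueError):
        ps.resampling_significance(expr, conn, [cfg], n_resamples=1)
    with pytest.raises(ValueError):
        ps.resampling_significance(expr, conn, [cfg], keep_fraction=0.0)
    with pytest.raises(ValueError):
        ps.resampling_significance(expr, conn, [cfg], n_resamples=2,
                                   keep_fraction=0.001)


def test_resampling_keep_fraction_one_uses_full_dataset(small_toy):
    """With keep_fraction = 1 every resample trains on all patterns, so
    the only variation between resamples comes from the training seeds."""
    expr, conn, _ = small_toy
    cfg = ps.SomConfig(rows=2, cols=2, alpha=0.5, epochs=10)
    samples, p = ps.resampling_significance(expr, conn, [cfg, cfg],
                                            n_resamples=4,
                                            keep_fraction=1.0, seed=3)
    assert samples.shape == (4, 2)
    assert list(samples.columns) == ["alpha=0.5", "alpha=0.5#2"]
    assert np.isfinite(samples.to_numpy()).all()
    assert 0.0 <= p <= 1.0


def test_resampling_is_deterministic(small_toy):
    expr, conn, _ = small_toy
    cfgs = [ps.SomConfig(rows=2, cols=2, alpha=0.0, epochs=10),
            ps.SomConfig(rows=2, cols=2, alpha=0.75, epochs=10)]
    s1, p1 = ps.resampling_significance(expr, conn, cfgs, n_resamples=3,
                                        seed=5)
    s2, p2 = ps.resampling_significance(expr, conn, cfgs, n_resamples=3,
                                        seed=5)
    assert np.array_equal(s1.to_numpy(), s2.to_numpy())
    assert p1 == p2
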