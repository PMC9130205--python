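"""Distance matrices, matrix correlation, Mantel test, MDS and graphs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hgadmix.distmantel import (
    DistanceMatrix,
    euclidean_matrix,
    mantel_test,
    matrix_correlation,
    mds_embedding,
    minimum_spanning_tree,
    read_distance_csv,
    read_phylip,
    threshold_edges,
    write_distance_csv,
    write_phylip,
)
from hgadmix.synthetic import generate_populations, generate_profiles


def _random_dm(rng, n, labels=None):
    pts = rng.uniform(size=(n, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return DistanceMatrix.from_array(d, labels or [f"p{i}" for i in range(n)])


def test_euclidean_examples(rng):
    df = pd.DataFrame(
        [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]],
        index=["a", "b", "c"],
        columns=["H", "U"],
    )
    d = euclidean_matrix(df)
    assert d.values.loc["a", "b"] == 0.0
    assert d.values.loc["a", "c"] == pytest.approx(np.sqrt(2))
    # direct-summation oracle on a random matrix
    X = rng.uniform(size=(5, 8))
    dm = euclidean_matrix(pd.DataFrame(X))
    for m in range(5):
        for n in range(5):
            oracle = np.sqrt(((X[m] - X[n]) ** 2).sum())
            assert dm.to_numpy()[m, n] == pytest.approx(oracle, abs=1e-12)


def test_euclidean_is_a_metric_on_generated_data():
    freq, _ = generate_populations(
        generate_profiles(3, 10, seed=1), 12, "admixed", 0.0, seed=2
    )
    d = euclidean_matrix(freq).to_numpy()
    n = len(d)
    for i, j, k in itertools.permutations(range(n), 3):
        assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


def test_matrix_correlation_identity_and_scale(rng):
    d = _random_dm(rng, 6)
    assert matrix_correlation(d, d) == pytest.approx(1.0)
    scaled = DistanceMatrix.from_array(2.0 * d.to_numpy(), d.labels)
    assert matrix_correlation(d, scaled) == pytest.approx(1.0)


def test_matrix_correlation_matches_flatten_oracle(rng):
    d1 = _random_dm(rng, 7)
    d2 = _random_dm(rng, 7)
    iu = np.triu_indices(7, k=1)
    oracle = np.corrcoef(d1.to_numpy()[iu], d2.to_numpy()[iu])[0, 1]
    assert matrix_correlation(d1, d2) == pytest.approx(oracle, abs=1e-12)


def test_matrix_correlation_relabel_invariance(rng):
    d1 = _random_dm(rng, 6)
    d2 = _random_dm(rng, 6)
    r = matrix_correlation(d1, d2)
    perm = list(rng.permutation(d1.labels))
    assert matrix_correlation(d1.reordered(perm), d2.reordered(perm)) == (
        pytest.approx(r)
    )
    # automatic label alignment: shuffling only one matrix changes nothing
    assert matrix_correlation(d1, d2.reordered(perm)) == pytest.approx(r)


def test_matrix_correlation_label_mismatch_errors(rng):
    d1 = _random_dm(rng, 5, labels=list("abcde"))
    d2 = _random_dm(rng, 5, labels=list("vwxyz"))
    with pytest.raises(ValueError, match="shared labels"):
        matrix_correlation(d1, d2)


def test_mantel_perfect_concordance_min_p(rng):
    d = _random_dm(rng, 8)
    res = mantel_test(d, d, n_permutations=99, seed=0)
    assert res.r_observed == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1 / 100)


def test_mantel_planted_correlation_significant(rng):
    d1 = _random_dm(rng, 12)
    noise = rng.normal(0, 0.01, size=(12, 12))
    noise = (noise + noise.T) / 2
    np.fill_diagonal(noise, 0)
    d2 = DistanceMatrix.from_array(
        np.abs(d1.to_numpy() + noise), d1.labels
    )
    res = mantel_test(d1, d2, n_permutations=999, seed=1)
    assert res.p_value < 0.01


def test_mantel_agrees_with_skbio(rng):
    skbio_dist = pytest.importorskip("skbio.stats.distance")
    d1 = _random_dm(rng, 9)
    d2 = _random_dm(rng, 9)
    r_skbio, p_skbio, _ = skbio_dist.mantel(
        skbio_dist.DistanceMatrix(d1.to_numpy(), ids=d1.labels),
        skbio_dist.DistanceMatrix(d2.to_numpy(), ids=d2.labels),
        method="pearson",
        permutations=999,
        alternative="greater",
    )
    res = mantel_test(d1, d2, n_permutations=999, seed=3)
    assert res.r_observed == pytest.approx(r_skbio, abs=1e-12)
    # both use one-sided permutation p-values; agreement within Monte Carlo noise
    assert res.p_value == pytest.approx(p_skbio, abs=0.05)


def test_mds_collinear_points_recovered():
    # 3 points on a line at 0, 1, 3
    d = DistanceMatrix.from_array(
        [[0, 1, 3], [1, 0, 2], [3, 2, 0]], ["a", "b", "c"]
    )
    emb = mds_embedding(d, dims=2)
    coords = emb.to_numpy()
    # second dimension is degenerate; pairwise distances preserved
    for i, j in itertools.combinations(range(3), 2):
        assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
            d.to_numpy()[i, j], abs=1e-9
        )


def test_mds_procrustes_recovery(rng):
    from scipy.spatial import procrustes

    pts = rng.uniform(size=(10, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    emb = mds_embedding(
        DistanceMatrix.from_array(d, [f"p{i}" for i in range(10)]), dims=2
    )
    _, _, disparity = procrustes(pts, emb.to_numpy())
    assert disparity < 1e-9


def test_mds_positive_distance_correlation(rng):
    d = _random_dm(rng, 9)
    emb = mds_embedding(d, dims=2).to_numpy()
    de = np.linalg.norm(emb[:, None] - emb[None, :], axis=-1)
    iu = np.triu_indices(9, k=1)
    assert np.corrcoef(d.to_numpy()[iu], de[iu])[0, 1] > 0


def test_threshold_edges_crafted():
    d = DistanceMatrix.from_array(
        [
            [0.0, 1.0, 5.0, 10.0],
            [1.0, 0.0, 2.0, 9.0],
            [5.0, 2.0, 0.0, 3.0],
            [10.0, 9.0, 3.0, 0.0],
        ],
        list("abcd"),
    )
    edges = {(a, b) for a, b, _ in threshold_edges(d, fraction=0.35)}
    assert edges == {("a", "b"), ("b", "c"), ("c", "d")}  # cutoff 3.5
    assert threshold_edges(d, fraction=1e-9) == []
    full = threshold_edges(d, fraction=1.0)
    assert len(full) == 5  # all pairs except the maximal distance itself


def _mst_oracle(d):
    """Exhaustive minimum over all spanning trees (tiny n only)."""
    n = len(d)
    all_edges = list(itertools.combinations(range(n), 2))
    best = np.inf
    for subset in itertools.combinations(all_edges, n - 1):
        # connectivity check by union-find
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            best = min(best, sum(d[a][b] for a, b in subset))
    return best


def test_mst_three_points_and_chain():
    d = DistanceMatrix.from_array(
        [[0, 1, 4], [1, 0, 2], [4, 2, 0]], list("abc")
    )
    edges = minimum_spanning_tree(d)
    assert {(a, b) for a, b, _ in edges} == {("a", "b"), ("b", "c")}
    # chain-structured distances yield the chain
    n = 5
    chain = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    edges = minimum_spanning_tree(
        DistanceMatrix.from_array(chain, [f"p{i}" for i in range(n)])
    )
    assert {(a, b) for a, b, _ in edges} == {
        (f"p{i}", f"p{i+1}") for i in range(n - 1)
    }


def test_mst_weight_matches_exhaustive_oracle(rng):
    d = _random_dm(rng, 6)
    edges = minimum_spanning_tree(d)
    assert len(edges) == 5
    total = sum(w for _, _, w in edges)
    assert total == pytest.approx(_mst_oracle(d.to_numpy()), abs=1e-12)


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix.from_array([[0, 1], [2, 0]], ["a", "b"])
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix.from_array([[1, 1], [1, 0]], ["a", "b"])


def test_csv_and_phylip_roundtrip(tmp_path, rng):
    d = _random_dm(rng, 5)
    csv = tmp_path / "d.csv"
    write_distance_csv(d, csv)
    back = read_distance_csv(csv)
    np.testing.assert_allclose(back.to_numpy(), d.to_numpy(), atol=1e-9)
    assert back.labels == d.labels
    phy = tmp_path / "d.phy"
    write_phylip(d, phy)
    back2 = read_phylip(phy)
    np.testing.assert_allclose(back2.to_numpy(), d.to_numpy(), atol=1e-9)
    assert back2.labels == d.labels
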