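"""Growing central-vector clustering: criterion, recovery, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from hgadmix.distmantel import euclidean_matrix
from hgadmix.soc import (
    SelfOrganizingCloud,
    cluster_radius,
    fit_soc,
    inherence_distance_correlation,
    inherence_matrix,
    significance_check,
)
from hgadmix.synthetic import generate_populations, generate_profiles


def _check_invariants(X, soc):
    """Nearest-center assignment and, on convergence, the radius criterion."""
    dist = cdist(X, soc.cluster_centers_)
    np.testing.assert_array_equal(soc.labels_, dist.argmin(axis=1))
    if soc.converged_:
        cc = cdist(soc.cluster_centers_, soc.cluster_centers_)
        np.fill_diagonal(cc, np.inf)
        for i in range(soc.n_clusters_):
            members = X[soc.labels_ == i]
            if len(members) >= 2:
                radius = np.linalg.norm(
                    members - soc.cluster_centers_[i], axis=1
                ).mean()
                assert radius < soc.ratio * cc[i].min()


def test_two_separated_clouds_recovered(rng):
    mu = np.array([[0.0] * 6, [10.0] * 6])
    X = np.vstack(
        [rng.normal(mu[0], 0.5, size=(30, 6)), rng.normal(mu[1], 0.5, size=(30, 6))]
    )
    soc = fit_soc(X, seed=0)
    assert soc.converged_
    assert soc.n_clusters_ == 2
    # centers within 3 standard errors of the sample means
    se = 0.5 / np.sqrt(30)
    sample_means = np.array([X[:30].mean(axis=0), X[30:].mean(axis=0)])
    d = cdist(soc.cluster_centers_, sample_means)
    order = d.argmin(axis=1)
    assert set(order) == {0, 1}
    for i, j in enumerate(order):
        assert np.all(np.abs(soc.cluster_centers_[i] - sample_means[j]) < 3 * se)
    _check_invariants(X, soc)


def test_invariants_hold_on_random_data(rng):
    """On arbitrary data the fit either satisfies the criterion or reports
    converged=False; assignment is always nearest-center."""
    for trial in range(3):
        X = rng.uniform(size=(25, 5))
        soc = SelfOrganizingCloud(max_n=8, random_state=trial).fit(X)
        _check_invariants(X, soc)


def test_planted_partition_recovered():
    profiles = generate_profiles(5, 16, concentration=0.3, seed=20)
    freq, truth = generate_populations(
        profiles, 100, mixture_mode="pure", noise_sd=0.01, seed=21
    )
    soc = fit_soc(freq, seed=42)
    assert soc.converged_
    assert soc.n_clusters_ == 5
    ari = adjusted_rand_score(truth.planted_partition.to_numpy(), soc.labels_)
    assert ari == 1.0


def test_center_recovery_improves_as_noise_vanishes():
    profiles = generate_profiles(4, 12, concentration=0.3, seed=5)
    errs = []
    for sd in (0.02, 0.002):
        freq, truth = generate_populations(
            profiles, 40, mixture_mode="pure", noise_sd=sd, seed=6
        )
        soc = fit_soc(freq, seed=7)
        d = cdist(soc.cluster_centers_, profiles)
        errs.append(d.min(axis=1).max())
    assert errs[1] < errs[0]
    assert errs[1] < 0.01


def test_reproducibility_same_seed(rng):
    X = rng.uniform(size=(30, 6))
    a = SelfOrganizingCloud(max_n=6, random_state=9).fit(X)
    b = SelfOrganizingCloud(max_n=6, random_state=9).fit(X)
    np.testing.assert_array_equal(a.labels_, b.labels_)
    np.testing.assert_array_equal(a.cluster_centers_, b.cluster_centers_)


def test_parameter_errors(rng):
    X = rng.uniform(size=(10, 3))
    with pytest.raises(ValueError, match="max_n"):
        SelfOrganizingCloud(n_start=5, max_n=3).fit(X)


def test_cluster_radius_examples():
    X = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.0], [1.0, -1.0], [10.0, 10.0]])
    soc = SelfOrganizingCloud(n_start=2, random_state=0).fit(X)
    # singleton cluster has radius 0
    singleton = [i for i in range(soc.n_clusters_) if (soc.labels_ == i).sum() == 1]
    for i in singleton:
        assert cluster_radius(X, soc, i) == 0.0
    # radius equals the direct averaging oracle
    for i in range(soc.n_clusters_):
        members = X[soc.labels_ == i]
        oracle = np.mean(
            [np.linalg.norm(m - soc.cluster_centers_[i]) for m in members]
        )
        assert cluster_radius(X, soc, i) == pytest.approx(oracle)


def test_significance_separated_vs_degenerate(rng):
    profiles = generate_profiles(3, 10, concentration=0.3, seed=31)
    freq, _ = generate_populations(
        profiles, 30, mixture_mode="pure", noise_sd=0.005, seed=32
    )
    soc = fit_soc(freq, seed=33)
    sig = significance_check(freq, soc)
    assert (sig.dropna() > 0.99).all()
    # all points identical: zero-variance differences are not computable
    X = np.ones((6, 4))
    X[5] += 5  # second center so the fit has >= 2 clusters
    soc2 = SelfOrganizingCloud(n_start=2, random_state=0).fit(X)
    sig2 = significance_check(X, soc2)
    big = int(pd.Series(soc2.labels_).value_counts().idxmax())
    assert np.isnan(sig2[big])


def test_inherence_matrix_shapes():
    assert (inherence_matrix(np.zeros(4, dtype=int)) == 1).all()
    np.testing.assert_array_equal(
        inherence_matrix(np.arange(4)), np.eye(4, dtype=int)
    )
    labels = np.array([0, 0, 1, 1])
    inh = inherence_matrix(labels)
    assert inh.tolist() == [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]]
    assert (inh == inh.T).all()


def test_inherence_distance_correlation_sign_and_errors(rng):
    profiles = generate_profiles(2, 8, concentration=0.3, seed=40)
    freq, _ = generate_populations(
        profiles, 20, mixture_mode="pure", noise_sd=0.01, seed=41
    )
    soc = fit_soc(freq, seed=42)
    d = euclidean_matrix(freq)
    # within-cluster distances are the small ones: strong negative correlation
    assert inherence_distance_correlation(soc, d) < -0.5
    with pytest.raises(ValueError, match="constant"):
        inherence_distance_correlation(np.zeros(20, dtype=int), d)
    with pytest.raises(ValueError, match="mismatch"):
        inherence_distance_correlation(np.array([0, 1]), d)


def test_estimator_clone_and_predict(rng):
    X = rng.uniform(size=(20, 4))
    soc = SelfOrganizingCloud(max_n=5, random_state=1)
    clone(soc)  # params round-trip
    soc.fit(X)
    np.testing.assert_array_equal(soc.predict(X), soc.labels_)
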