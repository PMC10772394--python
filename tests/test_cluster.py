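"""Hierarchical signaling clusters: distance, linkage, cut, sub-split."""

import numpy as np
import pandas as pd
import pytest

import rppasig as rs
from rppasig.core import ValidationError

from .oracles import linkage_to_merges, naive_complete_linkage


def _random_distance(rng, n):
    d = rng.uniform(0.1, 2.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


def test_pearson_distance_trivial_geometry():
    m = pd.DataFrame([[1.0, 2.0, 3.0],
                      [2.0, 4.0, 6.0],
                      [3.0, 2.0, 1.0]],
                     index=["same", "scaled", "anti"], columns=list("abc"))
    d = rs.pearson_distance(m)
    assert d.loc["same", "scaled"] == pytest.approx(0.0, abs=1e-12)
    assert d.loc["same", "anti"] == pytest.approx(2.0, abs=1e-12)
    assert (np.diag(d) == 0).all()


def test_pearson_distance_matches_corrcoef_oracle(rng):
    m = pd.DataFrame(rng.standard_normal((6, 10)))
    d = rs.pearson_distance(m)
    expected = 1.0 - np.corrcoef(m.to_numpy())
    np.testing.assert_allclose(d.to_numpy(), expected, atol=1e-12)


def test_pearson_distance_pairwise_complete_on_masks(rng):
    m = pd.DataFrame(rng.standard_normal((4, 12)))
    m.iloc[0, :3] = np.nan
    d = rs.pearson_distance(m)
    shared = m.iloc[[0, 1]].dropna(axis=1).to_numpy()
    expected = 1.0 - np.corrcoef(shared)[0, 1]
    assert d.iloc[0, 1] == pytest.approx(expected, abs=1e-12)


def test_zero_variance_profile_names_the_patient():
    m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
    with pytest.raises(ValidationError, match="flat"):
        rs.pearson_distance(m)


def test_hand_traced_three_point_linkage():
    d = np.array([[0.0, 1.0, 4.0],
                  [1.0, 0.0, 5.0],
                  [4.0, 5.0, 0.0]])
    Z = rs.complete_linkage(d)
    merges = linkage_to_merges(Z)
    assert merges[0] == (frozenset({0, 1}), 1.0)
    assert merges[1][0] == frozenset({0, 1, 2})
    assert merges[1][1] == pytest.approx(5.0)


def test_two_points_merge_at_their_distance():
    Z = rs.complete_linkage(np.array([[0.0, 0.7], [0.7, 0.0]]))
    assert Z.shape == (1, 4)
    assert Z[0, 2] == pytest.approx(0.7)


def test_linkage_rejects_asymmetric_input():
    d = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValidationError):
        rs.complete_linkage(d)


def test_linkage_matches_naive_agglomeration(rng):
    """Random 8-point instances against the exhaustive O(n^3) oracle."""
    for _ in range(25):
        d = _random_distance(rng, 8)
        ours = sorted(linkage_to_merges(rs.complete_linkage(d)),
                      key=lambda m: (m[1], sorted(m[0])))
        naive = sorted(naive_complete_linkage(d),
                       key=lambda m: (m[1], sorted(m[0])))
        for (ma, ha), (mb, hb) in zip(ours, naive):
            assert ma == mb
            assert ha == pytest.approx(hb, rel=1e-12)


def test_linkage_heights_are_monotone(rng):
    for _ in range(10):
        Z = rs.complete_linkage(_random_distance(rng, 12))
        assert (np.diff(Z[:, 2]) >= -1e-12).all()


def test_cut_tree_boundaries_and_traced_case():
    d = np.array([[0.0, 1.0, 4.0],
                  [1.0, 0.0, 5.0],
                  [4.0, 5.0, 0.0]])
    Z = rs.complete_linkage(d)
    assert len(set(rs.cut_tree_labels(Z, 0.5))) == 3      # below all merges
    assert len(set(rs.cut_tree_labels(Z, 10.0))) == 1     # above all merges
    labels = rs.cut_tree_labels(Z, 2.0)
    assert labels[0] == labels[1] != labels[2]
    # strictly-below convention: cutting exactly at a merge height excludes it
    assert len(set(rs.cut_tree_labels(Z, 1.0))) == 3
    # just below the final merge: exactly 2 clusters
    assert len(set(rs.cut_tree_labels(Z, Z[-1, 2] - 1e-9))) == 2


def test_labels_are_numbered_by_dendrogram_order(rng):
    Z = rs.complete_linkage(_random_distance(rng, 10))
    labels = rs.cut_tree_labels(Z, np.median(Z[:, 2]))
    from scipy.cluster.hierarchy import leaves_list
    seen = []
    for leaf in leaves_list(Z):
        if labels[leaf] not in seen:
            seen.append(labels[leaf])
    assert seen == sorted(seen) == list(range(1, max(labels) + 1))


def test_cluster_labels_invariant_to_row_permutation(rng):
    m = pd.DataFrame(rng.standard_normal((12, 8)),
                     index=[f"p{i}" for i in range(12)])
    a = rs.SignalingClusterer(cut_height=1.0).fit(m).labels_
    perm = rng.permutation(12)
    b = rs.SignalingClusterer(cut_height=1.0).fit(m.iloc[perm]).labels_
    joined = pd.DataFrame({"a": a, "b": b.reindex(a.index)})
    # same partition up to renumbering
    mapping = joined.groupby("a")["b"].nunique()
    assert (mapping == 1).all()
    assert joined.groupby("b")["a"].nunique().eq(1).all()


def test_split_recovers_planted_pairs():
    """Four points forming two tight pairs: the k=2 subtree cut of the merged
    cluster recovers the pairs as 'a'/'b' sub-labels."""
    d = np.array([
        [0.0, 0.1, 1.0, 1.1],
        [0.1, 0.0, 1.2, 1.0],
        [1.0, 1.2, 0.0, 0.2],
        [1.1, 1.0, 0.2, 0.0],
    ])
    Z = rs.complete_linkage(d)
    labels = rs.cut_tree_labels(Z, 5.0)          # one cluster
    refined = rs.split_cluster(Z, labels, labels[0], k=2)
    assert refined[0] == refined[1] != refined[2]
    assert refined[2] == refined[3]
    assert {str(v)[-1] for v in refined} == {"a", "b"}
    with pytest.raises(ValidationError):
        rs.split_cluster(Z, labels, labels[0], k=5)


def test_split_of_pair_gives_singletons():
    d = np.array([[0.0, 0.5], [0.5, 0.0]])
    Z = rs.complete_linkage(d)
    labels = rs.cut_tree_labels(Z, 2.0)
    refined = rs.split_cluster(Z, labels, labels[0], k=2)
    assert len(set(refined)) == 2


def test_cluster_means_matches_groupby_oracle(rng):
    m = pd.DataFrame(rng.standard_normal((9, 5)),
                     index=[f"p{i}" for i in range(9)])
    labels = np.array([1, 1, 1, 2, 2, 3, 3, 3, 3])
    means = rs.cluster_means(m, labels)
    for lab in (1, 2, 3):
        np.testing.assert_allclose(means.loc[lab],
                                   m[labels == lab].mean(), rtol=1e-12)
    # singleton cluster equals its own row
    means1 = rs.cluster_means(m.iloc[:4], np.array([1, 2, 2, 2]))
    np.testing.assert_allclose(means1.loc[1], m.iloc[0], rtol=1e-12)


def test_cluster_summary_composition(small_cohort):
    clinical = small_cohort["clinical"]
    est = rs.SignalingClusterer(cut_height=1.2).fit(small_cohort["harmonized"])
    summary = rs.cluster_summary(
        est.labels_,
        clinical.set_index("patient_id").loc[est.labels_.index].reset_index())
    assert summary["n"].sum() == len(est.labels_)
    assert ((summary["pcr_rate"] >= 0) & (summary["pcr_rate"] <= 1)).all()
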