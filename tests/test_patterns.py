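"""Hierarchical clustering, template labelling, Newick export, and PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

import rootarray as ra
from rootarray.differential import zscores
from rootarray.patterns import (SamplePCA, TemporalClusterer, cut_clusters,
                                hcluster, label_templates, pca_samples,
                                to_newick)
from rootarray.simulate import canonical_templates


def _brute_force_average_linkage(dist):
    """Independent agglomerator: repeatedly merge the closest pair under
    average linkage, returning the sequence of merge heights and the
    partition trace."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return heights


def test_identical_profiles_merge_at_height_zero():
    profiles = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    Z = hcluster(profiles, metric="euclidean")
    assert Z[0, 2] == 0.0


def test_average_linkage_hand_computed_three_points():
    """d(A,B)=0.1, d(A,C)=d(B,C)=0.9: first merge (A,B) at 0.1, then C
    joins at the average distance 0.9."""
    condensed = np.array([0.1, 0.9, 0.9])
    Z = hcluster(condensed, metric="precomputed")
    assert set(Z[0, :2]) == {0, 1} and Z[0, 2] == pytest.approx(0.1)
    assert Z[1, 2] == pytest.approx(0.9)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_merge_heights_match_brute_force_agglomeration(seed):
    rng = np.random.default_rng(seed)
    profiles = pd.DataFrame(rng.normal(size=(6, 5)))
    Z = hcluster(profiles, metric="euclidean")
    from scipy.spatial.distance import squareform, pdist
    dist = squareform(pdist(profiles.to_numpy()))
    np.testing.assert_allclose(Z[:, 2], _brute_force_average_linkage(dist),
                               rtol=1e-10)


def test_unsupported_metric_or_linkage():
    profiles = pd.DataFrame(np.eye(3))
    with pytest.raises(ValueError):
        hcluster(profiles, metric="cosine")
    with pytest.raises(ValueError):
        hcluster(profiles, linkage="ward2")


def test_zero_variance_profile_rejected_by_correlation_metric():
    profiles = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
    with pytest.raises(ValueError, match="zero-variance"):
        hcluster(profiles, metric="correlation")


def test_cut_clusters_extremes():
    rng = np.random.default_rng(0)
    profiles = pd.DataFrame(rng.normal(size=(5, 4)),
                            index=[f"g{i}" for i in range(5)])
    Z = hcluster(profiles, metric="euclidean")
    singletons = cut_clusters(Z, profiles, k=5)
    assert singletons.labels.nunique() == 5
    one = cut_clusters(Z, profiles, k=1)
    assert one.labels.nunique() == 1
    with pytest.raises(ValueError):
        cut_clusters(Z, profiles, k=0)
    with pytest.raises(ValueError):
        cut_clusters(Z, profiles, k=6)


def test_centroid_reconstruction_and_row_permutation_invariance():
    rng = np.random.default_rng(1)
    profiles = pd.DataFrame(rng.normal(size=(30, 7)),
                            index=[f"g{i}" for i in range(30)])
    Z = hcluster(profiles, metric="euclidean")
    result = cut_clusters(Z, profiles, k=4)
    for cid, centroid in result.centroids.iterrows():
        members = result.labels.index[result.labels == cid]
        np.testing.assert_allclose(profiles.loc[members].mean(axis=0),
                                   centroid, atol=1e-12)
    perm = profiles.sample(frac=1, random_state=2)
    result_p = cut_clusters(hcluster(perm, metric="euclidean"), perm, k=4)
    assert adjusted_rand_score(result.labels.loc[perm.index],
                               result_p.labels) == pytest.approx(1.0)


class TestTemplateLabelling:
    def test_exact_template_gets_label_with_unit_correlation(self):
        tpl = canonical_templates()
        profiles = pd.concat([tpl.loc[["III"]]] * 3)
        profiles.index = ["a", "b", "c"]
        Z = hcluster(np.array([0.0, 0.0, 0.0]), metric="precomputed")
        result = cut_clusters(Z, profiles, k=1)
        result = label_templates(result)
        assert result.template_labels == {1: "III"}

    def test_anticorrelated_centroid_unmatched(self):
        templates = pd.DataFrame({"10": [0.0], "15": [1.0], "20": [2.0]},
                                 index=["up"])
        profiles = pd.DataFrame({"10": [2.0, 2.1], "15": [1.0, 1.1],
                                 "20": [0.0, 0.1]})
        Z = hcluster(profiles, metric="euclidean")
        result = label_templates(cut_clusters(Z, profiles, k=1),
                                 templates=templates)
        assert result.template_labels == {1: "unmatched"}

    def test_greedy_assignment_is_one_to_one(self):
        tpl = canonical_templates()
        profiles = pd.concat([tpl + 1e-3 * (i + 1) for i in range(2)])
        profiles.index = [f"g{i}" for i in range(len(profiles))]
        clusterer = TemporalClusterer(n_clusters=6).fit(profiles)
        labels = [v for v in clusterer.template_labels_.values()
                  if v != "unmatched"]
        assert len(labels) == len(set(labels)) == 6


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_planted_six_template_recovery(seed):
    """Planted six-pattern DE genes are recovered by the k=6 cut with
    near-perfect agreement and correctly named templates."""
    counts = {f"de_cluster_{t}": 60 for t in ("I", "II", "III", "IV", "V", "VI")}
    cfg = ra.SimulationConfig(class_counts=counts, seed=seed)
    em, truth = ra.simulate(cfg)
    z, *_ = zscores(em.values)
    zmeans = pd.DataFrame(
        {s: z[em.stage_columns(s)].mean(axis=1) for s in em.stage_order}
    )
    clusterer = TemporalClusterer(n_clusters=6).fit(zmeans)
    assert adjusted_rand_score(truth["cluster"], clusterer.labels_) >= 0.95
    recovered = clusterer.labels_.map(clusterer.template_labels_)
    assert (recovered == truth["cluster"]).mean() >= 0.95


def test_newick_export_contains_leaves_and_heights():
    profiles = pd.DataFrame([[0.0, 0.0], [0.0, 1.0], [5.0, 5.0]],
                            index=["a", "b", "c"])
    Z = hcluster(profiles, metric="euclidean")
    nwk = to_newick(Z, profiles.index)
    assert nwk.strip().endswith(";")
    for leaf in ("a", "b", "c"):
        assert leaf in nwk
    assert ":" in nwk  # branch lengths present


class TestPCA:
    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=50)
        values = pd.DataFrame(
            {"s1": col, "s2": col, "s3": rng.normal(size=50),
             "s4": rng.normal(size=50)}
        )
        scores, _ = pca_samples(values, n_components=2)
        np.testing.assert_allclose(scores.loc["s1"], scores.loc["s2"],
                                   atol=1e-9)

    def test_two_samples_pc1_explains_everything(self):
        values = pd.DataFrame({"s1": [0.0, 1.0, 2.0], "s2": [1.0, 3.0, 2.0]})
        scores, evr = pca_samples(values, n_components=3)
        assert evr[0] == pytest.approx(1.0)

    def test_sign_convention_deterministic(self, small_em):
        s1, _ = pca_samples(small_em.values)
        s2, _ = pca_samples(small_em.values)
        pd.testing.assert_frame_equal(s1, s2)
        est = SamplePCA(n_components=2).fit(small_em.values)
        pd.testing.assert_frame_equal(est.scores_, s1.iloc[:, :2])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_replicate_pairs_cluster_in_pc_space(self, scaled_counts, seed):
        """Mean within-replicate-pair distance is smaller than mean
        between-stage distance in 3-component PC space."""
        cfg = ra.SimulationConfig(class_counts=scaled_counts, seed=seed)
        em, _ = ra.simulate(cfg)
        z, *_ = zscores(em.values)
        scores, _ = pca_samples(z, n_components=3)
        within, between = [], []
        stages = em.design["stage"]
        for a in scores.index:
            for b in scores.index:
                if b <= a:
                    continue
                d = np.linalg.norm(scores.loc[a] - scores.loc[b])
                (within if stages[a] == stages[b] else between).append(d)
        assert np.mean(within) < np.mean(between)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_sample_tree_splits_early_from_late_stages(seed):
    """With temporally smooth (monotone) templates, the k=2 cut of the
    sample dendrogram separates the early fibrous/thick stages
    {10,15,20} from the later tuberous stages {30,60,90,120}."""
    counts = {"constitutive": 1400, "de_cluster_V": 270, "de_cluster_VI": 270}
    cfg = ra.SimulationConfig(class_counts=counts, seed=seed)
    em, _ = ra.simulate(cfg)
    z, *_ = zscores(em.values)
    Z = hcluster(z.T, metric="correlation")
    cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    groups = {}
    for sample, c in zip(z.columns, cut):
        groups.setdefault(c, set()).add(em.design.at[sample, "stage"])
    assert sorted(map(sorted, groups.values())) == [
        ["10", "15", "20"], ["120", "30", "60", "90"]
    ]
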