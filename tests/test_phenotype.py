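"""Meta-clustering, embedding, profiles, and immune annotation."""

import logging

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from imcscope import phenotype
from imcscope.phenotype import (
    NON_IMMUNE_LABEL,
    annotate_immune,
    phenograph_cluster,
    profile_clusters,
    tsne_embed,
)


def _blob_cells(n_per=200, sep=10.0, dims=5, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 1, (n_per, dims)), rng.normal(sep, 1, (n_per, dims))]
    )
    return pd.DataFrame(X, columns=[f"m{i}" for i in range(dims)]), np.repeat(
        [0, 1], n_per
    )


class TestPhenographCluster:
    def test_two_blobs_recovered_at_default_k(self):
        cells, truth = _blob_cells()
        assign = phenograph_cluster(cells, list(cells.columns), k=75, seed=0)
        assert assign.n_clusters == 2
        assert adjusted_rand_score(truth, assign.cell_cluster) == 1.0

    def test_small_k_refines_but_never_mixes_blobs(self):
        # with k far below the blob size, modularity maximization may split
        # a blob into sub-communities, but clusters must stay pure
        cells, truth = _blob_cells()
        assign = phenograph_cluster(cells, list(cells.columns), k=15, seed=0)
        assert assign.n_clusters >= 2
        for c in range(1, assign.n_clusters + 1):
            assert len(set(truth[assign.cell_cluster == c])) == 1

    def test_identical_points_single_cluster(self):
        cells = pd.DataFrame(np.ones((10, 3)), columns=list("abc"))
        assign = phenograph_cluster(cells, list("abc"), k=75, seed=0)
        assert assign.n_clusters == 1

    def test_deterministic_for_fixed_seed(self):
        cells, _ = _blob_cells(seed=2)
        a = phenograph_cluster(cells, list(cells.columns), k=20, seed=5)
        b = phenograph_cluster(cells, list(cells.columns), k=20, seed=5)
        assert np.array_equal(a.cell_cluster, b.cell_cluster)

    def test_k_below_one_rejected(self):
        cells, _ = _blob_cells(n_per=5)
        with pytest.raises(ValueError):
            phenograph_cluster(cells, list(cells.columns), k=0)

    def test_sizes_sum_to_total(self):
        cells, _ = _blob_cells(seed=3)
        assign = phenograph_cluster(cells, list(cells.columns), k=30, seed=0)
        assert assign.clusters["size"].sum() == len(cells)
        assert (assign.cell_cluster >= 1).all()


class TestTsne:
    def test_reproducible_for_fixed_seed(self):
        cells, _ = _blob_cells(n_per=80)
        e1 = tsne_embed(cells, list(cells.columns), seed=1)
        e2 = tsne_embed(cells, list(cells.columns), seed=1)
        assert np.array_equal(e1, e2)

    def test_blobs_separate_in_embedding(self):
        cells, truth = _blob_cells(n_per=100, seed=4)
        emb = tsne_embed(cells, list(cells.columns), seed=0)
        c0, c1 = emb[truth == 0], emb[truth == 1]
        between = np.linalg.norm(c0.mean(0) - c1.mean(0))
        within = np.mean(
            [np.linalg.norm(c - c.mean(0), axis=1).mean() for c in (c0, c1)]
        )
        assert between > 3 * within

    def test_perplexity_guard(self, caplog):
        cells, _ = _blob_cells(n_per=40)  # n=80 <= 3*perplexity
        with caplog.at_level(logging.WARNING, logger="imcscope.phenotype"):
            tsne_embed(cells, list(cells.columns), perplexity=30, seed=0)
        assert any("perplexity" in r.message for r in caplog.records)

    def test_nonfinite_rejected(self):
        cells, _ = _blob_cells(n_per=40)
        cells.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            tsne_embed(cells, list(cells.columns), seed=0)


class TestProfileClusters:
    def test_single_cluster_z_is_zero(self):
        cells = pd.DataFrame({"CD3": [1.0, 2.0, 3.0]})
        assign = phenotype.ClusterAssignment(
            cell_cluster=np.ones(3, dtype=int),
            clusters=pd.DataFrame({"meta_cluster": [1], "size": [3]}),
        )
        prof = profile_clusters(cells, assign, ["CD3"])
        assert (prof.z == 0).all().all()

    def test_two_cluster_z_hand_computed(self):
        # medians {0, 10} -> mean 5, population SD 5 -> z = -1, +1
        cells = pd.DataFrame({"CD3": [0.0, 0.0, 10.0, 10.0]})
        assign = phenotype.ClusterAssignment(
            cell_cluster=np.array([1, 1, 2, 2]),
            clusters=pd.DataFrame({"meta_cluster": [1, 2], "size": [2, 2]}),
        )
        prof = profile_clusters(cells, assign, ["CD3"])
        assert prof.z["CD3"].tolist() == [-1.0, 1.0]

    def test_invariant_to_cell_order(self):
        rng = np.random.default_rng(0)
        cells = pd.DataFrame({"CD3": rng.lognormal(1, 1, 100)})
        clus = rng.integers(1, 4, 100)
        assign = phenotype.ClusterAssignment(
            cell_cluster=clus,
            clusters=pd.DataFrame(
                {"meta_cluster": [1, 2, 3], "size": np.bincount(clus)[1:]}
            ),
        )
        perm = rng.permutation(100)
        assign_p = phenotype.ClusterAssignment(
            cell_cluster=clus[perm], clusters=assign.clusters
        )
        a = profile_clusters(cells, assign, ["CD3"])
        b = profile_clusters(cells.iloc[perm].reset_index(drop=True), assign_p, ["CD3"])
        pd.testing.assert_frame_equal(a.medians, b.medians)


class TestAnnotateImmune:
    @staticmethod
    def _assignment(sizes):
        return phenotype.ClusterAssignment(
            cell_cluster=np.repeat(np.arange(1, len(sizes) + 1), sizes),
            clusters=pd.DataFrame(
                {"meta_cluster": np.arange(1, len(sizes) + 1), "size": sizes}
            ),
        )

    def test_ctl_numbering_by_size(self, panel):
        # two clusters sharing the CD45/CD3/CD8 pattern, sizes 500 and 200:
        # the larger becomes CTL-1
        medians = pd.DataFrame(
            0.0, index=[1, 2], columns=list(panel.markers)
        )
        for m, hi in [("CD45", 18.0), ("CD3", 15.0), ("CD8", 14.0)]:
            medians.loc[1, m] = hi
            medians.loc[2, m] = hi * 0.6
        z = pd.DataFrame(2.0, index=[1, 2], columns=list(panel.markers))
        prof = phenotype.ClusterProfile(medians=medians, z=z)
        assign = self._assignment([500, 200])
        ann = annotate_immune(assign, prof, panel)
        labels = ann.clusters.set_index("meta_cluster")["phenotype_label"]
        assert labels[1] == "CTL-1"
        assert labels[2] == "CTL-2"

    def test_all_hepatocyte_no_immune_clusters(self, panel):
        rng = np.random.default_rng(0)
        cells = pd.DataFrame({m: np.abs(rng.normal(0, 0.05, 300)) for m in panel.markers})
        cells["DNA-Ir"] = rng.normal(20, 2, 300)
        assign = self._assignment([150, 150])
        prof = profile_clusters(cells, assign, list(panel.markers))
        ann = annotate_immune(assign, prof, panel)
        assert not ann.clusters["immune"].any()
        assert (ann.clusters["phenotype_label"] == NON_IMMUNE_LABEL).all()

    def test_no_immune_markers_rejected(self, panel):
        cells = pd.DataFrame({"Collagen1": [1.0, 2.0], "DNA-Ir": [3.0, 4.0]})
        assign = self._assignment([1, 1])
        prof = profile_clusters(cells, assign, ["Collagen1", "DNA-Ir"])
        with pytest.raises(ValueError):
            annotate_immune(assign, prof, panel)


@pytest.fixture(scope="module")
def recovered(balanced_cohort, panel):
    cells, truth_labels = balanced_cohort
    assign = phenograph_cluster(cells, list(panel.markers), k=75, seed=0)
    prof = profile_clusters(cells, assign, list(panel.markers))
    ann = annotate_immune(assign, prof, panel)
    return cells, truth_labels, ann, prof


class TestFullRecovery:
    """Clustering + annotation against the simulator's planted phenotypes."""

    def test_ari_against_planted_phenotypes(self, recovered):
        _, truth_labels, ann, _ = recovered
        assert adjusted_rand_score(truth_labels, ann.cell_cluster) >= 0.9

    def test_all_eleven_immune_labels_recovered(self, recovered):
        _, _, ann, _ = recovered
        immune_labels = set(
            ann.clusters.loc[ann.clusters["immune"], "phenotype_label"]
        )
        from imcscope.simulate import IMMUNE_PHENOTYPES

        assert immune_labels == set(IMMUNE_PHENOTYPES)

    def test_macrophage_clusters_lack_cd3(self, recovered):
        _, _, ann, prof = recovered
        macs = ann.clusters.loc[
            ann.clusters["phenotype_label"].str.startswith("Macrophage"),
            "meta_cluster",
        ]
        assert len(macs) == 2
        assert (prof.z.loc[macs, "CD3"] < 1.0).all()

    def test_partition_exhaustive_and_disjoint(self, recovered):
        cells, _, ann, _ = recovered
        assert ann.clusters["size"].sum() == len(cells)
        immune_mask = ann.immune_cell_mask()
        labels = ann.cell_labels()
        assert ((labels == NON_IMMUNE_LABEL) == ~immune_mask).all()
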