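"""Co-association consensus, anchoring, similarity and merge behaviour."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cytoconsensus import (
    ChannelPanel,
    EventMatrix,
    anchor_and_merge,
    build_coassociation,
    cluster_similarity,
    consensus_partition,
    cross_embedding_consistency,
)
from cytoconsensus.consensus import ConsensusPopulations
from cytoconsensus.errors import ParameterError
from cytoconsensus.highdim import ClusteringResult, EmbeddingSet
from cytoconsensus.io_model import Scale

from conftest import SMALL_EVENTS, pooled_truth


def _cr(labels):
    return ClusteringResult(method="graph_community", labels=np.asarray(labels))


def _matrix(values, channels=None):
    channels = channels or tuple(f"M{i}" for i in range(values.shape[1]))
    return EventMatrix(values, ChannelPanel(channels), Scale.transformed)


def _meta(n, sample_type="labeled_cells", stain="", day=1, passage=5):
    return pd.DataFrame({
        "sample_id": ["s"] * n, "sample_type": [sample_type] * n,
        "stain_channel": [stain] * n, "day": [day] * n,
        "passage": [passage] * n, "source_row": np.arange(n)})


class TestCoassociation:
    def test_hand_enumeration(self):
        # partitions {AB|CD}, {AB|CD}, {AC|BD} over 4 events
        cls = [_cr([0, 0, 1, 1]), _cr([0, 0, 1, 1]), _cr([0, 1, 0, 1])]
        c = build_coassociation(cls, subsample=4, seed=0)
        m = c.matrix
        assert m[0, 1] == pytest.approx(2 / 3)
        assert m[0, 2] == pytest.approx(1 / 3)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_identical_partitions_binary(self):
        cls = [_cr([0, 0, 1, 1, 2])] * 3
        c = build_coassociation(cls, subsample=5, seed=0)
        assert set(np.unique(c.matrix)) <= {0.0, 1.0}

    def test_mismatched_event_sets_rejected(self):
        with pytest.raises(ParameterError):
            build_coassociation([_cr([0, 1]), _cr([0, 1, 2])])


class TestConsensusPartition:
    def test_recovers_identical_partitions(self):
        cls = [_cr([0, 0, 1, 1, 2, 2])] * 3
        c = build_coassociation(cls, subsample=6, seed=0)
        labels = consensus_partition(c, cut=0.5)
        assert adjusted_rand_score([0, 0, 1, 1, 2, 2], labels) == 1.0

    def test_cut_zero_single_cluster(self):
        cls = [_cr([0, 0, 1, 1]), _cr([0, 1, 0, 1])]
        c = build_coassociation(cls, subsample=4, seed=0)
        assert len(np.unique(consensus_partition(c, cut=0.0))) == 1

    def test_four_event_example_brute_force(self):
        """At cut 0.5 the majority partition {AB|CD} must emerge; verified
        against direct average-linkage on the 4x4 distance matrix."""
        cls = [_cr([0, 0, 1, 1]), _cr([0, 0, 1, 1]), _cr([0, 1, 0, 1])]
        c = build_coassociation(cls, subsample=4, seed=0)
        labels = consensus_partition(c, cut=0.5)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_centroid_extension_covers_all_events(self):
        rng = np.random.default_rng(0)
        vals = np.vstack([rng.normal(0, 1, (100, 3)),
                          rng.normal(10, 1, (100, 3))])
        m = _matrix(vals)
        truth = np.repeat([0, 1], 100)
        cls = [_cr(truth), _cr(truth)]
        c = build_coassociation(cls, subsample=50, seed=1)
        labels = consensus_partition(c, cut=0.5, m=m)
        assert labels.size == 200
        assert adjusted_rand_score(truth, labels) == 1.0


class TestClusterSimilarity:
    def test_same_distribution_near_zero(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, (2000, 3))
        labels = np.r_[np.zeros(1000, int), np.ones(1000, int)]
        s = cluster_similarity(_matrix(vals), labels, 0, 1)
        assert s.aggregate < 0.5

    def test_ten_sigma_offset(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (2000, 3))
        b = rng.normal(0, 1, (2000, 3))
        b[:, 1] += 10.0
        labels = np.r_[np.zeros(2000, int), np.ones(2000, int)]
        s = cluster_similarity(_matrix(np.vstack([a, b])), labels, 0, 1)
        assert s.aggregate == pytest.approx(10.0, rel=0.15)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (400, 2))
        labels = rng.integers(0, 2, 400)
        m = _matrix(vals)
        a = cluster_similarity(m, labels, 0, 1)
        b = cluster_similarity(m, labels, 1, 0)
        assert a.aggregate == pytest.approx(b.aggregate)


class TestAnchorAndMerge:
    def test_pure_bead_cluster_gets_stain_role(self):
        rng = np.random.default_rng(4)
        n = 600
        vals = np.vstack([rng.normal(0, 1, (n, 2)),
                          rng.normal(8, 1, (n, 2))])
        meta = pd.concat([
            _meta(n, "bead_single_stain", stain="M0"),
            _meta(n, "labeled_cells")], ignore_index=True)
        labels = np.r_[np.zeros(n, int), np.ones(n, int)]
        pops = anchor_and_merge(_matrix(vals), labels, meta, null_reps=50,
                                B_requested=40)
        assert pops.roles.get("bead_M0") == "bead_control:M0"

    def test_random_split_of_one_population_merges(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, (3000, 3))
        labels = rng.integers(0, 2, 3000)  # arbitrary split of one blob
        pops = anchor_and_merge(_matrix(vals), labels, _meta(3000),
                                null_reps=50, B_requested=40)
        labeled = [r for r in pops.roles.values() if r == "labeled_population"]
        assert len(labeled) == 1

    def test_separated_populations_never_merge(self):
        """Populations >5 robust-SD apart stay distinct across seeds."""
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            a = rng.normal(0, 1, (800, 3))
            b = rng.normal(0, 1, (800, 3))
            b[:, 0] += 8.0
            labels = np.r_[np.zeros(800, int), np.ones(800, int)]
            pops = anchor_and_merge(_matrix(np.vstack([a, b])), labels,
                                    _meta(1600), null_reps=50, B_requested=40)
            labeled = [r for r in pops.roles.values()
                       if r == "labeled_population"]
            assert len(labeled) == 2

    def test_merge_outcome_order_insensitive(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, (700, 2))
        b = rng.normal(12, 1, (700, 2))
        half = np.r_[np.zeros(350, int), np.ones(350, int)]
        labels = np.r_[half, 2 + half[::-1]]  # each blob pre-split in two
        m = _matrix(np.vstack([a, b]))
        p1 = anchor_and_merge(m, labels, _meta(1400), null_reps=50,
                              B_requested=30)
        relabel = np.array([3, 2, 1, 0])[labels]  # permuted cluster ids
        p2 = anchor_and_merge(m, relabel, _meta(1400), null_reps=50,
                              B_requested=30)
        assert adjusted_rand_score(p1.labels.astype(str),
                                   p2.labels.astype(str)) == 1.0

    def test_no_controls_warns(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, (500, 2))
        with pytest.warns(UserWarning, match="anchoring skipped"):
            anchor_and_merge(_matrix(vals), np.zeros(500, int), _meta(500),
                             null_reps=50, B_requested=25)


class TestFullRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_reference_study_recovered(self, seed):
        """The consensus pipeline recovers the generated structure: one
        unlabeled group, one negative-bead group, five stain-bead groups,
        and the four labeled populations (agreement >= 0.9)."""
        from cytoconsensus import generate_study, reference_design
        from cytoconsensus.pipeline import run_consensus

        design = reference_design(events_per_sample=SMALL_EVENTS)
        study = generate_study(design, seed=300 + seed)
        pops, t, meta = run_consensus(study, seed=300 + seed,
                                      coassoc_subsample=2000,
                                      null_reps=100, b_requested=50)
        roles = list(pops.roles.values())
        assert roles.count("unlabeled_cells") == 1
        assert roles.count("negative_beads") == 1
        assert sum(r.startswith("bead_control:") for r in roles) == 5
        assert roles.count("labeled_population") == 4

        truth = pooled_truth(study, meta)
        lab = (meta["sample_type"] == "labeled_cells").to_numpy()
        ari = adjusted_rand_score(truth[lab], pops.labels[lab].astype(str))
        assert ari >= 0.9


class TestCrossEmbeddingConsistency:
    def test_isolated_population_scores_one(self):
        rng = np.random.default_rng(8)
        layout = np.vstack([rng.normal(0, 1, (300, 2)),
                            rng.normal(25, 1, (300, 2))])
        labels = np.array(["a"] * 300 + ["b"] * 300, dtype=object)
        pops = ConsensusPopulations(
            labels=labels, roles={"a": "labeled_population",
                                  "b": "labeled_population"})
        emb = EmbeddingSet(layouts={"tsne": layout, "umap": layout[:, ::-1]},
                           seed=0)
        scores = cross_embedding_consistency(pops, emb, bandwidth=1.0,
                                             density_quantile=0.1)
        assert scores["a"] == 1.0
        assert scores["b"] == 1.0

    def test_scattered_population_scores_zero(self):
        rng = np.random.default_rng(9)
        layout = rng.normal(0, 1, (600, 2))
        labels = np.array(["bulk"] * 540 + ["sparse"] * 60, dtype=object)
        rng.shuffle(labels)
        pops = ConsensusPopulations(
            labels=labels, roles={"bulk": "labeled_population",
                                  "sparse": "labeled_population"})
        emb = EmbeddingSet(layouts={"tsne": layout}, seed=0)
        scores = cross_embedding_consistency(pops, emb, bandwidth=1.0,
                                             density_quantile=0.1)
        assert scores["sparse"] == 0.0
        assert 0.0 <= scores["bulk"] <= 1.0
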