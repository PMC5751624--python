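"""ncRNA similarity networks, RWR prioritisation and LOOCV evaluation."""

import numpy as np
import pytest
from scipy.stats import norm

from infdissim.disease_similarity import SimilarityMatrix
from infdissim.ncrna_prediction import (
    AssociationTable,
    ConvergenceError,
    DegenerateNetworkError,
    NcrnaSimilarityNetwork,
    RWRConfig,
    build_ncrna_similarity,
    column_normalize,
    loocv_auc,
    rank_candidates,
    read_associations,
    rwr,
)
from infdissim.pipeline import disease_similarity_pipeline


def dissim_from(entries, ids):
    values = np.eye(len(ids))
    idx = {e: i for i, e in enumerate(ids)}
    for (x, y), s in entries.items():
        values[idx[x], idx[y]] = values[idx[y], idx[x]] = s
    return SimilarityMatrix(tuple(ids), values)


def net_from_sim(sim_values, ids, assoc=None):
    sim = SimilarityMatrix(tuple(ids), sim_values)
    assoc = assoc or AssociationTable(frozenset())
    dummy = np.zeros_like(sim.values)
    return NcrnaSimilarityNetwork(sim, dummy, dummy, assoc)


class TestAssociationTable:
    def test_reader_ignores_header_comment_and_extra_column(self, tmp_path):
        p = tmp_path / "assoc.tsv"
        p.write_text(
            "# associations\nncRNA\tdisease\nr1\tDOID:1\tPMID:1\nr2\tDOID:2\nr1\tDOID:1\n"
        )
        table = read_associations(str(p))
        assert table.pairs == {("r1", "DOID:1"), ("r2", "DOID:2")}

    def test_restrict_drops_unresolvable(self):
        t = AssociationTable(frozenset({("r1", "d1"), ("r1", "d2"), ("r2", "d2")}))
        kept = t.restrict_to_diseases(["d1"])
        assert kept.pairs == {("r1", "d1")}


class TestBuildNcrnaSimilarity:
    def test_identical_disease_sets_score_one(self):
        dissim = dissim_from({("d1", "d2"): 0.4, ("d1", "d3"): 0.1}, ("d1", "d2", "d3"))
        assoc = AssociationTable(
            frozenset({("r1", "d1"), ("r1", "d2"), ("r2", "d1"), ("r2", "d2"),
                       ("r3", "d3")})
        )
        net = build_ncrna_similarity(assoc, dissim)
        assert net.sim.get("r1", "r2") == 1.0

    def test_degenerate_network_is_hard_error(self):
        dissim = dissim_from({}, ("d1", "d2", "d3"))  # all off-diagonals 0
        assoc = AssociationTable(
            frozenset({("r1", "d1"), ("r2", "d2"), ("r3", "d3")})
        )
        with pytest.raises(DegenerateNetworkError):
            build_ncrna_similarity(assoc, dissim)

    def test_zscore_standardization(self):
        """Scores {0.2, 0.5, 0.8}: z = (s - 0.5)/sd_pop with sd_pop = sqrt(0.06)."""
        dissim = dissim_from(
            {("d1", "d2"): 0.2, ("d1", "d3"): 0.5, ("d2", "d3"): 0.8},
            ("d1", "d2", "d3"),
        )
        assoc = AssociationTable(
            frozenset({("r1", "d1"), ("r2", "d2"), ("r3", "d3")})
        )
        net = build_ncrna_similarity(assoc, dissim)
        iu = np.triu_indices(3, k=1)
        z = np.sort(net.zscores[iu])
        np.testing.assert_allclose(
            z, [-np.sqrt(1.5), 0.0, np.sqrt(1.5)], atol=1e-12
        )
        # pooled z has mean 0 and population sd 1; p(z=0) = 0.5 one-sided
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(net.pvalues[iu], norm.sf(net.zscores[iu]))

    def test_row_order_invariance(self):
        dissim = dissim_from(
            {("d1", "d2"): 0.2, ("d1", "d3"): 0.5, ("d2", "d3"): 0.8},
            ("d1", "d2", "d3"),
        )
        pairs = [("r1", "d1"), ("r1", "d2"), ("r2", "d2"), ("r3", "d3")]
        a = build_ncrna_similarity(AssociationTable(frozenset(pairs)), dissim)
        b = build_ncrna_similarity(
            AssociationTable(frozenset(reversed(pairs))), dissim
        )
        np.testing.assert_array_equal(a.sim.values, b.sim.values)


class TestRWR:
    def test_restart_only(self):
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = rwr(adj, [0], RWRConfig(gamma=1.0))
        np.testing.assert_allclose(p.values, [1.0, 0.0])

    def test_two_node_fixed_point(self):
        """Seed node 1, gamma 0.5: p1 = 0.5 + 0.5 p2, p2 = 0.5 p1 -> (2/3, 1/3)."""
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = rwr(adj, [0], RWRConfig(gamma=0.5))
        np.testing.assert_allclose(p.values, [2 / 3, 1 / 3], atol=1e-9)

    def test_mass_conservation_and_fixed_point(self):
        rng = np.random.default_rng(0)
        adj = rng.uniform(size=(8, 8))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0.0)
        cfg = RWRConfig(gamma=0.7)
        p = rwr(adj, [1, 4], cfg)
        assert p.values.sum() == pytest.approx(1.0, abs=1e-9)
        A = column_normalize(adj)
        p0 = np.zeros(8)
        p0[[1, 4]] = 0.5
        residual = np.abs(p.values - (cfg.gamma * p0 + (1 - cfg.gamma) * A @ p.values)).sum()
        assert residual < 10 * cfg.tol
        direct = np.linalg.solve(np.eye(8) - (1 - cfg.gamma) * A, cfg.gamma * p0)
        np.testing.assert_allclose(p.values, direct, atol=1e-8)

    def test_zero_column_becomes_uniform(self):
        adj = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        A = column_normalize(adj)
        np.testing.assert_allclose(A[:, 2], [1 / 3, 1 / 3, 1 / 3])
        assert np.allclose(A.sum(axis=0), 1.0)

    def test_no_seeds_is_error(self):
        with pytest.raises(ValueError):
            rwr(np.eye(2), [], RWRConfig())

    def test_iteration_cap_raises_with_residual(self):
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ConvergenceError) as err:
            rwr(adj, [0], RWRConfig(gamma=0.5, max_iter=2))
        assert err.value.residual > 0


class TestRankCandidates:
    def test_isolated_candidates_tie_in_id_order(self):
        ids = ("rA", "rB", "rC", "rD")
        net = net_from_sim(np.eye(4), ids)
        assoc = AssociationTable(frozenset({("rA", "d")}))
        ranking = rank_candidates("d", assoc, net, RWRConfig())
        assert [r for r, _ in ranking] == ["rB", "rC", "rD"]
        scores = [s for _, s in ranking]
        assert len(set(scores)) == 1

    def test_similar_candidate_ranks_first(self):
        ids = ("rA", "rB", "rC", "rD")
        values = np.eye(4)
        sims = {(0, 1): 0.9, (0, 2): 0.1, (0, 3): 0.1, (1, 2): 0.1, (1, 3): 0.1,
                (2, 3): 0.1}
        for (i, j), s in sims.items():
            values[i, j] = values[j, i] = s
        net = net_from_sim(values, ids)
        assoc = AssociationTable(frozenset({("rA", "d")}))
        ranking = rank_candidates("d", assoc, net, RWRConfig())
        assert ranking[0][0] == "rB"

    def test_seeds_never_in_output(self):
        ids = ("rA", "rB", "rC")
        values = np.eye(3)
        values[0, 1] = values[1, 0] = 0.5
        values[1, 2] = values[2, 1] = 0.3
        net = net_from_sim(values, ids)
        assoc = AssociationTable(frozenset({("rA", "d"), ("rB", "d")}))
        ranking = rank_candidates("d", assoc, net, RWRConfig())
        assert [r for r, _ in ranking] == ["rC"]

    def test_disease_without_ncrnas_is_error(self):
        net = net_from_sim(np.eye(2), ("rA", "rB"))
        with pytest.raises(ValueError):
            rank_candidates("d", AssociationTable(frozenset()), net, RWRConfig())


class TestLoocv:
    def _world_network(self, default_world, default_pipeline):
        net = build_ncrna_similarity(
            default_world.ncrna_disease, default_pipeline.similarity
        )
        return net

    def test_all_singleton_diseases_is_error(self):
        ids = ("rA", "rB")
        values = np.eye(2)
        values[0, 1] = values[1, 0] = 0.5
        assoc = AssociationTable(frozenset({("rA", "d1"), ("rB", "d2")}))
        net = net_from_sim(values, ids, assoc)
        with pytest.raises(ValueError, match="eligible"):
            loocv_auc(assoc, net, RWRConfig())

    def test_auc_equals_bruteforce_pairwise(self, default_world, default_pipeline):
        net = self._world_network(default_world, default_pipeline)
        res = loocv_auc(net.assoc, net, RWRConfig())
        pos = res.scores[res.labels == 1]
        neg = res.scores[res.labels == 0]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert res.auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    def test_planted_world_recovery(self, default_world, default_pipeline):
        """RWR on the planted-cluster LSN recovers held-out associations."""
        net = self._world_network(default_world, default_pipeline)
        res = loocv_auc(net.assoc, net, RWRConfig(gamma=0.85))
        assert res.auc > 0.9

    def test_noise_similarity_gives_chance_auc(self, default_world):
        """i.i.d.-noise ncRNA similarity: mean LOOCV AUC near 0.5 over 20 seeds."""
        assoc = default_world.ncrna_disease
        ids = assoc.ncrnas
        n = len(ids)
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            raw = rng.uniform(size=(n, n))
            values = (raw + raw.T) / 2
            np.fill_diagonal(values, 1.0)
            net = net_from_sim(values, ids, assoc)
            aucs.append(loocv_auc(assoc, net, RWRConfig()).auc)
        assert 0.45 <= float(np.mean(aucs)) <= 0.55

    @pytest.mark.parametrize("gamma", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_gamma_sensitivity(self, gamma, default_world, default_pipeline):
        """Recovery stays clearly better than chance across the restart sweep."""
        net = self._world_network(default_world, default_pipeline)
        res = loocv_auc(net.assoc, net, RWRConfig(gamma=gamma))
        assert res.auc > 0.5

    def test_trial_bookkeeping(self, default_world, default_pipeline):
        net = self._world_network(default_world, default_pipeline)
        res = loocv_auc(net.assoc, net, RWRConfig())
        eligible = sum(
            len(net.assoc.ncrnas_of(d))
            for d in net.assoc.diseases
            if len(net.assoc.ncrnas_of(d)) >= 2
        )
        assert len(res.trials) == eligible
        for t in res.trials:
            assert 1 <= t.rank <= t.n_candidates
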