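import itertools
import math

import networkx as nx
import numpy as np
import pytest

import mutualcore as mc


def exhaustive_mixed_values(net, ranking, gc_threshold=0.5):
    """Oracle: removal percentage for every tie-respecting removal order."""
    bnet = mc.binarize(net)
    gc0 = mc.components(bnet).gc_size
    n = len(bnet.nodes)
    values = []
    for perm_groups in itertools.product(
            *[itertools.permutations(g) for g in ranking.tie_groups]):
        order = [x for g in perm_groups for x in g]
        g = bnet.to_graph()
        removed = 0
        for node in order:
            g.remove_node(node)
            removed += 1
            gc = max((len(c) for c in nx.connected_components(g)), default=0)
            if gc / gc0 <= gc_threshold:
                break
        values.append(removed / n * 100.0)
    return values


class TestMixedExtinction:
    def test_fig3_krisk_trace_is_deterministic(self, fig3):
        """Ranking has no ties among the first removals: disp1, then disp2
        (GC 6/9 then 4/9 <= 0.5), so every repetition removes 2 of 9."""
        summary = mc.run_mixed_extinction(
            fig3, mc.rank_by(fig3, "krisk"), n_reps=20, seed=123)
        assert summary.mean_value == pytest.approx(2 / 9 * 100, abs=1e-9)
        assert summary.sd == 0.0

    def test_fig3_krisk_trajectory_steps(self, fig3):
        _, trajs = mc.run_mixed_extinction(
            fig3, mc.rank_by(fig3, "krisk"), n_reps=1, seed=0,
            keep_trajectories=True)
        steps = trajs[0].steps
        assert [s.removed_node for s in steps] == [None, "disp1", "disp2"]
        assert [s.gc_fraction for s in steps] == pytest.approx([1.0, 6 / 9, 4 / 9])

    def test_single_edge_network_stops_at_first_removal(self):
        net = mc.build_network(["p1"], ["a1"], [("p1", "a1")])
        summary = mc.run_mixed_extinction(
            net, mc.rank_by(net, "degree"), n_reps=3, seed=0)
        assert summary.mean_value == pytest.approx(50.0)

    def test_fig3_degree_matches_exhaustive_tie_oracle(self, fig3):
        ranking = mc.rank_by(fig3, "degree")
        exact = exhaustive_mixed_values(fig3, ranking)
        mu, sigma = np.mean(exact), np.std(exact)
        summary = mc.run_mixed_extinction(fig3, ranking, n_reps=100, seed=5)
        se = sigma / math.sqrt(100)
        assert abs(summary.mean_value - mu) <= 3 * se + 1e-12

    def test_gc_fraction_monotone_and_counts_only_primary_removals(self, fig3):
        _, trajs = mc.run_mixed_extinction(
            fig3, mc.rank_by(fig3, "degree"), n_reps=10, seed=2,
            keep_trajectories=True)
        for traj in trajs:
            fracs = traj.gc_fractions
            assert fracs[0] == 1.0
            assert all(a >= b for a, b in zip(fracs, fracs[1:]))
            assert traj.steps[-1].removed_count == len(traj.steps) - 1

    def test_threshold_validation(self, fig3):
        with pytest.raises(ValueError, match="gc_threshold"):
            mc.run_mixed_extinction(fig3, mc.rank_by(fig3, "degree"),
                                    gc_threshold=1.5, n_reps=1, seed=0)

    def test_requires_both_guild_ranking(self, fig3):
        r = mc.rank_by(fig3, "kdegree", mc.ANIMALS_ONLY)
        with pytest.raises(ValueError, match="both-guild"):
            mc.run_mixed_extinction(fig3, r, n_reps=1, seed=0)


class TestPrimaryExtinction:
    def test_fig3_kdegree_hand_trace(self, fig3):
        """disp1 isolates pl4+pl5, disp2 isolates pl3, the last bird
        strands pl1+pl2: plant curve (1, .6, .4, .4, 0)."""
        plants_s, gc_s, trajs = mc.run_primary_extinction(
            fig3, mc.rank_by(fig3, "kdegree", mc.ANIMALS_ONLY),
            n_reps=4, seed=7)
        for traj in trajs:
            assert traj.surviving_plant_fractions == pytest.approx(
                (1.0, 0.6, 0.4, 0.4, 0.0))
            assert traj.gc_fractions == pytest.approx(
                (1.0, 6 / 9, 4 / 9, 3 / 9, 0.0))
        assert plants_s.mean_value == pytest.approx(0.475, abs=1e-12)
        assert plants_s.sd == 0.0

    def test_generalist_plant_survives_to_the_end(self):
        # p1 linked to every animal only dies at the final step
        net = mc.build_network(["p1", "p2"], ["a1", "a2", "a3"],
                               [("p1", "a1"), ("p1", "a2"), ("p1", "a3"),
                                ("p2", "a1")])
        _, _, trajs = mc.run_primary_extinction(
            net, mc.rank_by(net, "degree"), n_reps=6, seed=1)
        for traj in trajs:
            assert traj.surviving_plant_fractions[-1] == 0.0
            assert all(f >= 0.5 for f in traj.surviving_plant_fractions[:-1])

    def test_identical_seed_identical_trajectories(self, fig3):
        r = mc.rank_by(fig3, "degree")
        _, _, t1 = mc.run_primary_extinction(fig3, r, n_reps=5, seed=99)
        _, _, t2 = mc.run_primary_extinction(fig3, r, n_reps=5, seed=99)
        assert t1 == t2

    def test_initially_isolated_plants_never_go_extinct(self):
        net = mc.build_network(["p1", "p2", "p3"], ["a1"],
                               [("p1", "a1"), ("p2", "a1")])
        _, _, trajs = mc.run_primary_extinction(
            net, mc.rank_by(net, "degree"), n_reps=1, seed=0)
        # p3 was isolated from the start: final surviving fraction 1/3
        assert trajs[0].surviving_plant_fractions[-1] == pytest.approx(1 / 3)

    def test_prefix_identical_until_first_tie(self, fig3):
        r = mc.rank_by(fig3, "kdegree", mc.ANIMALS_ONLY)
        # order disp1 (2.8), disp2 (2.4), tie {disp3, disp4}
        _, _, ta = mc.run_primary_extinction(fig3, r, n_reps=1, seed=1)
        _, _, tb = mc.run_primary_extinction(fig3, r, n_reps=1, seed=2)
        seq_a = [s.removed_node for s in ta[0].steps]
        seq_b = [s.removed_node for s in tb[0].steps]
        assert seq_a[:3] == seq_b[:3] == [None, "disp1", "disp2"]
        assert set(seq_a[3:]) == set(seq_b[3:]) == {"disp3", "disp4"}

    def test_no_animals_rejected(self):
        net = mc.build_network(["p1"], [], [])
        with pytest.raises(ValueError, match="no animal"):
            mc.run_primary_extinction(
                net, mc.Ranking("degree", {}, (), (), mc.BOTH_GUILDS),
                n_reps=1, seed=0)


class TestAuc:
    @pytest.mark.parametrize("xs,ys,expected", [
        ((0, 1), (1, 1), 1.0),
        ((0, 1), (1, 0), 0.5),
        ((0, 0.25, 0.5, 0.75, 1), (1, 0.6, 0.4, 0.4, 0), 0.475),
    ])
    def test_known_areas(self, xs, ys, expected):
        assert mc.auc(xs, ys) == pytest.approx(expected, abs=1e-12)

    def test_collinear_point_insertion_invariance(self):
        base = mc.auc((0, 1), (1, 0))
        refined = mc.auc((0, 0.3, 0.7, 1), (1, 0.7, 0.3, 0))
        assert refined == pytest.approx(base, abs=1e-12)

    def test_non_increasing_xs_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            mc.auc((0, 0.5, 0.5, 1), (1, 0.5, 0.4, 0))

    def test_must_anchor_at_intact_network(self):
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            mc.auc((0.25, 1), (0.8, 0))


class TestCompareRankings:
    def test_fig3_krisk_beats_degree_in_mixed(self, fig3):
        table = mc.compare_rankings(fig3, ["krisk", "degree"],
                                    procedure=mc.PROCEDURE_MIXED,
                                    n_reps=50, seed=3)
        assert set(table["index"]) == {"krisk", "degree"}
        winner = table.loc[table["winner"], "index"].tolist()
        assert winner == ["krisk"]

    def test_single_index_wins_trivially(self, fig3):
        table = mc.compare_rankings(fig3, ["degree"], n_reps=5, seed=0)
        assert table["winner"].all()

    def test_musrank_rejected_for_mixed(self, fig3):
        with pytest.raises(ValueError, match="musrank"):
            mc.compare_rankings(fig3, ["krisk", "musrank"],
                                procedure=mc.PROCEDURE_MIXED, n_reps=1, seed=0)

    def test_primary_procedure_yields_both_metrics(self, fig3):
        table = mc.compare_rankings(fig3, ["kdegree", "musrank"],
                                    procedure=mc.PROCEDURE_PRIMARY,
                                    n_reps=10, seed=4)
        assert set(table["metric"]) == {"auc_plants", "auc_gc"}
        assert len(table) == 4

    def test_order_independent_results(self, fig3):
        a = mc.compare_rankings(fig3, ["krisk", "degree"], n_reps=20, seed=8)
        b = mc.compare_rankings(fig3, ["degree", "krisk"], n_reps=20, seed=8)
        a = a.set_index("index").sort_index()
        b = b.set_index("index").sort_index()
        assert (a["mean"] == b["mean"]).all()


class TestTieShuffleStatistics:
    def test_mean_within_three_se_of_exact_permutation_mean(self):
        """100 shuffled repetitions agree with the exhaustive tie oracle
        on a network with a 4-way top tie."""
        net = mc.build_network(
            ["p1", "p2", "p3", "p4"], ["a1", "a2", "a3", "a4"],
            [("p1", "a1"), ("p1", "a2"), ("p2", "a1"), ("p2", "a2"),
             ("p3", "a3"), ("p3", "a4"), ("p4", "a3"), ("p4", "a4"),
             ("p1", "a3")])
        ranking = mc.rank_by(net, "degree")
        assert max(len(g) for g in ranking.tie_groups) <= 6
        exact = exhaustive_mixed_values(net, ranking)
        mu, sigma = np.mean(exact), np.std(exact)
        summary = mc.run_mixed_extinction(net, ranking, n_reps=100, seed=17)
        assert abs(summary.mean_value - mu) <= 3 * sigma / 10 + 1e-12
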