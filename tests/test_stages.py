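"""Hub tracking, temporal classification, expression annotation, hourglass."""
import itertools

import networkx as nx
import numpy as np
import pytest

from tfclust import examples
from tfclust.mcl import ClusterSet
from tfclust.preprocess import DEFAULT_STAGES, ExpressionMatrix
from tfclust.stages import (
    StagePresenceTable,
    annotate_expression,
    classify_temporal,
    count_all_stage_pairs,
    count_union_pairs,
    filter_reportable_clusters,
    find_hub,
    hourglass_profile,
    track_hub_across_stages,
)

STAGES = [s.name for s in DEFAULT_STAGES]


def weighted_graph(edges):
    net = nx.Graph()
    for u, v, w in edges:
        net.add_edge(u, v, weight=float(w))
    return net


class TestFindHub:
    def test_star_center(self):
        net = weighted_graph([("c", "x", 1), ("c", "y", 1), ("c", "z", 1)])
        assert find_hub(net.nodes, net) == "c"

    def test_two_node_tie_breaks_lexicographically(self):
        net = weighted_graph([("b", "a", 2)])
        assert find_hub(["a", "b"], net) == "a"

    def test_weighted_degree_selects_center(self):
        # within-cluster weighted degrees: a=7, b=5, c=5, d=3
        net = weighted_graph([("a", "b", 3), ("a", "c", 2), ("a", "d", 2),
                              ("b", "c", 2), ("c", "d", 1)])
        assert find_hub(net.nodes, net) == "a"

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            find_hub([], nx.Graph())


class TestReportableClusters:
    def test_edge_count_rule(self):
        net = weighted_graph([
            ("a", "b", 1), ("b", "c", 1), ("a", "c", 1),   # triangle: 3 edges
            ("p", "q", 1),                                  # single edge
            ("s", "t", 1), ("s", "u", 1), ("s", "v", 1),    # 4-node star
        ])
        net.add_node("lone")
        cs = ClusterSet(stage="x", clusters=[
            ["a", "b", "c"], ["p", "q"], ["s", "t", "u", "v"], ["lone"],
        ])
        kept = filter_reportable_clusters(cs, net)
        assert sorted(kept.clusters) == [["a", "b", "c"], ["s", "t", "u", "v"]]


class TestTrackHub:
    def test_single_stage_hub_with_two_partners(self):
        net = weighted_graph([("h", "p1", 2), ("h", "p2", 2), ("p1", "p2", 1)])
        clusters = {STAGES[0]: ClusterSet(STAGES[0], [["h", "p1", "p2"]])}
        nets = {STAGES[0]: net}
        table = track_hub_across_stages(clusters, nets, "h")
        assert set(table.rows) == {"p1", "p2"}
        assert table.rows["p1"] == (True, False, False, False, False)

    def test_partner_union_spans_stages(self):
        net1 = weighted_graph([("h", "p1", 2), ("h", "p2", 2)])
        net2 = weighted_graph([("h", "p1", 2), ("h", "p3", 2)])
        clusters = {
            STAGES[0]: ClusterSet(STAGES[0], [["h", "p1", "p2"]]),
            STAGES[1]: ClusterSet(STAGES[1], [["h", "p1", "p3"]]),
        }
        nets = {STAGES[0]: net1, STAGES[1]: net2}
        table = track_hub_across_stages(clusters, nets, "h")
        assert set(table.rows) == {"p1", "p2", "p3"}
        assert table.rows["p1"] == (True, True, False, False, False)
        assert table.rows["p3"] == (False, True, False, False, False)

    def test_partner_outside_hub_cluster_not_counted(self):
        # h-p2 edge exists but p2 sits in another cluster
        net = weighted_graph([("h", "p1", 3), ("h", "p2", 1), ("p2", "q", 3),
                              ("h", "p3", 3)])
        clusters = {STAGES[0]: ClusterSet(STAGES[0], [["h", "p1", "p3"],
                                                      ["p2", "q"]])}
        table = track_hub_across_stages(clusters, {STAGES[0]: net}, "h")
        assert set(table.rows) == {"p1", "p3"}

    def test_never_clustered_hub_rejected(self):
        with pytest.raises(ValueError):
            track_hub_across_stages({}, {}, "ghost")

    def test_recovers_reference_presence_rows(self):
        """Per-stage hub-adjacent edge lists encoding the published NFAT
        cluster reproduce its printed presence rows."""
        hub, rows = examples.CLUSTER_TABLES["NFAT"]
        clusters, nets = {}, {}
        for i, stage in enumerate(STAGES):
            partners = [p for p, vec in rows.items() if vec[i]]
            net = weighted_graph([(hub, p, 2) for p in partners])
            clusters[stage] = ClusterSet(stage, [[hub] + partners])
            nets[stage] = net
        table = track_hub_across_stages(clusters, nets, hub,
                                        stage_names=STAGES)
        assert table.rows == rows

    def test_matches_generator_hub_membership(self, small_fixture):
        from tfclust.pipeline import run_pipeline_on_fixture

        fx = small_fixture
        res = run_pipeline_on_fixture(fx)
        truth = fx.ground_truth
        for hub, table in res.hub_tables.items():
            for i, stage in enumerate(STAGES):
                expected = set(truth.hub_members[stage].get(hub, []))
                if len(expected) < 3:
                    # a hub star with < 3 partners has < 3 within-cluster
                    # interactions and is filtered from the presence tables
                    expected = set()
                got = {p for p, vec in table.rows.items() if vec[i]}
                assert got == expected


def brute_force_category(vec):
    if all(vec):
        return "all_stages"
    if sum(vec) == 1:
        return "stage_specific"
    for i, j, k in itertools.combinations(range(len(vec)), 3):
        if vec[i] and not vec[j] and vec[k]:
            return "interrupted"
    return "other"


class TestTemporalClassification:
    @pytest.mark.parametrize(
        "vec, expected",
        [
            ((True,) * 5, "all_stages"),
            ((True, True, False, True, True), "interrupted"),
            ((True, False, False, False, False), "stage_specific"),
            ((True, True, False, False, False), "other"),
        ],
    )
    def test_category_examples(self, vec, expected):
        assert classify_temporal(vec) == expected

    def test_exhaustive_against_brute_force(self):
        for bits in itertools.product([False, True], repeat=5):
            if not any(bits):
                continue
            assert classify_temporal(bits) == brute_force_category(bits)

    def test_reference_rows_classify_as_printed(self):
        # every all-true row -> all_stages, every one-true row ->
        # stage_specific, every broken (true-false-true) row -> interrupted;
        # the contiguous-block rows fall into the residual category
        for name, (_, rows) in examples.CLUSTER_TABLES.items():
            for partner, vec in rows.items():
                assert classify_temporal(vec) == brute_force_category(vec), (
                    name, partner,
                )

    def test_all_false_rejected(self):
        with pytest.raises(ValueError):
            classify_temporal((False,) * 5)


class TestPairCounts:
    @pytest.mark.parametrize("name, union, all_stage", [
        ("NFAT", 6, 3),
        ("SMAD", 3, 1),
        ("HMGIY", 5, 2),
        ("AP1", 3, 0),
    ])
    def test_reference_tables(self, name, union, all_stage):
        table = examples.presence_table(name)
        assert count_union_pairs(table) == union
        assert count_all_stage_pairs(table) == all_stage

    def test_all_stage_bounded_by_union(self):
        for name in examples.CLUSTER_TABLES:
            table = examples.presence_table(name)
            assert count_all_stage_pairs(table) <= count_union_pairs(table)


def expression_of(profiles, days=(0, 3, 8, 13, 29, 60)):
    genes = list(profiles)
    values = np.array([profiles[g] for g in genes], dtype=float)
    return ExpressionMatrix.from_arrays(genes, days, values)


class TestExpressionAnnotation:
    MAPPING = {"A": ["gA"], "B": ["gB", "gB2"]}

    def test_both_sides_high_everywhere_is_synergistic(self):
        expr = expression_of({"gA": [30] * 6, "gB": [30] * 6, "gB2": [1] * 6})
        ann = annotate_expression(("A", "B"), (True,) * 5, self.MAPPING, expr)
        assert ann.mode == "synergistic_candidate"
        assert ann.expressed_a == frozenset({0, 3, 8, 13, 29, 60})

    def test_early_late_split_is_antagonistic(self):
        expr = expression_of({
            "gA": [30, 30, 1, 1, 1, 1],
            "gB": [1, 1, 1, 1, 30, 30],
            "gB2": [1] * 6,
        })
        presence = (True, False, False, False, True)
        ann = annotate_expression(("A", "B"), presence, self.MAPPING, expr)
        assert ann.mode == "antagonistic_candidate"

    def test_mixed_overlap_is_indeterminate(self):
        expr = expression_of({
            "gA": [30, 30, 30, 1, 1, 1],
            "gB": [30, 30, 1, 1, 1, 1],
            "gB2": [1] * 6,
        })
        # present in stages 1 and 3: overlap in stage 1 but not stage 3
        presence = (True, False, True, False, False)
        ann = annotate_expression(("A", "B"), presence, self.MAPPING, expr)
        assert ann.mode == "indeterminate"

    def test_threshold_boundary_is_inclusive(self):
        expr = expression_of({"gA": [10] * 6, "gB": [30] * 6, "gB2": [1] * 6})
        ann = annotate_expression(("A", "B"), (True,) * 5, self.MAPPING, expr)
        assert 0 in ann.expressed_a

    def test_mapping_uses_max_over_genes(self):
        expr = expression_of({"gA": [30] * 6, "gB": [1] * 6, "gB2": [40] * 6})
        ann = annotate_expression(("A", "B"), (True,) * 5, self.MAPPING, expr)
        assert ann.expressed_b == frozenset({0, 3, 8, 13, 29, 60})

    def test_unmapped_side_rejected(self):
        expr = expression_of({"gA": [30] * 6})
        with pytest.raises(ValueError, match="B"):
            annotate_expression(("A", "B"), (True,) * 5, {"A": ["gA"]}, expr)

    def test_raising_threshold_shrinks_expressed_sets(self):
        rng = np.random.default_rng(9)
        expr = expression_of({
            "gA": rng.uniform(0, 40, 6), "gB": rng.uniform(0, 40, 6),
            "gB2": rng.uniform(0, 40, 6),
        })
        prev_a = prev_b = None
        was_synergistic = False
        for t in (5.0, 10.0, 20.0, 35.0):
            try:
                ann = annotate_expression(("A", "B"), (True,) * 5,
                                          self.MAPPING, expr, threshold=t)
            except ValueError:
                break
            if prev_a is not None:
                assert ann.expressed_a <= prev_a
                assert ann.expressed_b <= prev_b
                # a pair cannot become synergistic as the threshold rises
                if ann.mode == "synergistic_candidate":
                    assert was_synergistic
            prev_a, prev_b = ann.expressed_a, ann.expressed_b
            was_synergistic = ann.mode == "synergistic_candidate"

    def test_fixture_designed_pairs(self, small_fixture):
        fx = small_fixture
        truth = fx.ground_truth
        syn_a, syn_b = truth.synergistic_pair.split("~")
        ann = annotate_expression(
            (syn_a, syn_b),
            tuple(truth.pair_patterns[truth.synergistic_pair]),
            fx.tf_mapping, fx.expression,
        )
        assert ann.mode == "synergistic_candidate"
        ant_a, ant_b = truth.antagonistic_pair.split("~")
        ann = annotate_expression(
            (ant_a, ant_b),
            tuple(truth.pair_patterns[truth.antagonistic_pair]),
            fx.tf_mapping, fx.expression,
        )
        assert ann.mode == "antagonistic_candidate"


class TestHourglass:
    def test_reference_pair_counts_dip_at_late_specification(self):
        argmin, interior = hourglass_profile(examples.PAIR_COUNTS_PER_STAGE)
        assert (argmin, interior) == (3, True)

    def test_reference_deg_counts_dip_at_late_specification(self):
        argmin, interior = hourglass_profile(examples.DEG_COUNTS_PER_STAGE)
        assert (argmin, interior) == (3, True)

    def test_monotone_counts_have_edge_minimum(self):
        assert hourglass_profile([1, 2, 3, 4, 5]) == (1, False)

    def test_first_minimum_wins_ties(self):
        assert hourglass_profile([5, 2, 2, 5, 5])[0] == 2

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            hourglass_profile([1, 2, 3])


class TestPresenceTableInvariants:
    def test_hub_among_partners_rejected(self):
        with pytest.raises(ValueError):
            StagePresenceTable(hub="h", rows={"h": (True,) * 5})

    def test_all_false_row_rejected(self):
        with pytest.raises(ValueError):
            StagePresenceTable(hub="h", rows={"p": (False,) * 5})

    def test_tsv_rendering_uses_plus_minus(self, tmp_path):
        table = examples.presence_table("SMAD")
        out = tmp_path / "presence.tsv"
        table.to_tsv(out)
        text = out.read_text()
        assert "V$SMAD_Q6_01 - V$FOX_Q2\t+\t+\t+\t+\t+" in text
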