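"""Regulator-module network construction, ranking and novelty flags."""

import pytest

from comethnet import (
    RegulatorMap,
    annotate_novelty,
    build_regnet,
    rank_regulators,
)
from comethnet.treecut import ModuleAssignment


def assignment_from_colors(color_of: dict[str, str]) -> ModuleAssignment:
    order = {c: i for i, c in enumerate(sorted(set(color_of.values()) - {"grey"}), start=1)}
    index = {g: (0 if c == "grey" else order[c]) for g, c in color_of.items()}
    return ModuleAssignment(genes=list(color_of), module_index=index, module_color=dict(color_of))


def empty(cls):
    return RegulatorMap(regulator_class=cls)


class TestBuildRegnet:
    def test_grey_and_absent_targets_excluded(self):
        asg = assignment_from_colors({"G1": "turquoise", "G2": "grey"})
        tf = RegulatorMap(regulator_class="TF",
                          edges={("TFX", "G2"), ("TFX", "ghost"), ("TFY", "G1")})
        net = build_regnet(asg, tf, empty("miRNA"))
        assert net.regulators("TF") == ["TFY"]
        assert net.n_unmatched["TF"] == 2

    def test_whsc1_module_breakdown(self):
        """Multi-module TF: 4 blue + 2 brown + 3 turquoise targets = 9 genes
        over 3 modules."""
        colors = {}
        for g in ("KIFC1b", "KIFC1a", "MSI2", "KIFC1"):
            colors[g] = "blue"
        for g in ("UHRF1", "MYH11"):
            colors[g] = "brown"
        for g in ("GTF2H4", "TFDP1", "UHRF1a"):
            colors[g] = "turquoise"
        asg = assignment_from_colors(colors)
        tf = RegulatorMap(regulator_class="TF", edges={("WHSC1", g) for g in colors})
        net = build_regnet(asg, tf, empty("miRNA"))
        summary = net.summaries[("TF", "WHSC1")]
        assert {c: len(v) for c, v in summary.items()} == {"blue": 4, "brown": 2, "turquoise": 3}
        row = rank_regulators(net, "TF", 10).rows[0]
        assert (row.n_modules, row.n_genes) == (3, 9)

    def test_edges_match_exhaustive_enumeration(self):
        colors = {f"g{i}": c for i, c in enumerate(["blue", "blue", "brown", "turquoise", "grey"])}
        asg = assignment_from_colors(colors)
        edges = {("A", "g0"), ("A", "g2"), ("A", "g4"), ("B", "g1"), ("B", "g3")}
        tf = RegulatorMap(regulator_class="TF", edges=edges)
        net = build_regnet(asg, tf, empty("miRNA"))
        expected = {(r, g) for r, g in edges if colors.get(g, "grey") != "grey"}
        assert {(r, g) for _, r, g, _ in net.edges} == expected


class TestRankRegulators:
    def build(self, spec):
        """spec: regulator -> {color: n_targets}; builds a one-class net."""
        colors, edges = {}, set()
        for reg, breakdown in spec.items():
            for color, count in breakdown.items():
                for i in range(count):
                    g = f"{color}_{i}"
                    colors[g] = color
                    edges.add((reg, g))
        asg = assignment_from_colors(colors)
        tf = RegulatorMap(regulator_class="TF", edges=edges)
        return build_regnet(asg, tf, empty("miRNA"))

    def test_gene_count_breaks_module_ties(self):
        # equal module counts: the 11-gene regulator outranks the 10-gene one
        net = self.build({
            "BAZ2B": {"blue": 9, "turquoise": 2},
            "E2F4": {"blue": 2, "turquoise": 8},
        })
        rows = rank_regulators(net, "TF", 10).rows
        assert [r.regulator_id for r in rows] == ["BAZ2B", "E2F4"]
        assert rows[0].rank == 1 and rows[1].rank == 2

    def test_module_count_dominates_gene_count(self):
        net = self.build({"MANY": {"blue": 1, "brown": 1, "turquoise": 1}, "BIG": {"blue": 50}})
        rows = rank_regulators(net, "TF", 10).rows
        assert rows[0].regulator_id == "MANY"

    def test_alphabetical_final_tie_break(self):
        net = self.build({"ZZZ": {"blue": 2}, "AAA": {"blue": 2}})
        assert [r.regulator_id for r in rank_regulators(net, "TF", 10).rows] == ["AAA", "ZZZ"]

    def test_singleton_network_rank_one(self):
        net = self.build({"ONLY": {"blue": 1}})
        rows = rank_regulators(net, "TF", 10).rows
        assert len(rows) == 1 and rows[0].rank == 1

    def test_truncation_and_full_table(self):
        net = self.build({f"TF{i}": {"blue": i + 1} for i in range(5)})
        ranking = rank_regulators(net, "TF", 2)
        assert len(ranking.rows) == 2
        assert len(ranking.all_rows) == 5
        assert [r.rank for r in ranking.all_rows] == [1, 2, 3, 4, 5]

    def test_counts_consistent(self):
        net = self.build({"A": {"blue": 3, "brown": 2}})
        row = rank_regulators(net, "TF", 10).rows[0]
        assert row.n_genes == sum(row.breakdown.values()) == 5
        assert row.n_modules == len(row.breakdown) == 2

    def test_empty_network_warns(self, caplog):
        asg = assignment_from_colors({"G1": "grey"})
        net = build_regnet(asg, empty("TF"), empty("miRNA"))
        with caplog.at_level("WARNING", logger="comethnet"):
            ranking = rank_regulators(net, "TF", 10)
        assert ranking.rows == []

    def test_removing_module_never_increases_counts(self):
        spec = {"A": {"blue": 3, "brown": 2, "turquoise": 4}, "B": {"brown": 5}}
        full = {r.regulator_id: (r.n_modules, r.n_genes)
                for r in rank_regulators(self.build(spec), "TF", 10).rows}
        reduced_spec = {r: {c: n for c, n in b.items() if c != "brown"} for r, b in spec.items()}
        reduced_spec = {r: b for r, b in reduced_spec.items() if b}
        reduced = {r.regulator_id: (r.n_modules, r.n_genes)
                   for r in rank_regulators(self.build(reduced_spec), "TF", 10).rows}
        for reg, (nm, ng) in reduced.items():
            assert nm <= full[reg][0] and ng <= full[reg][1]


class TestNovelty:
    def ranking(self):
        asg = assignment_from_colors({"G1": "blue", "G2": "blue"})
        tf = RegulatorMap(regulator_class="TF",
                          edges={("WHSC1", "G1"), ("MYST3", "G2"), ("ZNF771", "G1")})
        return rank_regulators(build_regnet(asg, tf, empty("miRNA")), "TF", 10)

    def test_empty_known_list_all_unknown(self):
        out = annotate_novelty(self.ranking(), set())
        assert {r.status for r in out.rows} == {"Unknown"}

    def test_known_list_flags_rest_unknown(self):
        out = annotate_novelty(self.ranking(), {"WHSC1"})
        status = {r.regulator_id: r.status for r in out.rows}
        assert status == {"WHSC1": "Known", "MYST3": "Unknown", "ZNF771": "Unknown"}

    def test_case_insensitive_match(self):
        out = annotate_novelty(self.ranking(), {"whsc1"})
        assert {r.regulator_id: r.status for r in out.rows}["WHSC1"] == "Known"

    def test_ranking_order_is_stable(self):
        a = [(r.rank, r.regulator_id) for r in self.ranking().rows]
        b = [(r.rank, r.regulator_id) for r in self.ranking().rows]
        assert a == b
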