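"""Published per-regulator module breakdowns used as worked examples.

Each entry maps a regulator to its per-module target counts as printed in
the source study's ranking tables.  Where the study names the target genes
they are used verbatim; where only counts are printed, synthetic
placeholder gene ids are generated (the ranking statistic depends only on
the counts).
"""

from comethnet import RegulatorMap, build_regnet
from comethnet.treecut import ModuleAssignment

# human intra-species: WHSC1 regulates 9 genes over 3 modules
WHSC1_TARGETS = {
    "blue": ["KIFC1b", "KIFC1a", "MSI2", "KIFC1"],
    "brown": ["UHRF1", "MYH11"],
    "turquoise": ["GTF2H4", "TFDP1", "UHRF1a"],
}

# human intra-species: hsa-miR-579 targets 17 genes over 4 modules
MIR579_COUNTS = {"blue": 2, "brown": 2, "green": 1, "turquoise": 12}

# rhesus intra-species TFs (top two rows of the ranking table)
BAZ2B_COUNTS = {"blue": 9, "turquoise": 2}
E2F4_RHESUS_COUNTS = {"blue": 2, "turquoise": 8}

# rhesus intra-species: mml-miR-338-5p targets 33 genes over 2 modules
MIR338_COUNTS = {"blue": 6, "turquoise": 27}

# inter-species TFs
ZNF286A_COUNTS = {
    "black": 1, "blue": 2, "brown": 3, "cyan": 1, "green": 6,
    "magenta": 1, "purple": 1, "red": 2, "turquoise": 7, "yellow": 7,
}
E2F4_INTER_COUNTS = {
    "black": 3, "blue": 14, "brown": 13, "green": 4, "magenta": 1,
    "midnightblue": 1, "pink": 2, "turquoise": 15, "yellow": 8,
}


def expand_counts(regulator: str, counts: dict[str, int]) -> dict[str, list[str]]:
    """Synthetic placeholder targets for a counts-only table row."""
    return {
        color: [f"{regulator}.{color}.{i + 1}" for i in range(n)]
        for color, n in counts.items()
    }


def network_from_breakdowns(breakdowns: dict[str, dict[str, list[str]]], regulator_class: str):
    """Build a module assignment plus regulator map reproducing the printed
    breakdowns, and intersect them into a regulator-module network."""
    color_of: dict[str, str] = {}
    edges: set[tuple[str, str]] = set()
    for reg, by_color in breakdowns.items():
        for color, genes in by_color.items():
            for g in genes:
                color_of[g] = color
                edges.add((reg, g))
    order = {c: i for i, c in enumerate(sorted(set(color_of.values())), start=1)}
    assignment = ModuleAssignment(
        genes=list(color_of),
        module_index={g: order[c] for g, c in color_of.items()},
        module_color=dict(color_of),
    )
    rmap = RegulatorMap(regulator_class=regulator_class, edges=edges)
    empty_cls = "miRNA" if regulator_class == "TF" else "TF"
    empty = RegulatorMap(regulator_class=empty_cls)
    if regulator_class == "TF":
        return build_regnet(assignment, rmap, empty)
    return build_regnet(assignment, empty, rmap)
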