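"""TF-miRNA-gene-module network and regulator ranking.

Regulator -> gene edges are restricted to genes assigned to a non-grey
module.  Regulators are then ranked by how many distinct modules their
targets span, ties broken by the total number of regulated genes inside
modules (descending), and finally alphabetically by regulator id.  A gene
belongs to exactly one module, so the per-module counts of a regulator sum
to its gene total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from .datatypes import RegulatorMap
from .treecut import GREY, ModuleAssignment

logger = logging.getLogger("comethnet")

__all__ = [
    "RegModuleNetwork",
    "RegulatorRanking",
    "RankRow",
    "build_regnet",
    "rank_regulators",
    "annotate_novelty",
]


@dataclass
class RegModuleNetwork:
    """Bipartite regulator/gene/module structure.

    ``summaries`` maps ``(regulator_class, regulator_id)`` to a
    ``module_color -> sorted target genes`` breakdown; ``edges`` holds the
    retained ``(regulator_class, regulator_id, gene, module_color)``
    tuples.  ``n_unmatched`` counts dropped edges whose target was grey or
    absent from the assignment, per class.
    """

    summaries: dict[tuple[str, str], dict[str, list[str]]]
    edges: list[tuple[str, str, str, str]]
    n_unmatched: dict[str, int] = field(default_factory=dict)

    def regulators(self, regulator_class: str) -> list[str]:
        return sorted(r for cls, r in self.summaries if cls == regulator_class)


@dataclass
class RankRow:
    rank: int
    regulator_id: str
    regulator_class: str
    n_modules: int
    n_genes: int
    breakdown: dict[str, int]
    status: str = "Unknown"


@dataclass
class RegulatorRanking:
    """Ranked regulator table; ``rows`` is the top-k slice, ``all_rows``
    the full untruncated ordering."""

    regulator_class: str
    rows: list[RankRow]
    all_rows: list[RankRow]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tregulator\tclass\tn_modules\tn_genes\tbreakdown\tstatus\n")
            for row in self.rows:
                breakdown = ";".join(f"{color}:{count}" for color, count in sorted(row.breakdown.items()))
                fh.write(
                    f"{row.rank}\t{row.regulator_id}\t{row.regulator_class}\t"
                    f"{row.n_modules}\t{row.n_genes}\t{breakdown}\t{row.status}\n"
                )


def build_regnet(
    assignment: ModuleAssignment,
    tf_map: RegulatorMap,
    mir_map: RegulatorMap,
) -> RegModuleNetwork:
    """Intersect regulator maps with the module assignment.

    Only edges whose target gene sits in a non-grey module are kept;
    duplicate edges were already removed at map construction.  Regulators
    left with no in-module target are excluded from the network.
    """
    if not assignment.genes:
        raise ValueError("module assignment is empty")
    if not assignment.module_color:
        raise ValueError("assignment has no colors; run assign_colors first")
    color_of = {
        g: c for g, c in assignment.module_color.items() if c != GREY
    }
    summaries: dict[tuple[str, str], dict[str, set[str]]] = {}
    edges: list[tuple[str, str, str, str]] = []
    n_unmatched: dict[str, int] = {}
    for rmap in (tf_map, mir_map):
        cls = rmap.regulator_class
        dropped = 0
        for reg, target in sorted(rmap.edges):
            color = color_of.get(target)
            if color is None:
                dropped += 1
                continue
            summaries.setdefault((cls, reg), {}).setdefault(color, set()).add(target)
            edges.append((cls, reg, target, color))
        n_unmatched[cls] = dropped
        if dropped:
            logger.info("%s map: %d edges dropped (grey or unknown targets)", cls, dropped)
    frozen = {
        key: {color: sorted(genes) for color, genes in by_color.items()}
        for key, by_color in summaries.items()
    }
    return RegModuleNetwork(summaries=frozen, edges=edges, n_unmatched=n_unmatched)


def rank_regulators(net: RegModuleNetwork, regulator_class: str, k: int) -> RegulatorRanking:
    """Rank regulators of one class by (n_modules desc, n_genes desc, id asc).

    ``rows`` holds the first ``k`` rows; the full ordering stays available
    as ``all_rows``.  An empty network yields an empty ranking with a
    warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    entries = []
    for (cls, reg), by_color in net.summaries.items():
        if cls != regulator_class:
            continue
        breakdown = {color: len(genes) for color, genes in by_color.items()}
        entries.append((reg, breakdown))
    if not entries:
        logger.warning("no %s regulators connected to any module", regulator_class)
        return RegulatorRanking(regulator_class=regulator_class, rows=[], all_rows=[])
    entries.sort(key=lambda e: (-len(e[1]), -sum(e[1].values()), e[0]))
    all_rows = [
        RankRow(
            rank=i,
            regulator_id=reg,
            regulator_class=regulator_class,
            n_modules=len(breakdown),
            n_genes=sum(breakdown.values()),
            breakdown=breakdown,
        )
        for i, (reg, breakdown) in enumerate(entries, start=1)
    ]
    return RegulatorRanking(regulator_class=regulator_class, rows=all_rows[:k], all_rows=all_rows)


def annotate_novelty(ranking: RegulatorRanking, known_list: set[str]) -> RegulatorRanking:
    """Set status to ``Known`` iff the regulator id appears in
    ``known_list`` (case-insensitive), else ``Unknown``."""
    known = {r.lower() for r in known_list}

    def tag(row: RankRow) -> RankRow:
        status = "Known" if row.regulator_id.lower() in known else "Unknown"
        return replace(row, status=status, breakdown=dict(row.breakdown))

    all_rows = [tag(r) for r in ranking.all_rows]
    k = len(ranking.rows)
    return RegulatorRanking(
        regulator_class=ranking.regulator_class,
        rows=all_rows[:k],
        all_rows=all_rows,
    )
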