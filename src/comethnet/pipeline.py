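"""End-to-end driver: fold change -> selection -> adjacency -> TOM ->
dissimilarity -> UPGMA -> tree cut -> colors -> regulator network ->
ranking -> novelty -> export.

Intra-species mode contrasts the experimental cytosine group (5hmC)
against the control group (5mC) of one matrix.  Inter-species mode first
intersects the two species' gene universes (exact identifier match, no
orthology mapping), then contrasts all samples of species 2 against all
samples of species 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from .cluster import Dendrogram, average_linkage_tree
from .config import PipelineConfig
from .datatypes import MethylationMatrix, RegulatorMap
from .diffmeth import FoldChangeTable, compute_fold_change, select_differential
from .network import correlation_adjacency, tom_dissimilarity, tom_similarity
from .regnet import RegModuleNetwork, RegulatorRanking, annotate_novelty, build_regnet, rank_regulators
from .treecut import GREY, ModuleAssignment, assign_colors, dynamic_tree_cut

logger = logging.getLogger("comethnet")

__all__ = ["PipelineInputs", "PipelineResult", "run_pipeline", "run_pipeline_from_paths", "export_results"]


@dataclass
class PipelineInputs:
    """File inputs of a pipeline run; ``matrix2``/``groups2`` only for
    inter-species mode, regulator maps and known lists optional."""

    matrix: str | Path
    groups: str | Path
    matrix2: str | Path | None = None
    groups2: str | Path | None = None
    tf_map: str | Path | None = None
    mir_map: str | Path | None = None
    known_tfs: str | Path | None = None
    known_mirnas: str | Path | None = None
    species: str = "species1"
    species2: str = "species2"


@dataclass
class PipelineResult:
    config: PipelineConfig
    matrix: MethylationMatrix
    fold_changes: FoldChangeTable
    selected: list[str]
    tree: Dendrogram
    assignment: ModuleAssignment
    network: RegModuleNetwork
    tf_ranking: RegulatorRanking
    mir_ranking: RegulatorRanking


def _combine_species(
    m1: MethylationMatrix, m2: MethylationMatrix, tag1: str, tag2: str
) -> MethylationMatrix:
    """Intersect gene universes and pool all samples of both species,
    grouping samples by species tag (species 1 = control)."""
    common = [g for g in m1.gene_ids if g in set(m2.gene_ids)]
    if not common:
        raise ValueError("no common genes between the two species matrices")
    logger.info("inter-species: %d common genes", len(common))
    d1 = m1.data.loc[common].add_prefix(f"{tag1}.", axis=1)
    d2 = m2.data.loc[common].add_prefix(f"{tag2}.", axis=1)
    data = pd.concat([d1, d2], axis=1)
    groups = {c: tag1 for c in d1.columns}
    groups.update({c: tag2 for c in d2.columns})
    return MethylationMatrix(data=data, sample_groups=groups, species=f"{tag1}+{tag2}")


def run_pipeline(
    config: PipelineConfig,
    matrix: MethylationMatrix,
    tf_map: RegulatorMap | None = None,
    mir_map: RegulatorMap | None = None,
    matrix2: MethylationMatrix | None = None,
    known_tfs: set[str] | None = None,
    known_mirnas: set[str] | None = None,
) -> PipelineResult:
    """Run the full module-detection and regulator-ranking pipeline on
    in-memory inputs.  Deterministic given the config (no randomness is
    consumed after data loading)."""
    config.validate()
    if config.mode == "inter":
        if matrix2 is None:
            raise ValueError("inter-species mode needs two matrices")
        tag1 = matrix.species or "species1"
        tag2 = matrix2.species or "species2"
        if tag1 == tag2:
            tag1, tag2 = f"{tag1}_1", f"{tag2}_2"
        matrix = _combine_species(matrix, matrix2, tag1, tag2)
        control, experimental = tag1, tag2
    else:
        control, experimental = config.control_group, config.experimental_group

    for group in (control, experimental):
        cols = [s for s, g in matrix.sample_groups.items() if g == group]
        if len(cols) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 samples")

    fct = compute_fold_change(matrix, control, experimental)
    selected = select_differential(fct, config.fc_threshold, config.fc_criterion)
    if len(selected) < 2:
        raise ValueError(f"only {len(selected)} genes survive fold-change selection; need >= 2")
    logger.info("selected %d / %d genes (criterion %s, threshold %g)",
                len(selected), matrix.n_genes, config.fc_criterion, config.fc_threshold)

    adjacency = correlation_adjacency(
        matrix, selected, transform=config.correlation_transform, power=config.soft_power
    )
    dissim = tom_dissimilarity(tom_similarity(adjacency))
    tree = average_linkage_tree(dissim)
    assignment = assign_colors(
        dynamic_tree_cut(
            tree,
            dissim,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            deep_split=config.deep_split,
        )
    )

    tf_map = tf_map or RegulatorMap(regulator_class="TF")
    mir_map = mir_map or RegulatorMap(regulator_class="miRNA")
    network = build_regnet(assignment, tf_map, mir_map)
    tf_ranking = annotate_novelty(rank_regulators(network, "TF", config.top_k), known_tfs or set())
    mir_ranking = annotate_novelty(rank_regulators(network, "miRNA", config.top_k), known_mirnas or set())

    return PipelineResult(
        config=config,
        matrix=matrix,
        fold_changes=fct,
        selected=selected,
        tree=tree,
        assignment=assignment,
        network=network,
        tf_ranking=tf_ranking,
        mir_ranking=mir_ranking,
    )


def run_pipeline_from_paths(config: PipelineConfig, inputs: PipelineInputs) -> PipelineResult:
    """Load inputs from disk and run the pipeline."""
    groups = cio.read_sample_groups(inputs.groups)
    matrix = cio.read_methylation_tsv(inputs.matrix, groups, species=inputs.species)
    matrix2 = None
    if config.mode == "inter":
        if inputs.matrix2 is None or inputs.groups2 is None:
            raise ValueError("inter-species mode needs matrix2 and groups2")
        groups2 = cio.read_sample_groups(inputs.groups2)
        matrix2 = cio.read_methylation_tsv(inputs.matrix2, groups2, species=inputs.species2)
    tf_map = cio.read_regulator_map(inputs.tf_map, "TF") if inputs.tf_map else None
    mir_map = cio.read_regulator_map(inputs.mir_map, "miRNA") if inputs.mir_map else None
    known_tfs = set(cio.read_gene_list(inputs.known_tfs)) if inputs.known_tfs else set()
    known_mirs = set(cio.read_gene_list(inputs.known_mirnas)) if inputs.known_mirnas else set()
    return run_pipeline(
        config,
        matrix,
        tf_map=tf_map,
        mir_map=mir_map,
        matrix2=matrix2,
        known_tfs=known_tfs,
        known_mirnas=known_mirs,
    )


def export_results(result: PipelineResult, out_dir: str | Path) -> set[Path]:
    """Write all run outputs to ``out_dir`` and return the written paths.

    Outputs: module assignment TSV, regulator-module and regulator-gene
    edge lists, ranked TF/miRNA tables, fold-change table, ultrametric
    Newick dendrogram, a flat merge table, and one gene-list file per
    module for external enrichment tools.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: set[Path] = set()

    path = out / "module_assignment.tsv"
    cio.write_module_assignment(result.assignment, path)
    written.add(path)

    path = out / "fold_change.tsv"
    result.fold_changes.to_tsv(path, selected=result.selected)
    written.add(path)

    path = out / "dendrogram.nwk"
    path.write_text(result.tree.to_newick() + "\n", encoding="utf-8")
    written.add(path)

    path = out / "merge_table.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tleft\tright\theight\tsize\n")
        for row in result.tree.to_merge_table():
            fh.write(f"{row['node']}\t{row['left']}\t{row['right']}\t{row['height']:.10g}\t{row['size']}\n")
    written.add(path)

    path = out / "regulator_gene_edges.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("class\tregulator\tgene\tmodule_color\n")
        for cls, reg, gene, color in sorted(result.network.edges):
            fh.write(f"{cls}\t{reg}\t{gene}\t{color}\n")
    written.add(path)

    path = out / "regulator_module_edges.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("class\tregulator\tmodule_color\tn_genes\n")
        for (cls, reg), by_color in sorted(result.network.summaries.items()):
            for color, genes in sorted(by_color.items()):
                fh.write(f"{cls}\t{reg}\t{color}\t{len(genes)}\n")
    written.add(path)

    for ranking, name in ((result.tf_ranking, "tf_ranking.tsv"), (result.mir_ranking, "mirna_ranking.tsv")):
        path = out / name
        ranking.to_tsv(path)
        written.add(path)

    modules_dir = out / "modules"
    modules_dir.mkdir(exist_ok=True)
    colors = sorted({c for c in result.assignment.module_color.values() if c != GREY})
    for color in colors:
        path = modules_dir / f"{color}.txt"
        path.write_text(
            "\n".join(result.assignment.color_members(color)) + "\n", encoding="utf-8"
        )
        written.add(path)

    logger.info("wrote %d result files to %s", len(written), out)
    return written
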