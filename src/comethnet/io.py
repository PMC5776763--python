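"""Readers and writers for the plain-text formats the pipeline touches.

All tabular files are tab-separated UTF-8 with a header row and ``.`` as the
decimal mark.  Dendrograms are exported as ultrametric Newick trees (leaves
at height zero, branch length = parent merge height - child merge height).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MethylationMatrix, RegulatorMap

logger = logging.getLogger("comethnet")

__all__ = [
    "read_methylation_tsv",
    "read_sample_groups",
    "read_regulator_map",
    "read_gene_list",
    "write_regulator_map",
    "write_module_assignment",
    "read_module_assignment",
]

_HEADER_TOKENS = {
    "regulator", "regulator_id", "tf", "mirna", "mir",
    "target", "gene", "target_gene", "target_gene_id",
}


def read_methylation_tsv(
    path: str | Path,
    groups: dict[str, str],
    species: str = "",
) -> MethylationMatrix:
    """Load a gene x sample methylation matrix from TSV.

    The first row is a header of sample ids, the first column holds gene
    ids.  Duplicate gene rows (probe-level input) are collapsed to their
    arithmetic mean per sample, with the number of collapsed rows logged.

    Parameters
    ----------
    path
        TSV file to read.
    groups
        Mapping assigning every sample in the header to a group label.
    species
        Free-text tag stored on the returned matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"methylation matrix not found: {path}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty methylation matrix")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        rows, cols = np.nonzero(numeric.isna().to_numpy())
        gene, sample = df.index[rows[0]], df.columns[cols[0]]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[rows[0], cols[0]]!r} "
            f"at gene {gene!r}, sample {sample!r}"
        )
    unknown = [s for s in numeric.columns if s not in groups]
    if unknown:
        raise ValueError(f"{path}: samples missing from group annotation: {unknown}")
    n_dup = int(numeric.index.duplicated().sum())
    if n_dup:
        numeric = numeric.groupby(level=0, sort=False).mean()
        logger.warning("%s: collapsed %d duplicate gene rows by mean", path, n_dup)
    sample_groups = {s: groups[s] for s in numeric.columns}
    return MethylationMatrix(data=numeric, sample_groups=sample_groups, species=species)


def read_sample_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, group label); header optional."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"group annotation not found: {path}")
    out: dict[str, str] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    for lineno, raw in enumerate(lines, 1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
        if lineno == 1 and fields[0].lower() in ("sample", "sample_id"):
            continue
        out[fields[0]] = fields[1]
    if not out:
        raise ValueError(f"{path}: no sample group assignments found")
    return out


def read_regulator_map(path: str | Path, regulator_class: str) -> RegulatorMap:
    """Read a regulator -> target two-column TSV into a deduplicated map.

    An optional header line is recognised by common column names
    (``regulator``, ``tf``, ``mirna``, ``target``, ``gene`` ...).  An empty
    file yields an empty map with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"regulator map not found: {path}")
    edges: set[tuple[str, str]] = set()
    lines = path.read_text(encoding="utf-8").splitlines()
    n_rows = 0
    for lineno, raw in enumerate(lines, 1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
        if lineno == 1 and all(f.strip().lower() in _HEADER_TOKENS for f in fields):
            continue
        reg, target = fields[0].strip(), fields[1].strip()
        if not reg or not target:
            raise ValueError(f"{path}: line {lineno}: empty identifier")
        edges.add((reg, target))
        n_rows += 1
    if not edges:
        logger.warning("%s: empty regulator map", path)
    else:
        logger.info(
            "%s: %d %s->gene edges (%d rows, %d duplicates dropped)",
            path, len(edges), regulator_class, n_rows, n_rows - len(edges),
        )
    return RegulatorMap(regulator_class=regulator_class, edges=edges, source=str(path))


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line list (e.g. known disease regulators)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"list file not found: {path}")
    return [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]


def write_regulator_map(rmap: RegulatorMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("regulator\ttarget\n")
        for reg, target in sorted(rmap.edges):
            fh.write(f"{reg}\t{target}\n")


def write_module_assignment(assignment, path: str | Path) -> None:
    """Write (gene_id, module_index, module_color) rows in input gene order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tmodule_index\tmodule_color\n")
        for gene in assignment.genes:
            fh.write(f"{gene}\t{assignment.module_index[gene]}\t{assignment.module_color[gene]}\n")


def read_module_assignment(path: str | Path):
    """Inverse of :func:`write_module_assignment`."""
    from .treecut import ModuleAssignment

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "module_color": str})
    genes = list(df["gene_id"])
    index = dict(zip(df["gene_id"], df["module_index"].astype(int)))
    color = dict(zip(df["gene_id"], df["module_color"]))
    return ModuleAssignment(genes=genes, module_index=index, module_color=color)
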