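"""Fold-change screening of differentially methylated genes.

With the very small sample counts typical of 5mC/5hmC profiling, formal
hypothesis tests are underpowered, so differential genes are selected by a
simple per-gene fold change: the ratio of the experimental-group mean to
the control-group mean (5hmC over 5mC within a species, or species 2 over
species 1 across species).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .datatypes import MethylationMatrix

logger = logging.getLogger("comethnet")

__all__ = ["FoldChangeTable", "compute_fold_change", "select_differential"]

CRITERIA = ("abs_log2fc_ge", "fc_ge", "fc_le")


@dataclass
class FoldChangeTable:
    """Per-gene group means and fold changes.

    ``table`` is indexed by gene id with columns ``mean_control``,
    ``mean_experimental``, ``fc`` and ``log2fc``; genes whose control or
    experimental mean is non-positive are excluded from ``table`` and
    listed in ``excluded`` as (gene_id, reason) pairs.
    """

    table: pd.DataFrame
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self, path: str | Path, selected: list[str] | None = None) -> None:
        out = self.table.copy()
        if selected is not None:
            sel = set(selected)
            out["selected"] = [int(g in sel) for g in out.index]
        out.to_csv(path, sep="\t", index_label="gene_id")


def compute_fold_change(
    m: MethylationMatrix,
    control_group: str,
    experimental_group: str,
) -> FoldChangeTable:
    """Per-gene ratio of experimental-group mean to control-group mean.

    Raises if either group label is unknown or if every gene ends up
    excluded.  Exclusions (non-positive group mean) are logged, not
    silently dropped.
    """
    present = set(m.sample_groups.values())
    for g in (control_group, experimental_group):
        if g not in present:
            raise ValueError(f"unknown group label {g!r}; present: {sorted(present)}")
    ctrl_cols = m.group_samples(control_group)
    exp_cols = m.group_samples(experimental_group)
    mean_ctrl = m.data[ctrl_cols].mean(axis=1)
    mean_exp = m.data[exp_cols].mean(axis=1)

    excluded: list[tuple[str, str]] = []
    keep: list[str] = []
    for gene in m.gene_ids:
        if mean_ctrl[gene] <= 0:
            excluded.append((gene, "non-positive control mean"))
        elif mean_exp[gene] <= 0:
            excluded.append((gene, "non-positive experimental mean"))
        else:
            keep.append(gene)
    if excluded:
        logger.warning("fold change: excluded %d genes with non-positive group means", len(excluded))
    if not keep:
        raise ValueError("all genes excluded: no positive group means")

    fc = mean_exp[keep] / mean_ctrl[keep]
    table = pd.DataFrame(
        {
            "mean_control": mean_ctrl[keep],
            "mean_experimental": mean_exp[keep],
            "fc": fc,
            "log2fc": [math.log2(v) for v in fc],
        },
        index=pd.Index(keep, name="gene_id"),
    )
    return FoldChangeTable(table=table, excluded=excluded)


def select_differential(fct: FoldChangeTable, threshold: float, criterion: str = "abs_log2fc_ge") -> list[str]:
    """Threshold the fold-change table into an ordered differential gene set.

    ``abs_log2fc_ge`` keeps ``|log2 FC| >= threshold`` (symmetric in up- and
    down-methylation), ``fc_ge`` keeps ``FC >= threshold``, ``fc_le`` keeps
    ``FC <= threshold``.  Boundary values are kept; input gene order is
    preserved.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")
    t = fct.table
    if criterion == "abs_log2fc_ge":
        mask = t["log2fc"].abs() >= threshold
    elif criterion == "fc_ge":
        mask = t["fc"] >= threshold
    else:
        mask = t["fc"] <= threshold
    return list(t.index[mask])
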