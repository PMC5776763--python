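"""Core containers shared across the pipeline.

A :class:`MethylationMatrix` holds a gene x sample matrix of methylation
levels together with a sample -> group mapping (e.g. ``5mC`` control vs
``5hmC`` experimental samples of one species).  A :class:`RegulatorMap` is a
bipartite edge set linking regulators (transcription factors or miRNAs) to
the genes they regulate or target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MethylationMatrix", "RegulatorMap"]


@dataclass
class MethylationMatrix:
    """Gene x sample methylation levels with per-sample group labels.

    Parameters
    ----------
    data
        DataFrame with unique gene identifiers as the index and unique
        sample identifiers as the columns; all values must be finite.
    sample_groups
        Mapping from every sample id to its group label (for example
        ``"5mC"`` / ``"5hmC"``, or a species tag for a cross-species
        contrast).
    species
        Free-text provenance tag; not interpreted by the pipeline.
    """

    data: pd.DataFrame
    sample_groups: dict[str, str]
    species: str = ""

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("methylation matrix is empty")
        if self.data.index.duplicated().any():
            dups = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = sorted(self.data.columns[self.data.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("methylation values must be numeric")
        if not np.all(np.isfinite(values)):
            raise ValueError("methylation values must be finite")
        missing = [s for s in self.data.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def group_samples(self, group: str) -> list[str]:
        """Sample ids belonging to ``group``, in column order."""
        cols = [s for s in self.data.columns if self.sample_groups[s] == group]
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        return cols


@dataclass
class RegulatorMap:
    """Deduplicated regulator -> target-gene edge set.

    ``regulator_class`` is ``"TF"`` or ``"miRNA"``; ``source`` is a free
    provenance tag (e.g. the name of the interaction database the table was
    exported from).
    """

    regulator_class: str
    edges: set[tuple[str, str]] = field(default_factory=set)
    source: str = ""

    def __post_init__(self) -> None:
        if self.regulator_class not in ("TF", "miRNA"):
            raise ValueError(f"regulator_class must be 'TF' or 'miRNA', got {self.regulator_class!r}")
        for reg, target in self.edges:
            if not reg or not target:
                raise ValueError("empty regulator or target identifier in edge set")

    @property
    def regulators(self) -> list[str]:
        return sorted({r for r, _ in self.edges})

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets_of(self, regulator: str) -> list[str]:
        return sorted({t for r, t in self.edges if r == regulator})
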