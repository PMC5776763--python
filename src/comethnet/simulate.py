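"""Synthetic methylation data with planted co-methylated modules.

The generator emulates the statistical structure the downstream analysis
assumes: blocks of genes sharing a latent per-sample factor (co-methylated
modules) and a subset of genes whose experimental-group levels are shifted
by a chosen log2 fold change (differentially methylated genes).

Model for gene *g* in module *b* and sample *s*::

    value(g, s) = (baseline + loading * f_b(s) + eps(g, s)) * 2**(shift * 1[g shifted and s experimental])

with ``f_b ~ N(0, 1)`` centred within each sample group and
``eps ~ N(0, noise_sd**2)``.  Centring the factor within groups makes the
group means free of factor leakage, so with ``noise_sd = 0`` the planted
fold change is recovered exactly.  The expected within-module Pearson
correlation is ``loading**2 / (loading**2 + noise_sd**2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MethylationMatrix, RegulatorMap

__all__ = ["SyntheticSpec", "GroundTruth", "generate_methylation", "generate_regulator_maps"]

CONTROL_GROUP = "5mC"
EXPERIMENTAL_GROUP = "5hmC"
BACKGROUND = 0


@dataclass
class SyntheticSpec:
    """Parameters of the planted-module generator.

    Defaults give three modules of 50/40/30 genes plus 30 background genes
    over 20 control + 20 experimental samples, with within-module
    correlation ~0.95 (loading 0.9, noise 0.2) and a third of the genes
    shifted by one log2 unit in the experimental group.
    """

    n_genes: int = 150
    module_sizes: tuple[int, ...] = (50, 40, 30)
    n_control_samples: int = 20
    n_experimental_samples: int = 20
    within_module_loading: float = 0.9
    noise_sd: float = 0.2
    diff_fraction: float = 0.3
    shift_log2: float = 1.0
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_control_samples < 1 or self.n_experimental_samples < 1:
            raise ValueError("n_genes and sample counts must be positive")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        if not (0 <= self.within_module_loading <= 1):
            raise ValueError("within_module_loading must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 <= self.diff_fraction <= 1):
            raise ValueError("diff_fraction must lie in [0, 1]")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")


@dataclass
class GroundTruth:
    """Planted structure: gene -> module index (0 = background) and the
    set of genes carrying the experimental-group shift."""

    module_of: dict[str, int]
    shifted: set[str] = field(default_factory=set)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_methylation(spec: SyntheticSpec) -> tuple[MethylationMatrix, GroundTruth]:
    """Draw a methylation matrix with planted modules and group shifts.

    Fully deterministic given ``spec.seed``; module genes come first in the
    returned gene order, background genes last.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    n_ctrl, n_exp = spec.n_control_samples, spec.n_experimental_samples
    n_samples = n_ctrl + n_exp
    samples = [f"{CONTROL_GROUP}_{i + 1:02d}" for i in range(n_ctrl)] + [
        f"{EXPERIMENTAL_GROUP}_{i + 1:02d}" for i in range(n_exp)
    ]
    groups = {s: (CONTROL_GROUP if i < n_ctrl else EXPERIMENTAL_GROUP) for i, s in enumerate(samples)}

    module_of = {g: BACKGROUND for g in genes}
    pos = 0
    for b, size in enumerate(spec.module_sizes, start=1):
        for g in genes[pos : pos + size]:
            module_of[g] = b
        pos += size

    values = spec.baseline_mean + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))
    pos = 0
    for size in spec.module_sizes:
        f = rng.standard_normal(n_samples)
        # centre the factor within each group so group means carry no
        # factor leakage and the planted shift is the only group signal
        f[:n_ctrl] -= f[:n_ctrl].mean()
        f[n_ctrl:] -= f[n_ctrl:].mean()
        values[pos : pos + size, :] += spec.within_module_loading * f
        pos += size

    n_shift = int(round(spec.diff_fraction * spec.n_genes))
    shifted_idx = rng.choice(spec.n_genes, size=n_shift, replace=False) if n_shift else np.array([], dtype=int)
    if n_shift:
        values[np.ix_(np.sort(shifted_idx), np.arange(n_ctrl, n_samples))] *= 2.0 ** spec.shift_log2
    shifted = {genes[i] for i in shifted_idx}

    matrix = MethylationMatrix(
        data=pd.DataFrame(values, index=genes, columns=samples),
        sample_groups=groups,
        species="synthetic",
    )
    return matrix, GroundTruth(module_of=module_of, shifted=shifted)


def generate_regulator_maps(
    truth: GroundTruth,
    n_tfs: int,
    n_mirs: int,
    targets_per_regulator: int | tuple[int, int],
    seed: int,
) -> tuple[RegulatorMap, RegulatorMap]:
    """Random TF and miRNA maps whose targets are drawn uniformly (without
    replacement per regulator) from the generated gene universe.

    ``targets_per_regulator`` is either a fixed count or an inclusive
    ``(low, high)`` range sampled per regulator.
    """
    if not truth.module_of:
        raise ValueError("ground truth is empty")
    if isinstance(targets_per_regulator, int):
        low = high = targets_per_regulator
    else:
        low, high = targets_per_regulator
    if high > 0 and n_tfs == 0 and n_mirs == 0:
        raise ValueError("no regulators requested but targets_per_regulator > 0")
    genes = sorted(truth.module_of)
    if high > len(genes):
        raise ValueError("targets_per_regulator exceeds the gene universe")
    rng = np.random.default_rng(seed)

    def draw(prefix: str, count: int, cls: str) -> RegulatorMap:
        edges: set[tuple[str, str]] = set()
        for i in range(count):
            reg = f"{prefix}{i + 1:03d}"
            k = int(rng.integers(low, high + 1))
            for j in rng.choice(len(genes), size=k, replace=False):
                edges.add((reg, genes[j]))
        return RegulatorMap(regulator_class=cls, edges=edges, source="synthetic")

    return draw("TF", n_tfs, "TF"), draw("mir-", n_mirs, "miRNA")
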