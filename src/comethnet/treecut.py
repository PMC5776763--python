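"""Dynamic tree cut of the dendrogram into color-labeled modules.

Merges above ``cut_height * max_height`` are removed and each remaining
branch becomes a candidate module; candidates are then recursively
decomposed at significant internal gaps.  A branch is accepted as a
module when it is (a) cohesive -- its root merge height does not exceed
its core scatter (the mean pairwise dissimilarity of its members) by
more than a tolerance controlled by ``deep_split`` -- and (b) tight --
its core scatter stays below a maximum expressed relative to the span
between a reference height (5th percentile of merge heights) and the cut
level.  A branch failing either test -- a union of distinct modules, or
a module with loosely chained outlier/background genes on top -- has its
top merge undone and both sides are examined recursively, so outliers
peel off while tight modules survive intact.  Candidates smaller than
``min_module_size`` are left unassigned ("grey").

Modules are numbered 1..K in decreasing size and mapped onto the
conventional module-color sequence, the largest module being turquoise and
unassigned genes grey.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cluster import Dendrogram
from .network import DissimMatrix

logger = logging.getLogger("comethnet")

__all__ = ["ModuleAssignment", "MODULE_COLORS", "GREY", "dynamic_tree_cut", "assign_colors"]

GREY = "grey"

# conventional module-color order: largest module first
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightyellow", "royalblue",
    "darkred", "darkgreen", "darkturquoise", "darkgrey", "orange",
    "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]

# cohesion tolerance per deep_split level: a branch counts as one module
# while root height <= (1 + tol) * core scatter; smaller tolerances split
# more aggressively
_COHESION_TOL = {0: 0.40, 1: 0.30, 2: 0.20, 3: 0.10, 4: 0.05}

# maximum core scatter as a fraction of (cut level - reference height);
# the values follow the published defaults of the dynamic cut method
_MAX_CORE_SCATTER = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}

_EPS = 1e-12


@dataclass
class ModuleAssignment:
    """Gene -> module partition.

    ``module_index`` maps every gene to 1..K (0 = unassigned); after
    :func:`assign_colors`, ``module_color`` maps genes to color names with
    unassigned genes labeled grey.
    """

    genes: list[str]
    module_index: dict[str, int]
    module_color: dict[str, str] = field(default_factory=dict)
    palette: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [g for g in self.genes if g not in self.module_index]
        if missing:
            raise ValueError(f"genes without a module index: {missing[:5]}")

    @property
    def n_modules(self) -> int:
        return max(self.module_index.values(), default=0)

    def module_members(self, index: int) -> list[str]:
        return [g for g in self.genes if self.module_index[g] == index]

    def color_members(self, color: str) -> list[str]:
        return [g for g in self.genes if self.module_color.get(g) == color]


def dynamic_tree_cut(
    tree: Dendrogram,
    d: DissimMatrix,
    min_module_size: int = 3,
    cut_height: float = 0.99,
    deep_split: int = 2,
) -> ModuleAssignment:
    """Decompose a dendrogram into modules (indices only; no colors yet).

    Parameters
    ----------
    tree
        Average-linkage dendrogram over the genes of ``d``.
    d
        The dissimilarity the tree was built from (checked for consistency).
    min_module_size
        Candidate branches with fewer leaves stay unassigned.
    cut_height
        Fraction of the maximum merge height above which merges are
        removed, in (0, 1].
    deep_split
        0..4; larger values lower the cohesion tolerance and split
        branches more aggressively.
    """
    if not (0 < cut_height <= 1):
        raise ValueError("cut_height must lie in (0, 1]")
    if min_module_size < 1:
        raise ValueError("min_module_size must be >= 1")
    if deep_split not in _COHESION_TOL:
        raise ValueError("deep_split must be an integer in 0..4")
    if list(tree.leaves) != list(d.gene_ids):
        raise ValueError("dendrogram and dissimilarity cover different gene sets")

    n = tree.n_leaves
    heights = [h for _, _, h, _ in tree.merges]
    max_height = max(heights)
    level = cut_height * max_height
    tol = _COHESION_TOL[deep_split]
    ref = float(np.percentile(heights, 5))
    max_scatter = ref + _MAX_CORE_SCATTER[deep_split] * max(level - ref, 0.0)

    # core scatter per node: mean pairwise dissimilarity inside the branch,
    # accumulated bottom-up (leaves have scatter 0)
    members: dict[int, list[int]] = {}
    scatter = [0.0] * (2 * n - 1)
    pair_sum = [0.0] * (2 * n - 1)
    for k, (left, right, _, size) in enumerate(tree.merges):
        mem_l = members.pop(left, None) or [left]
        mem_r = members.pop(right, None) or [right]
        cross = float(d.values[np.ix_(mem_l, mem_r)].sum())
        u = n + k
        pair_sum[u] = pair_sum[left] + pair_sum[right] + cross
        scatter[u] = pair_sum[u] / (size * (size - 1) / 2)
        members[u] = mem_l + mem_r

    # static cut: branches whose merge height is <= level but whose parent
    # merge (if any) is above it
    branch_roots: list[int] = []
    stack = [tree.root]
    while stack:
        u = stack.pop()
        if tree.node_height(u) > level + _EPS:
            stack.extend(tree.children(u))
        else:
            branch_roots.append(u)

    # recursive decomposition: undo the top merge of every branch that is
    # not cohesive (root height above (1 + tol) * core scatter) or not
    # tight (core scatter above the maximum)
    candidates: list[int] = []
    for root in branch_roots:
        stack = [root]
        while stack:
            u = stack.pop()
            ch = tree.children(u)
            height = tree.node_height(u)
            cohesive = height <= (1.0 + tol) * scatter[u] + _EPS
            tight = scatter[u] <= max_scatter + _EPS
            if ch is None or (cohesive and tight):
                candidates.append(u)
            else:
                stack.extend((ch[1], ch[0]))

    modules = [tree.members(c) for c in candidates if tree.node_size(c) >= min_module_size]
    # number 1..K in decreasing size; ties by smallest leaf index
    modules.sort(key=lambda mem: (-len(mem), min(mem)))
    index = {g: 0 for g in tree.leaves}
    for rank, members in enumerate(modules, start=1):
        for leaf in members:
            index[tree.leaves[leaf]] = rank
    n_grey = sum(1 for v in index.values() if v == 0)
    logger.info("tree cut: %d modules, %d/%d genes unassigned", len(modules), n_grey, n)
    return ModuleAssignment(genes=list(tree.leaves), module_index=index)


def assign_colors(assignment: ModuleAssignment) -> ModuleAssignment:
    """Map module indices onto the standard color sequence.

    Module 1 (the largest) becomes turquoise, then blue, brown, yellow,
    green, ...; index 0 becomes grey.  If there are more modules than
    palette entries the palette is extended with ``module_K`` names and a
    warning is logged.
    """
    k = assignment.n_modules
    palette = list(MODULE_COLORS)
    if k > len(palette):
        extra = [f"module_{i}" for i in range(len(palette) + 1, k + 1)]
        logger.warning("more modules (%d) than palette colors (%d); extending with %s",
                       k, len(palette), extra[:3])
        palette += extra
    colors = {
        g: (GREY if idx == 0 else palette[idx - 1])
        for g, idx in assignment.module_index.items()
    }
    return ModuleAssignment(
        genes=list(assignment.genes),
        module_index=dict(assignment.module_index),
        module_color=colors,
        palette=palette[:k],
    )
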