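"""Pipeline configuration with a flat key=value file representation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

__all__ = ["PipelineConfig"]

_MODES = ("intra", "inter")
_FC_CRITERIA = ("abs_log2fc_ge", "fc_ge", "fc_le")
_TRANSFORMS = ("abs", "signed_half", "clamp_zero")


@dataclass
class PipelineConfig:
    """All tunable knobs of the co-methylation module pipeline.

    Attributes
    ----------
    mode
        ``intra`` contrasts two cytosine-variant groups within one species;
        ``inter`` contrasts all samples of a second species against all
        samples of a first after intersecting their gene universes.
    fc_threshold, fc_criterion
        Fold-change selection rule for differentially methylated genes.
        The default keeps genes with ``|log2 FC| >= 0.25``.
    correlation_transform, soft_power
        How signed Pearson correlations become adjacency weights:
        ``abs`` -> |r|, ``signed_half`` -> (1+r)/2, ``clamp_zero`` -> max(r, 0),
        each then raised to ``soft_power``.
    min_module_size, cut_height, deep_split
        Dynamic tree cut parameters; ``cut_height`` is a fraction of the
        maximum merge height, ``deep_split`` (0-4) controls how aggressively
        branches are decomposed.
    top_k
        Number of rows kept in the ranked regulator tables.
    control_group / experimental_group
        Group labels used by the intra-species fold-change contrast.
    """

    mode: str = "intra"
    fc_threshold: float = 0.25
    fc_criterion: str = "abs_log2fc_ge"
    correlation_transform: str = "abs"
    soft_power: float = 1.0
    min_module_size: int = 3
    cut_height: float = 0.99
    deep_split: int = 2
    top_k: int = 10
    seed: int = 0
    control_group: str = "5mC"
    experimental_group: str = "5hmC"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if self.fc_criterion not in _FC_CRITERIA:
            raise ValueError(f"fc_criterion must be one of {_FC_CRITERIA}")
        if self.correlation_transform not in _TRANSFORMS:
            raise ValueError(f"correlation_transform must be one of {_TRANSFORMS}")
        if self.soft_power <= 0:
            raise ValueError("soft_power must be positive")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not (0 < self.cut_height <= 1):
            raise ValueError("cut_height must lie in (0, 1]")
        if not (0 <= int(self.deep_split) <= 4):
            raise ValueError("deep_split must be an integer in 0..4")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    def save(self, path: str | Path) -> None:
        """Write the configuration as ``key = value`` lines (UTF-8)."""
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        """Read a configuration written by :meth:`save` (lossless round trip)."""
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
            kwargs[key] = casts[str(types[key])](value)
        return cls(**kwargs)
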