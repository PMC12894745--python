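"""Analysis configuration: thresholds, counts, and seed handling.

Defaults are the study's operating point: differential-activity cutoff
p < 0.05, forest edge weight ≥ 0.01 stable over 10 runs, correlation
edge |r| ≥ 0.5, module size ≥ 5, 1000-permutation activity null,
100 label shuffles for the assortativity z-test, 10 independent
components.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid analysis configuration; message lists every violation."""


@dataclasses.dataclass
class AnalysisConfig:
    da_p: float = 0.05            # differential-activity significance cutoff
    edge_w: float = 0.01          # forest edge-weight threshold
    edge_cor: float = 0.5         # |Pearson r| threshold for correlation edges
    module_min_size: int = 5      # smallest reported community
    n_perm: int = 1000            # gene-label permutations for the activity null
    n_runs: int = 10              # forest runs entering the stability intersection
    n_shuffles: int = 100         # label shuffles for the assortativity null
    n_ics: int = 10               # independent components
    n_trees: int = 1000           # trees per forest run
    tree_method: str = "rf"       # 'rf' (random forest) or 'et' (extra-trees)
    min_targets: int = 5          # measured targets required to score a TF
    min_count: int = 2            # gene filter: count threshold ...
    min_count_samples: int = 2    # ... in at least this many samples
    seed: int = 0

    def validate(self) -> "AnalysisConfig":
        problems = []
        if not 0 < self.da_p <= 1:
            problems.append(f"da_p={self.da_p} outside (0, 1]")
        if not 0 <= self.edge_w <= 1:
            problems.append(f"edge_w={self.edge_w} outside [0, 1]")
        if not 0 <= self.edge_cor <= 1:
            problems.append(f"edge_cor={self.edge_cor} outside [0, 1]")
        if self.module_min_size < 1:
            problems.append(f"module_min_size={self.module_min_size} < 1")
        for name in ("n_perm", "n_runs", "n_shuffles", "n_ics", "n_trees", "min_targets"):
            if getattr(self, name) < 1:
                problems.append(f"{name}={getattr(self, name)} < 1")
        if self.tree_method not in ("rf", "et"):
            problems.append(f"tree_method={self.tree_method!r} not in {{'rf','et'}}")
        if not isinstance(self.seed, int):
            problems.append("seed must be an integer (mandatory for stochastic stages)")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(path: str | Path | None, **overrides) -> AnalysisConfig:
    """Load a YAML config, fill defaults, and report all violations together.

    Unknown keys warn and are ignored; an empty file yields the default
    configuration.
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        raw = loaded
    raw.update(overrides)
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {unknown}", stacklevel=2)
    cfg = AnalysisConfig(**{k: v for k, v in raw.items() if k in known})
    return cfg.validate()
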