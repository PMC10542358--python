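"""Pipeline configuration: every tunable parameter with its default.

Defaults follow the published cut-offs where one exists (best-site coverage
> 25 reads and methylation > 10%, two-fold dependence rule, 50 bp windows);
everything else is an explicit, documented choice. Configs round-trip through
a flat ``key = value`` text file, and each pipeline run writes its fully
resolved config next to the outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path

from .core import PipelineError


@dataclass
class PipelineConfig:
    # --- input paths (empty string = not provided) ---
    genome_fasta: str = ""
    transcripts_bed: str = ""
    counts_wt_nodmg: str = ""
    counts_wt_dmg: str = ""
    counts_ko_nodmg: str = ""
    counts_ko_dmg: str = ""
    spikein_counts: str = ""
    drip_untreated_bed: str = ""
    drip_rnaseh_bed: str = ""

    # --- m5C calling ---
    alpha: float = 0.05            # BH-adjusted significance level
    min_call_coverage: int = 10    # below this a site is reported untested
    best_min_coverage: int = 25    # "best" requires coverage strictly > this
    best_min_meth: float = 0.10    # ... and methylation strictly > this
    top_fraction: float = 0.10     # "best 10%" ranking fraction
    background_meth_factor: float = 2.0  # background C: meth <= factor * epsilon

    # --- dependence classification ---
    fold_threshold: float = 2.0    # two-fold rule, applied as fold >= threshold
    pseudocount_reads: float = 0.5

    # --- R-loop overlap ---
    removal_overlap_frac: float = 0.5  # RNaseH peak removal: overlap fraction

    # --- sequence features ---
    window_size: int = 50
    window_step: int = 50          # non-overlapping tiles by default
    skew_bin_width: float = 0.1
    gc_bin_width: float = 0.05
    flank_k: int = 10

    # --- run control ---
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise PipelineError("window_size must be >= 2")
        if self.fold_threshold <= 1:
            raise PipelineError("fold_threshold must be > 1")
        for name in ("alpha", "top_fraction", "best_min_meth"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise PipelineError(f"{name} must be in (0, 1], got {v}")
        if self.pseudocount_reads < 0:
            raise PipelineError("pseudocount_reads must be >= 0")
        if not (0 <= self.removal_overlap_frac <= 1):
            raise PipelineError("removal_overlap_frac must be in [0, 1]")


def write_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a config as a flat ``key = value`` file (fully resolved)."""
    with open(path, "w") as fh:
        for f in fields(config):
            fh.write(f"{f.name} = {getattr(config, f.name)}\n")


def read_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key = value`` config file; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"config file not found: {path}")
    known = {f.name: f.type for f in fields(PipelineConfig)}
    defaults = PipelineConfig()
    kwargs: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise PipelineError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise PipelineError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(defaults, key)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    return PipelineConfig(**kwargs)


def replace(config: PipelineConfig, **kwargs) -> PipelineConfig:
    return dataclasses.replace(config, **kwargs)
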