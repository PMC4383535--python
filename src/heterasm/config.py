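"""Pipeline configuration: a flat key = value text format with documented
defaults, range validation and exact round-tripping."""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, fields

# defaults chosen for the clone-based workflow; see docs/methods.md
@dataclass
class PipelineConfig:
    # k-mer spectrum
    spectrum_k: int = 17
    kmer_include_errors: bool = False
    smooth_window: int = 3
    peak_min_frac: float = 0.10
    # per-unit assembly k-sweep
    ksweep_min: int = 25
    ksweep_max: int = 63
    ksweep_step: int = 2
    pop_bubbles: bool = True
    bubble_identity: float = 0.9
    # overlap merge
    overlap_seed_k: int = 15
    overlap_min_len: int = 200
    overlap_min_identity: float = 0.95
    end_slack: int = 50
    # haplotig purge
    purge_k: int = 21
    purge_depth_ratio: float = 0.65
    purge_shared_frac: float = 0.60
    # scaffolding
    scaffold_seed_k: int = 21
    scaffold_min_links: int = 3
    # gap filling
    gapfill_k: int = 31
    gapfill_flank: int = 500
    gapfill_rounds: int = 2
    # misc
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spectrum_k", "purge_k", "gapfill_k"):
            k = getattr(self, name)
            if k % 2 == 0 or k < 11:
                raise ValueError(f"{name} must be odd and >= 11, got {k}")
        if self.ksweep_min % 2 == 0 or self.ksweep_max % 2 == 0:
            raise ValueError("k-sweep bounds must be odd")
        if self.ksweep_step % 2 != 0 or self.ksweep_step < 2:
            raise ValueError("k-sweep step must be even and >= 2 (odd k only)")
        if not (self.ksweep_min <= self.ksweep_max):
            raise ValueError("k-sweep range is empty")
        for name in ("overlap_min_identity", "purge_depth_ratio", "purge_shared_frac",
                     "bubble_identity", "peak_min_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("overlap_min_len", "scaffold_min_links", "gapfill_flank", "gapfill_rounds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def _parse_value(text: str, typ: type):
    if typ is bool:
        if text.lower() in ("true", "1", "yes"):
            return True
        if text.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"not a boolean: {text!r}")
    return typ(text)


def read_config(path: str | os.PathLike) -> PipelineConfig:
    """Read a flat ``key = value`` config file.

    Unknown keys warn and are ignored; missing keys take the defaults.
    """
    known = {f.name: f.type for f in fields(PipelineConfig)}
    types = {f.name: type(getattr(PipelineConfig(), f.name)) for f in fields(PipelineConfig)}
    kv: dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno} is not 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                warnings.warn(f"{path}: unknown config key {key!r} ignored")
                continue
            kv[key] = _parse_value(val, types[key])
    return PipelineConfig(**kv)


def write_config(cfg: PipelineConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for f in fields(cfg):
            fh.write(f"{f.name} = {getattr(cfg, f.name)}\n")


def sweep_ks(cfg: PipelineConfig) -> list[int]:
    return list(range(cfg.ksweep_min, cfg.ksweep_max + 1, cfg.ksweep_step))
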