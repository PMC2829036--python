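"""Run configuration: tunable thresholds outside the motif catalog.

Everything here has a stated default; a YAML file may override any
subset.  Unknown keys are rejected so typos fail loudly, and the
effective configuration is echoed to the log for reproducibility.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Optional

import yaml

from .errors import ConfigError

log = logging.getLogger("motifarch")


@dataclass(frozen=True)
class RunConfig:
    # pattern matching: one tolerated mismatch per this many pattern
    # elements (0 disables tolerance entirely); short motifs stay exact.
    mismatch_len_per_error: int = 8
    # classifier thresholds
    b15_min_extension: int = 15   # extension in front of the PRVPVAGV signature
    fusion_max_gap: int = 5       # SRICH..DLRICH gap treated as fused
    prvp_max_gap: int = 3         # PRVPVAGV..KRRW adjacency
    # consensus building
    single_threshold: float = 0.6
    class_threshold: float = 0.8
    # ancestral reconstruction
    root_state_policy: str = "prefer_absence"
    # catalog override (None = bundled catalog)
    catalog_path: Optional[str] = None
    psi_members: Optional[str] = None

    def max_mismatches(self, pattern_length: int) -> int:
        if self.mismatch_len_per_error <= 0:
            return 0
        return pattern_length // self.mismatch_len_per_error


DEFAULT_CONFIG = RunConfig()

_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides."""
    values = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            try:
                raw = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ConfigError(f"config is not valid YAML: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(values) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**values)
    _validate(cfg)
    log.info("effective config: %s", dataclasses.asdict(cfg))
    return cfg


def _validate(cfg: RunConfig) -> None:
    if cfg.root_state_policy not in {"prefer_absence", "prefer_presence"}:
        raise ConfigError(
            f"unknown root_state_policy {cfg.root_state_policy!r}"
        )
    if not 0 < cfg.single_threshold <= 1 or not 0 < cfg.class_threshold <= 1:
        raise ConfigError("consensus thresholds must be in (0, 1]")
    if cfg.mismatch_len_per_error < 0:
        raise ConfigError("mismatch_len_per_error must be >= 0")
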