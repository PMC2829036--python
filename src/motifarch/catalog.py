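"""Loading and validation of the motif catalog.

The catalog is a human-editable YAML document bundled with the package
(``data/catalog.yaml``); users may point the annotator at their own copy
to change residue classes, pattern sources or composition parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Optional

import yaml

from .errors import ConfigError
from .grammar import (
    Alternation,
    DegeneratePattern,
    ResidueClass,
    compile_pattern,
)

MOTIF_IDS = (
    "SUMO",
    "NLS",
    "NLS_VARIANT",
    "DDW",
    "ABOX",
    "SRICH",
    "SP",
    "DLRICH",
    "KRRW",
    "TXXPSIW",
    "DLKHE",
    "PSIAYRG",
    "DTS_REPEATS",
    "YRLN",
    "PRVPVAGV",
)

_MODES = {"pattern", "composition", "hybrid"}
_POSITION_KINDS = {"n_terminal", "c_terminal", "between"}


@dataclass(frozen=True)
class PositionRule:
    kind: str  # n_terminal | c_terminal | between
    window: Optional[int] = None
    anchor_after: Optional[str] = None
    anchor_gap: int = 3
    left: Optional[str] = None
    right: Optional[str] = None


@dataclass(frozen=True)
class CompositionRule:
    class_names: tuple
    members: frozenset
    window: int
    min_fraction: float
    min_run: Optional[int] = None


@dataclass
class MicrodomainDefinition:
    """One motif's detection recipe."""

    motif_id: str
    mode: str
    patterns: dict = field(default_factory=dict)  # name -> DegeneratePattern
    composition: Optional[CompositionRule] = None
    cores: dict = field(default_factory=dict)  # name -> DegeneratePattern
    fallback_patterns: dict = field(default_factory=dict)
    position: Optional[PositionRule] = None
    min_repeats: Optional[int] = None
    consensi: dict = field(default_factory=dict)  # per-type printed source strings

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ConfigError(f"{self.motif_id}: unknown mode {self.mode!r}")
        if self.mode == "hybrid" and not self.cores:
            raise ConfigError(f"{self.motif_id}: hybrid mode requires a core pattern")
        if self.mode in {"composition", "hybrid"} and self.composition is None:
            raise ConfigError(
                f"{self.motif_id}: mode {self.mode!r} requires a composition rule"
            )
        if self.mode == "pattern" and self.composition is not None:
            raise ConfigError(
                f"{self.motif_id}: composition rule only valid for "
                "composition/hybrid modes"
            )


@dataclass
class Catalog:
    classes: dict  # name -> ResidueClass
    motifs: dict  # motif_id -> MicrodomainDefinition

    @property
    def psi(self) -> ResidueClass:
        return self.classes["PSI"]

    def class_union(self, names) -> frozenset:
        members = frozenset()
        for name in names:
            if name not in self.classes:
                raise ConfigError(f"unknown residue class {name!r}")
            members |= self.classes[name].members
        return members

    def pairable_pairs(self) -> set:
        """Residue pairs a consensus column may be collapsed to.

        A pair qualifies if both residues sit in one catalog class or if
        the pair appears verbatim as an alternation in a catalog pattern.
        """
        pairs = set()
        for rc in self.classes.values():
            for a, b in combinations(sorted(rc.members), 2):
                pairs.add(frozenset((a, b)))
        for pat in self.iter_patterns():
            for el in pat.elements:
                if isinstance(el, Alternation):
                    pairs.add(frozenset(el.options))
        return pairs

    def iter_patterns(self):
        for defn in self.motifs.values():
            yield from defn.patterns.values()
            yield from defn.cores.values()
            yield from defn.fallback_patterns.values()

    def printed_sources(self) -> list:
        """Every consensus source string the catalog carries (deduplicated)."""
        out = []
        seen = set()
        for defn in self.motifs.values():
            for group in (defn.patterns, defn.cores, defn.fallback_patterns):
                for pat in group.values():
                    if pat.source not in seen:
                        seen.add(pat.source)
                        out.append(pat.source)
            for src in defn.consensi.values():
                if src not in seen:
                    seen.add(src)
                    out.append(src)
        return out


def _parse_position(raw, motif_id) -> Optional[PositionRule]:
    if raw is None:
        return None
    kind = raw.get("kind")
    if kind not in _POSITION_KINDS:
        raise ConfigError(f"{motif_id}: unknown position kind {kind!r}")
    return PositionRule(
        kind=kind,
        window=raw.get("window"),
        anchor_after=raw.get("anchor_after"),
        anchor_gap=raw.get("anchor_gap", 3),
        left=raw.get("left"),
        right=raw.get("right"),
    )


def load_catalog(path: Optional[str] = None, psi_members: Optional[str] = None) -> Catalog:
    """Read a catalog YAML file (the bundled one by default).

    ``psi_members`` overrides the membership of the Ψ class, which the
    underlying convention leaves open.
    """
    if path is None:
        text = (
            resources.files("motifarch").joinpath("data/catalog.yaml").read_text("utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"catalog is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict) or set(raw) != {"classes", "motifs"}:
        raise ConfigError("catalog must contain exactly 'classes' and 'motifs'")

    classes = {}
    for name, letters in raw["classes"].items():
        classes[name] = ResidueClass(name, frozenset(letters))
    if "PSI" not in classes:
        raise ConfigError("catalog must define the PSI class")
    if psi_members is not None:
        classes["PSI"] = ResidueClass("PSI", frozenset(psi_members))
    psi = classes["PSI"]

    motifs = {}
    for motif_id, spec in raw["motifs"].items():
        if motif_id not in MOTIF_IDS:
            raise ConfigError(f"unknown motif id {motif_id!r}")
        known = {
            "mode",
            "patterns",
            "composition",
            "cores",
            "fallback_patterns",
            "position",
            "min_repeats",
            "consensi",
        }
        extra = set(spec) - known
        if extra:
            raise ConfigError(f"{motif_id}: unknown keys {sorted(extra)}")
        comp = None
        if "composition" in spec:
            c = spec["composition"]
            comp = CompositionRule(
                class_names=tuple(c["classes"]),
                members=frozenset().union(
                    *(classes[n].members for n in c["classes"])
                ),
                window=int(c["window"]),
                min_fraction=float(c["min_fraction"]),
                min_run=c.get("min_run"),
            )
        defn = MicrodomainDefinition(
            motif_id=motif_id,
            mode=spec["mode"],
            patterns={
                name: compile_pattern(src, psi)
                for name, src in spec.get("patterns", {}).items()
            },
            composition=comp,
            cores={
                name: compile_pattern(src, psi)
                for name, src in spec.get("cores", {}).items()
            },
            fallback_patterns={
                name: compile_pattern(src, psi)
                for name, src in spec.get("fallback_patterns", {}).items()
            },
            position=_parse_position(spec.get("position"), motif_id),
            min_repeats=spec.get("min_repeats"),
            consensi=dict(spec.get("consensi", {})),
        )
        motifs[motif_id] = defn
    missing = set(MOTIF_IDS) - set(motifs)
    if missing:
        raise ConfigError(f"catalog missing motifs: {sorted(missing)}")
    return Catalog(classes=classes, motifs=motifs)
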