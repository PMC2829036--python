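"""Whole-catalog annotation of one isoform-specific-region sequence.

``detect_microdomains`` scans every motif in the catalog, applies the
positional constraints (N-/C-terminal windows, the between-motifs rule
for the SP dipeptide), keeps at most one hit per motif class (best
score, then leftmost) and attaches architecture flags.  The raw,
pre-retention hit list is kept on the region for debugging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .catalog import Catalog, load_catalog
from .config import DEFAULT_CONFIG, RunConfig
from .errors import InputError
from .grammar import (
    MotifHit,
    compile_pattern,
    scan_composition,
    scan_core_rescue,
    scan_pattern,
    scan_repeats,
    validate_sequence,
)

# expected left-to-right ranks; motifs sharing a rank are mutually unordered
A_ORDER = {
    "DLKHE": 0,
    "PSIAYRG": 0,
    "DTS_REPEATS": 0,
    "YRLN": 0,
    "SUMO": 1,
    "NLS": 2,
    "DDW": 3,
    "ABOX": 4,
}
B1_ORDER = {
    "PRVPVAGV": 0,
    "KRRW": 1,
    "TXXPSIW": 1,
    "SRICH": 2,
    "SP": 3,
    "DLRICH": 4,
}
A_EXPECTED = ("SUMO", "NLS", "DDW", "ABOX")
B1_EXPECTED = ("SRICH", "SP", "DLRICH")


@dataclass
class AnnotatedRegion:
    """One sequence's retained hits plus architecture diagnostics."""

    sequence_id: str
    isoform_hint: str  # A | B1 | unknown
    sequence: str
    hits: List[MotifHit] = field(default_factory=list)
    architecture_flags: List[str] = field(default_factory=list)
    raw_hits: List[MotifHit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def hit(self, motif_id: str) -> Optional[MotifHit]:
        for h in self.hits:
            if h.motif_id == motif_id:
                return h
        return None

    def present(self) -> set:
        return {h.motif_id for h in self.hits}


def _scan_motif(seq, defn, catalog, config) -> list:
    hits = []
    if defn.mode == "pattern":
        if defn.min_repeats:
            for pat in defn.patterns.values():
                hits.extend(
                    scan_repeats(seq, pat, defn.min_repeats, motif_id=defn.motif_id)
                )
        else:
            for name, pat in defn.patterns.items():
                mm = config.max_mismatches(len(pat))
                for h in scan_pattern(seq, pat, mm, motif_id=defn.motif_id):
                    h.detail["variant"] = name
                    hits.append(h)
        return hits

    comp = defn.composition
    cores = list(defn.cores.items()) or None
    hits = scan_composition(
        seq,
        comp.members,
        comp.window,
        comp.min_fraction,
        core_patterns=cores,
        min_run=comp.min_run,
        motif_id=defn.motif_id,
    )
    if not hits and cores:
        hits = scan_core_rescue(seq, comp.members, cores, motif_id=defn.motif_id)
    if not hits and defn.fallback_patterns:
        for name, pat in defn.fallback_patterns.items():
            mm = config.max_mismatches(len(pat))
            for h in scan_pattern(seq, pat, mm, motif_id=defn.motif_id):
                h.detail["variant"] = name
                hits.append(h)
    return hits


def _position_ok(hit, rule, seq_len, anchors) -> bool:
    if rule is None:
        return True
    if rule.kind == "n_terminal":
        if hit.start <= rule.window:
            return True
        if rule.anchor_after:
            for a in anchors.get(rule.anchor_after, []):
                gap = hit.start - a.end - 1
                if 0 <= gap <= rule.anchor_gap:
                    return True
        return False
    if rule.kind == "c_terminal":
        return hit.start >= seq_len - rule.window + 1
    return True  # 'between' handled separately


def _retain_best(hits) -> Optional[MotifHit]:
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.score, h.start, h.end))


def detect_microdomains(
    seq: str,
    isoform_hint: str = "unknown",
    sequence_id: str = "seq",
    catalog: Optional[Catalog] = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> AnnotatedRegion:
    """Scan ``seq`` with the full catalog and return an annotated region.

    ``seq`` must be an (optionally gapped) amino-acid string; gaps are
    stripped, lowercase is uppercased, and any residue outside the 20
    canonical codes is rejected with its offset.
    """
    if isoform_hint not in {"A", "B1", "unknown"}:
        raise InputError(f"unknown isoform hint {isoform_hint!r}")
    if catalog is None:
        catalog = load_catalog(config.catalog_path, psi_members=config.psi_members)
    if not seq:
        raise InputError(f"empty sequence {sequence_id!r}")
    stripped = seq.replace("-", "")
    if not stripped:
        raise InputError(f"all-gap sequence {sequence_id!r}")
    stripped = validate_sequence(stripped, sequence_id)
    n = len(stripped)

    raw = {}
    for motif_id, defn in catalog.motifs.items():
        raw[motif_id] = _scan_motif(stripped, defn, catalog, config)

    # positional filtering; anchored motifs (e.g. KRRW behind its
    # signature) see the already-filtered hits of their anchor motif.
    filtered = {}
    order = sorted(
        catalog.motifs,
        key=lambda m: (
            catalog.motifs[m].position is not None
            and catalog.motifs[m].position.anchor_after is not None
        ),
    )
    for motif_id in order:
        defn = catalog.motifs[motif_id]
        rule = defn.position
        if rule is not None and rule.kind == "between":
            continue
        filtered[motif_id] = [
            h for h in raw[motif_id] if _position_ok(h, rule, n, filtered)
        ]

    retained = {}
    for motif_id, hits in filtered.items():
        best = _retain_best(hits)
        if best is not None:
            retained[motif_id] = best

    # 'between' motifs: a dipeptide occurrence strictly inside the gap
    # separating the two flanking motifs.
    for motif_id, defn in catalog.motifs.items():
        rule = defn.position
        if rule is None or rule.kind != "between":
            continue
        left = retained.get(rule.left)
        right = retained.get(rule.right)
        if left is None or right is None:
            continue
        candidates = [
            h
            for h in raw[motif_id]
            if h.start > left.end and h.end < right.start
        ]
        best = _retain_best(candidates)
        if best is not None:
            retained[motif_id] = best
        filtered[motif_id] = candidates

    hits = sorted(retained.values(), key=lambda h: (h.start, h.end))
    all_raw = sorted(
        (h for hs in filtered.values() for h in hs), key=lambda h: (h.start, h.end)
    )
    region = AnnotatedRegion(
        sequence_id=sequence_id,
        isoform_hint=isoform_hint,
        sequence=stripped,
        hits=hits,
        raw_hits=all_raw,
    )
    region.architecture_flags = check_architecture(region)
    return region


def check_architecture(region: AnnotatedRegion) -> list:
    """Deterministic ordering/missing/duplicate diagnostics.

    Out-of-order flags name the expected-earlier motif first; the
    expected motif set depends on the isoform hint (union for
    ``unknown``).
    """
    flags = []
    if region.isoform_hint == "A":
        orders = [A_ORDER]
        expected = A_EXPECTED
    elif region.isoform_hint == "B1":
        orders = [B1_ORDER]
        expected = B1_EXPECTED
    else:
        orders = [A_ORDER, B1_ORDER]
        expected = tuple(A_EXPECTED) + tuple(B1_EXPECTED)

    present = region.present()
    for motif_id in expected:
        if motif_id not in present:
            flags.append(f"missing({motif_id})")

    for order in orders:
        ranked = [h for h in region.hits if h.motif_id in order]
        for i, a in enumerate(ranked):
            for b in ranked[i + 1 :]:
                # hits are start-sorted, so b starts at/after a
                if order[a.motif_id] > order[b.motif_id]:
                    flags.append(f"out_of_order({b.motif_id},{a.motif_id})")

    by_class = {}
    for h in region.raw_hits:
        by_class.setdefault(h.motif_id, []).append(h)
    for motif_id, hs in sorted(by_class.items()):
        disjoint = 0
        last_end = 0
        for h in sorted(hs, key=lambda h: (h.start, h.end)):
            if h.start > last_end:
                disjoint += 1
                last_end = h.end
        if disjoint > 1:
            flags.append(f"duplicate({motif_id})")
    return flags
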