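"""Rule-based assignment of structural types from a motif inventory.

The decision tables are priority-ordered: the first rule whose minimal
evidence is present fires, so additive architectures (a type-2 signature
on top of a full type-1 inventory) resolve deterministically.  Taxon
metadata is optional and only ever used to apply a documented subgroup
exemption; structure-only calls are deterministic without it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .annotate import AnnotatedRegion
from .config import DEFAULT_CONFIG, RunConfig
from .errors import InputError

A_LABELS = ("A1", "A2", "A3", "A4", "A5")
B1_LABELS = ("B1-1", "B1-2", "B1-2'", "B1-3", "B1-4", "B1-5", "B1-6")
UNCLASSIFIED = "unclassified"

#: minimal motif inventory per label (variant exemptions documented in notes)
INVENTORY = {
    "A1": {"SUMO", "NLS", "DDW", "ABOX"},
    "A2": {"DLKHE", "PSIAYRG", "SUMO", "NLS", "DDW", "ABOX"},
    "A3": {"DDW", "ABOX"},
    "A4": {"DTS_REPEATS", "SUMO", "NLS", "DDW", "ABOX"},
    "A5": {"YRLN", "SUMO", "NLS", "DDW", "ABOX"},
    "B1-1": {"SRICH", "SP", "DLRICH"},
    "B1-2": {"TXXPSIW", "SRICH", "SP", "DLRICH"},
    "B1-2'": {"TXXPSIW", "SRICH", "SP", "DLRICH"},
    "B1-3": {"KRRW", "SRICH", "SP", "DLRICH"},
    "B1-4": {"PRVPVAGV", "KRRW", "SRICH", "SP", "DLRICH"},
    "B1-5": {"PRVPVAGV", "KRRW", "SRICH", "SP", "DLRICH"},
    "B1-6": {"KRRW", "SRICH", "SP", "DLRICH"},
}


@dataclass
class StructuralTypeCall:
    label: str
    missing_motifs: List[str] = field(default_factory=list)
    notes: List[str] = field(default_factory=list)
    taxon_used: bool = False


def _finish(label, present, notes, taxon_used) -> StructuralTypeCall:
    missing = sorted(INVENTORY.get(label, set()) - present)
    return StructuralTypeCall(
        label=label, missing_motifs=missing, notes=notes, taxon_used=taxon_used
    )


def classify_a_region(
    region: AnnotatedRegion,
    taxon: Optional[str] = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> StructuralTypeCall:
    """Assign one of the five A-region structural types (or unclassified)."""
    if region.isoform_hint == "B1":
        raise InputError(
            f"{region.sequence_id}: region was annotated as B1, not A"
        )
    present = region.present()
    notes: List[str] = []
    taxon_used = False
    taxon_norm = (taxon or "").strip().lower()

    if {"DDW", "ABOX"} <= present and "SUMO" not in present and "NLS" not in present:
        return _finish("A3", present, notes, taxon_used)
    if "DTS_REPEATS" in present:
        return _finish("A4", present, notes, taxon_used)
    if "YRLN" in present:
        return _finish("A5", present, notes, taxon_used)
    if "DLKHE" in present or "PSIAYRG" in present:
        if "NLS" not in present:
            notes.append("NLS absent; consistent with the lepidopteran type-2 variant")
        return _finish("A2", present, notes, taxon_used)
    if (
        "SUMO" in present
        and ("NLS" in present or "NLS_VARIANT" in present)
        and "DDW" in present
        and "ABOX" in present
    ):
        if "NLS" not in present:
            notes.append("monopartite NLS replaced by the KxxR variant")
            if taxon_norm == "hymenoptera":
                notes.append("KxxR variant expected in Hymenoptera")
                taxon_used = True
        if taxon_norm == "diptera":
            notes.append("drosophilid N-terminal YRLN loss tolerated for Diptera")
            return _finish("A5", present, notes, True)
        return _finish("A1", present, notes, taxon_used)
    notes.append("no decision rule matched the motif inventory")
    return _finish(UNCLASSIFIED, present, notes, taxon_used)


def classify_b1_region(
    region: AnnotatedRegion,
    taxon: Optional[str] = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> StructuralTypeCall:
    """Assign one of the seven B1-region structural types (or unclassified)."""
    if region.isoform_hint == "A":
        raise InputError(
            f"{region.sequence_id}: region was annotated as A, not B1"
        )
    present = region.present()
    notes: List[str] = []

    krrw = region.hit("KRRW")
    prvp = region.hit("PRVPVAGV")
    srich = region.hit("SRICH")
    dlrich = region.hit("DLRICH")

    if krrw is not None:
        if prvp is not None and 0 <= krrw.start - prvp.end - 1 <= config.prvp_max_gap:
            extension = prvp.start - 1
            if extension >= config.b15_min_extension:
                notes.append(
                    f"{extension}-residue N-terminal extension before the signature"
                )
                return _finish("B1-5", present, notes, False)
            return _finish("B1-4", present, notes, False)
        if dlrich is not None and dlrich.detail.get("variant") == "modified":
            notes.append("DL-rich motif matched only by the modified consensus")
            return _finish("B1-6", present, notes, False)
        return _finish("B1-3", present, notes, False)

    if "TXXPSIW" in present:
        fused = (
            srich is not None
            and dlrich is not None
            and dlrich.start - srich.end - 1 <= config.fusion_max_gap
        )
        qvsss = srich is not None and srich.detail.get("core") == "qvsss"
        if fused or qvsss:
            if fused:
                notes.append("S-rich and DL-rich motifs fused or nearly fused")
            if qvsss:
                notes.append("S-rich core matched by the QVSSS variant")
            return _finish("B1-2'", present, notes, False)
        return _finish("B1-2", present, notes, False)

    if srich is not None and dlrich is not None:
        if "SP" not in present:
            notes.append("SP residues absent; heteropteran-style exception")
        return _finish("B1-1", present, notes, False)

    notes.append("no decision rule matched the motif inventory")
    return _finish(UNCLASSIFIED, present, notes, False)


def classify_region(
    region: AnnotatedRegion,
    taxon: Optional[str] = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> StructuralTypeCall:
    """Dispatch on the region's isoform hint."""
    if region.isoform_hint == "A":
        return classify_a_region(region, taxon, config)
    if region.isoform_hint == "B1":
        return classify_b1_region(region, taxon, config)
    raise InputError(
        f"{region.sequence_id}: cannot classify with isoform hint 'unknown'"
    )
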