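"""FASTA / GFF3 / TSV readers and writers.

GFF3 output is one ``polypeptide_motif`` feature per retained hit,
1-based inclusive, score column carrying the hit score; the TSV mirrors
it.  The GFF3 round trip is lossless for (motif_id, start, end, score).
"""

from __future__ import annotations

import csv
from typing import Dict, Iterable, List, Optional, Tuple

from Bio import SeqIO

from .annotate import AnnotatedRegion
from .errors import InputError
from .grammar import MotifHit

GFF_SOURCE = "motifarch"
GFF_TYPE = "polypeptide_motif"


def read_sequences(path: str, strip_gaps: bool = True) -> List[Tuple[str, str]]:
    """Read FASTA records, preserving order; duplicate ids are an error."""
    try:
        records = list(SeqIO.parse(path, "fasta"))
    except FileNotFoundError:
        raise InputError(f"no such file: {path}")
    except Exception as exc:
        raise InputError(f"cannot parse FASTA {path!r}: {exc}") from exc
    if not records:
        raise InputError(f"no FASTA records in {path!r}")
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if strip_gaps:
            seq = seq.replace("-", "").replace(".", "")
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[Tuple[str, str]], path: str, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gff_line(seqid: str, hit: MotifHit, idx: int) -> str:
    attrs = [f"ID={seqid}.{hit.motif_id}.{idx}", f"motif_id={hit.motif_id}"]
    for key in ("variant", "core"):
        if key in hit.detail:
            attrs.append(f"{key}={hit.detail[key]}")
    return "\t".join(
        [
            seqid,
            GFF_SOURCE,
            GFF_TYPE,
            str(hit.start),
            str(hit.end),
            f"{hit.score:.4f}",
            ".",
            ".",
            ";".join(attrs),
        ]
    )


def write_gff3(
    items: Iterable[Tuple[str, Iterable[MotifHit]]], path: str
) -> None:
    """Write ``(sequence_id, hits)`` pairs as GFF3 (header-only when empty)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for seqid, hits in items:
            for i, hit in enumerate(hits, start=1):
                fh.write(_gff_line(seqid, hit, i) + "\n")


def read_gff3(path: str) -> Dict[str, List[MotifHit]]:
    """Parse GFF3 back into per-sequence hit lists (inverse of write_gff3)."""
    out: Dict[str, List[MotifHit]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise InputError(f"malformed GFF3 line: {line!r}")
            seqid, _, _, start, end, score, _, _, attrs = parts
            detail = {}
            motif_id = None
            for chunk in attrs.split(";"):
                if "=" not in chunk:
                    continue
                key, value = chunk.split("=", 1)
                if key == "motif_id":
                    motif_id = value
                elif key in ("variant", "core"):
                    detail[key] = value
            if motif_id is None:
                raise InputError(f"GFF3 line lacks motif_id attribute: {line!r}")
            out.setdefault(seqid, []).append(
                MotifHit(motif_id, int(start), int(end), "", float(score), detail)
            )
    return out


def write_annotations(
    regions: Iterable[AnnotatedRegion], gff_path: str, tsv_path: str
) -> None:
    """GFF3 + TSV summary for a batch of annotated regions."""
    regions = list(regions)
    write_gff3(((r.sequence_id, r.hits) for r in regions), gff_path)
    with open(tsv_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["sequence_id", "motif_id", "start", "end", "score", "flags"]
        )
        for r in regions:
            flags = ";".join(r.architecture_flags)
            for hit in r.hits:
                writer.writerow(
                    [r.sequence_id, hit.motif_id, hit.start, hit.end, f"{hit.score:.4f}", flags]
                )


def write_classifications(rows, path: str) -> None:
    """``rows`` is an iterable of (sequence_id, isoform, StructuralTypeCall)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["sequence_id", "isoform", "label", "missing_motifs", "notes", "taxon_used"]
        )
        for seqid, isoform, call in rows:
            writer.writerow(
                [
                    seqid,
                    isoform,
                    call.label,
                    ",".join(call.missing_motifs),
                    ";".join(call.notes),
                    int(call.taxon_used),
                ]
            )


def read_taxa(path: str) -> Dict[str, str]:
    """Two-column TSV mapping sequence id to taxon (header optional)."""
    out: Dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"taxa table line {i + 1} needs two columns")
            if i == 0 and parts[0].lower() in {"sequence_id", "id", "seqid"}:
                continue
            out[parts[0]] = parts[1]
    return out
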