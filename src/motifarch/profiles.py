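"""Consensus strings and information-content profiles from alignments.

Per column the rule is: emit a residue when it reaches
``single_threshold``; otherwise collapse the two most frequent residues
to an ``(X/Y)`` symbol when they jointly reach ``class_threshold`` and
form a pairable class (a catalog residue class, or an alternation the
catalog itself prints); otherwise emit ``x``.  Columns that are mostly
gaps are dropped from the consensus string.  Information content is the
standard ``log2(20) - H`` in bits, with no small-sample correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .catalog import Catalog, load_catalog
from .errors import InputError
from .grammar import CANONICAL_RESIDUES

MAX_BITS = math.log2(20.0)


@dataclass
class ConsensusProfile:
    columns: List[dict]            # per-position residue -> frequency (gap-free)
    gap_fractions: List[float]
    info_bits: List[float]
    consensus: str
    consensus_symbols: List[str]   # one symbol per retained column
    dropped: List[bool]            # True where gap fraction > 0.5

    @property
    def length(self) -> int:
        return len(self.columns)


def information_content(frequencies: dict) -> float:
    """``log2(20) - H`` for one column's residue frequency vector."""
    total = 0.0
    entropy = 0.0
    for residue, f in frequencies.items():
        if f < 0:
            raise InputError(f"negative frequency {f} for residue {residue!r}")
        total += f
        if f > 0:
            entropy -= f * math.log2(f)
    if frequencies and abs(total - 1.0) > 1e-6:
        raise InputError(f"frequencies sum to {total}, expected 1")
    return MAX_BITS - entropy


def _column_symbol(freqs, single_threshold, class_threshold, pairable):
    items = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    if items and items[0][1] >= single_threshold - 1e-9:
        return items[0][0]
    if len(items) >= 2:
        (a, fa), (b, fb) = items[0], items[1]
        if fa + fb >= class_threshold - 1e-9 and frozenset((a, b)) in pairable:
            return f"({a}/{b})"
    return "x"


def build_consensus(
    alignment: Sequence[str],
    single_threshold: float = 0.6,
    class_threshold: float = 0.8,
    catalog: Optional[Catalog] = None,
) -> ConsensusProfile:
    """Column-wise consensus of equal-length rows ('-' marks a gap)."""
    rows = [r.upper() for r in alignment]
    if len(rows) < 2:
        raise InputError("consensus needs at least two rows")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise InputError(
                f"row {i + 1} has length {len(r)}, expected {width}"
            )
        for j, ch in enumerate(r):
            if ch != "-" and ch not in CANONICAL_RESIDUES:
                raise InputError(
                    f"illegal residue {ch!r} at row {i + 1}, column {j + 1}"
                )
    if catalog is None:
        catalog = load_catalog()
    pairable = catalog.pairable_pairs()

    columns, gap_fracs, info, dropped, symbols = [], [], [], [], []
    pieces = []
    for j in range(width):
        col = [r[j] for r in rows]
        gaps = col.count("-")
        residues = [c for c in col if c != "-"]
        counts = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        freqs = {c: k / len(residues) for c, k in counts.items()} if residues else {}
        gap_frac = gaps / len(col)
        columns.append(freqs)
        gap_fracs.append(gap_frac)
        info.append(information_content(freqs) if freqs else 0.0)
        drop = gap_frac > 0.5
        dropped.append(drop)
        if not drop:
            sym = _column_symbol(freqs, single_threshold, class_threshold, pairable)
            symbols.append(sym)
            pieces.append(sym)
    return ConsensusProfile(
        columns=columns,
        gap_fractions=gap_fracs,
        info_bits=info,
        consensus="".join(pieces),
        consensus_symbols=symbols,
        dropped=dropped,
    )


def write_profile_tsv(profile: ConsensusProfile, path: str) -> None:
    alphabet = sorted(CANONICAL_RESIDUES)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "position\tgap_fraction\tinfo_bits\tdropped\tsymbol\t"
            + "\t".join(alphabet)
            + "\n"
        )
        sym_iter = iter(profile.consensus_symbols)
        for j in range(profile.length):
            sym = "-" if profile.dropped[j] else next(sym_iter)
            freqs = profile.columns[j]
            fh.write(
                f"{j + 1}\t{profile.gap_fractions[j]:.4f}\t"
                f"{profile.info_bits[j]:.4f}\t"
                f"{int(profile.dropped[j])}\t{sym}\t"
                + "\t".join(f"{freqs.get(a, 0.0):.4f}" for a in alphabet)
                + "\n"
            )


def plot_logo(profile: ConsensusProfile, path: str) -> None:
    """Minimal information-content logo (stacked letters, height in bits)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, profile.length * 0.35), 2.5))
    for j, freqs in enumerate(profile.columns):
        if profile.dropped[j]:
            continue
        y = 0.0
        total = profile.info_bits[j]
        for residue, f in sorted(freqs.items(), key=lambda kv: kv[1]):
            h = f * total
            if h < 1e-3:
                continue
            ax.text(
                j + 0.5,
                y + h / 2,
                residue,
                ha="center",
                va="center",
                fontsize=6 + 10 * min(h / MAX_BITS, 1.0),
                family="monospace",
            )
            y += h
    ax.set_xlim(0, profile.length)
    ax.set_ylim(0, MAX_BITS)
    ax.set_ylabel("bits")
    ax.set_xlabel("position")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
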