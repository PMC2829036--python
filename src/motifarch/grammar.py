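"""Residue classes, degenerate consensus patterns, and sequence scanners.

The pattern notation supports four element kinds:

* a fixed one-letter residue (``K``),
* the wildcard ``x`` (matches any canonical residue, never a gap),
* a two-way alternation ``(X/Y)``,
* the large-hydrophobic class symbol ``Ψ`` (membership configurable,
  default ``{F, I, L, M, V, W, Y}``).

Two scanners are provided: an exhaustive sliding-window pattern matcher
(optionally tolerating a bounded number of element mismatches for long
patterns) and a compositional scanner that reports maximal runs enriched
for a union of residue classes, as used for low-complexity
activator-like elements.  All reported coordinates are 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import InputError, PatternError

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

PSI_SYMBOL = "Ψ"  # Ψ
WILDCARD_SYMBOL = "x"


@dataclass(frozen=True)
class ResidueClass:
    """A named subset of the 20 canonical amino-acid codes."""

    name: str
    members: frozenset

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        bad = self.members - CANONICAL_RESIDUES
        if bad:
            raise InputError(
                f"residue class {self.name!r} has non-canonical members: {sorted(bad)}"
            )

    def __contains__(self, residue: str) -> bool:
        return residue in self.members

    def __len__(self) -> int:
        return len(self.members)


DEFAULT_PSI = ResidueClass("PSI", frozenset("FILMVWY"))


@dataclass(frozen=True)
class Fixed:
    residue: str

    def matches(self, ch: str) -> bool:
        return ch == self.residue

    def render(self) -> str:
        return self.residue


@dataclass(frozen=True)
class Wildcard:
    def matches(self, ch: str) -> bool:
        return ch in CANONICAL_RESIDUES

    def render(self) -> str:
        return WILDCARD_SYMBOL


@dataclass(frozen=True)
class ClassSymbol:
    residue_class: ResidueClass

    def matches(self, ch: str) -> bool:
        return ch in self.residue_class

    def render(self) -> str:
        return PSI_SYMBOL


@dataclass(frozen=True)
class Alternation:
    options: tuple

    def matches(self, ch: str) -> bool:
        return ch in self.options

    def render(self) -> str:
        return "(%s/%s)" % self.options


@dataclass(frozen=True)
class DegeneratePattern:
    """An ordered list of pattern elements plus the source notation."""

    elements: tuple
    source: str

    def __len__(self) -> int:
        return len(self.elements)

    def render(self) -> str:
        """Canonical notation; round-trips through :func:`compile_pattern`."""
        return "".join(e.render() for e in self.elements)


def compile_pattern(source: str, psi: ResidueClass = DEFAULT_PSI) -> DegeneratePattern:
    """Parse a printed consensus string into a :class:`DegeneratePattern`.

    Raises :class:`PatternError` naming the 1-based offending position for
    malformed alternations or symbols outside the notation.
    """
    elements = []
    i = 0
    n = len(source)
    while i < n:
        ch = source[i]
        pos = i + 1
        if ch == PSI_SYMBOL:
            elements.append(ClassSymbol(psi))
            i += 1
        elif ch == WILDCARD_SYMBOL:
            elements.append(Wildcard())
            i += 1
        elif ch == "(":
            end = source.find(")", i)
            if end == -1:
                raise PatternError(
                    f"unterminated alternation starting at position {pos}", position=pos
                )
            body = source[i + 1 : end]
            parts = body.split("/")
            if len(parts) != 2 or any(len(p) != 1 for p in parts):
                raise PatternError(
                    f"malformed alternation {source[i:end + 1]!r} at position {pos}",
                    position=pos,
                )
            for p in parts:
                if p not in CANONICAL_RESIDUES:
                    raise PatternError(
                        f"non-amino-acid symbol {p!r} in alternation at position {pos}",
                        position=pos,
                    )
            elements.append(Alternation((parts[0], parts[1])))
            i = end + 1
        elif ch in CANONICAL_RESIDUES:
            elements.append(Fixed(ch))
            i += 1
        else:
            raise PatternError(
                f"unexpected symbol {ch!r} at position {pos}", position=pos
            )
    if len(elements) < 2:
        raise PatternError("pattern must contain at least two elements", position=1)
    return DegeneratePattern(tuple(elements), source)


@dataclass
class MotifHit:
    """One positioned motif match. ``start``/``end`` are 1-based inclusive."""

    motif_id: Optional[str]
    start: int
    end: int
    matched: str
    score: float
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid hit span {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def validate_sequence(seq: str, sequence_id: Optional[str] = None) -> str:
    """Uppercase ``seq`` and reject anything outside the 20 canonical codes."""
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in CANONICAL_RESIDUES:
            where = f" in sequence {sequence_id!r}" if sequence_id else ""
            raise InputError(
                f"illegal residue {ch!r} at position {i + 1}{where}"
            )
    return seq


def scan_pattern(
    seq: str,
    pattern: DegeneratePattern,
    max_mismatches: int = 0,
    motif_id: Optional[str] = None,
) -> list:
    """All (possibly overlapping) matches of ``pattern`` in ``seq``.

    A match at offset ``s`` compares element ``j`` against residue
    ``s + j``; at most ``max_mismatches`` element failures are tolerated
    (default exact).  Hits are returned sorted by start, score
    ``1 - mismatches / len(pattern)``.
    """
    seq = validate_sequence(seq)
    m = len(pattern)
    hits = []
    for s in range(len(seq) - m + 1):
        mm = 0
        ok = True
        for j, el in enumerate(pattern.elements):
            if not el.matches(seq[s + j]):
                mm += 1
                if mm > max_mismatches:
                    ok = False
                    break
        if ok:
            hits.append(
                MotifHit(
                    motif_id,
                    s + 1,
                    s + m,
                    seq[s : s + m],
                    1.0 - mm / m,
                    {"mismatches": mm},
                )
            )
    return hits


def scan_repeats(
    seq: str,
    unit: DegeneratePattern,
    min_repeats: int = 2,
    motif_id: Optional[str] = None,
) -> list:
    """Maximal tandem runs of ``unit`` with at least ``min_repeats`` copies."""
    seq = validate_sequence(seq)
    u = len(unit)
    starts = {h.start - 1 for h in scan_pattern(seq, unit)}
    hits = []
    for s in sorted(starts):
        if s - u in starts:
            continue  # not the head of a tandem chain
        k = 0
        t = s
        while t in starts:
            k += 1
            t += u
        if k >= min_repeats:
            end0 = s + k * u - 1
            hits.append(
                MotifHit(
                    motif_id,
                    s + 1,
                    end0 + 1,
                    seq[s : end0 + 1],
                    1.0,
                    {"repeats": k},
                )
            )
    return hits


def _member_flags(seq: str, members) -> list:
    return [c in members for c in seq]


def scan_composition(
    seq: str,
    members,
    window: int,
    min_fraction: float,
    core_patterns: Optional[Sequence] = None,
    min_run: Optional[int] = None,
    motif_id: Optional[str] = None,
) -> list:
    """Maximal class-enriched runs.

    A run is the union of all overlapping/abutting length-``window``
    subwindows whose class-member fraction is at least ``min_fraction``,
    extended outward over contiguous class members and trimmed to
    class-member boundaries.  ``core_patterns`` is an optional sequence of
    ``(name, DegeneratePattern)`` pairs; runs lacking an exact core match
    are discarded and the matching core name is recorded in the hit
    detail.  Hit score is the overall class fraction of the final span.

    A window longer than the sequence yields an empty result.
    """
    if not 0 < min_fraction <= 1:
        raise InputError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if window < 3:
        raise InputError(f"window must be >= 3, got {window}")
    seq = validate_sequence(seq)
    n = len(seq)
    if n == 0 or window > n:
        return []
    ism = _member_flags(seq, members)
    pref = [0]
    for f in ism:
        pref.append(pref[-1] + int(f))
    need = min_fraction * window - 1e-9
    good = [
        i for i in range(n - window + 1) if pref[i + window] - pref[i] >= need
    ]
    spans = []
    for g in good:
        if spans and g <= spans[-1][1] + 1:
            spans[-1][1] = max(spans[-1][1], g + window - 1)
        else:
            spans.append([g, g + window - 1])
    hits = []
    for a, b in spans:
        while a > 0 and ism[a - 1]:
            a -= 1
        while b < n - 1 and ism[b + 1]:
            b += 1
        while a <= b and not ism[a]:
            a += 1
        while b >= a and not ism[b]:
            b -= 1
        if a > b:
            continue
        length = b - a + 1
        if min_run is not None and length < min_run:
            continue
        detail = {}
        if core_patterns:
            sub = seq[a : b + 1]
            core_name = None
            for name, pat in core_patterns:
                if scan_pattern(sub, pat):
                    core_name = name
                    break
            if core_name is None:
                continue
            detail["core"] = core_name
        frac = (pref[b + 1] - pref[a]) / length
        hits.append(MotifHit(motif_id, a + 1, b + 1, seq[a : b + 1], frac, detail))
    return hits


def scan_core_rescue(
    seq: str,
    members,
    core_patterns: Sequence,
    motif_id: Optional[str] = None,
) -> list:
    """Fallback for hybrid motifs whose surrounding composition is too dilute.

    Each exact core match is extended outward over contiguous class
    members; the hit keeps the full core even where core positions are
    not class members.  Score is the class fraction of the final span.
    """
    seq = validate_sequence(seq)
    ism = _member_flags(seq, members)
    n = len(seq)
    hits = []
    seen = set()
    for name, pat in core_patterns:
        for h in scan_pattern(seq, pat):
            a, b = h.start - 1, h.end - 1
            while a > 0 and ism[a - 1]:
                a -= 1
            while b < n - 1 and ism[b + 1]:
                b += 1
            if (a, b) in seen:
                continue
            seen.add((a, b))
            frac = sum(ism[a : b + 1]) / (b - a + 1)
            hits.append(
                MotifHit(
                    motif_id,
                    a + 1,
                    b + 1,
                    seq[a : b + 1],
                    frac,
                    {"core": name, "rescued": True},
                )
            )
    hits.sort(key=lambda h: (h.start, h.end))
    return hits
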