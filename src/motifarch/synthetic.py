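"""Ground-truthed exemplar sequences for the twelve structural types.

Each template realizes its motif consensi (alternations take the first
alternative, ``x`` draws from the linker alphabet, ``Ψ`` becomes ``L``)
and joins them with linkers drawn from an alphabet chosen to be outside
every motif residue class (default ``{G, N, Q}``), so linkers can never
create spurious compositional hits.  Optional substitution noise is
applied inside motif instances only; motif-destroying substitutions are
deliberately allowed.  Generation is fully deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .catalog import load_catalog
from .errors import InputError
from .grammar import (
    Alternation,
    CANONICAL_RESIDUES,
    ClassSymbol,
    DegeneratePattern,
    Fixed,
    MotifHit,
    Wildcard,
    compile_pattern,
)

DEFAULT_LINKER_ALPHABET = "GNQ"
_ALL = sorted(CANONICAL_RESIDUES)

A_TEMPLATES = ("A1", "A2", "A3", "A4", "A5")
B1_TEMPLATES = ("B1-1", "B1-2", "B1-2'", "B1-3", "B1-4", "B1-5", "B1-6")
ALL_TEMPLATES = A_TEMPLATES + B1_TEMPLATES

# segment grammar: ("linker", lo, hi) draws a linker of random length;
# ("motif", motif_id, source) realizes one instance and records ground
# truth. Linker segments tagged "free" may be globally overridden.
_T = {
    "A1": (
        "A",
        [
            ("linker", 2, 6, True),
            ("motif", "SUMO", "ΨKxE"),
            ("linker", 4, 10, True),
            ("motif", "NLS", "K(K/R)x(K/R)"),
            ("linker", 4, 10, True),
            ("motif", "DDW", "(D/E)(D/E)W"),
            ("linker", 4, 10, True),
            ("motif", "ABOX", "NGxSPSxxSSYDxxYSP"),
            ("linker", 0, 3, True),
        ],
    ),
    "A2": (
        "A",
        [
            ("motif", "DLKHE", "DLKHE"),
            ("linker", 1, 3, False),
            ("motif", "PSIAYRG", "ΨAYRG"),
            ("linker", 4, 10, True),
            ("motif", "SUMO", "ΨKxE"),
            ("linker", 3, 8, True),
            ("motif", "NLS", "K(K/R)x(K/R)"),
            ("linker", 4, 10, True),
            ("motif", "DDW", "(D/E)(D/E)W"),
            ("linker", 4, 10, True),
            ("motif", "ABOX", "NGYSSP(M/L)SSGSYDPYSP"),
            ("linker", 0, 3, True),
        ],
    ),
    "A3": (
        "A",
        [
            ("linker", 2, 6, True),
            ("motif", "DDW", "(D/E)(D/E)W"),
            ("linker", 4, 10, True),
            ("motif", "ABOX", "NGxPSPTMSSMSYDPYSP"),
            ("linker", 0, 3, True),
        ],
    ),
    "A4": (
        "A",
        [
            ("motif", "DTS_REPEATS", "D(T/S)SD(T/S)SD(T/S)S"),
            ("linker", 3, 8, True),
            ("motif", "SUMO", "ΨKxE"),
            ("linker", 3, 8, True),
            ("motif", "NLS", "K(K/R)x(K/R)"),
            ("linker", 4, 10, True),
            ("motif", "DDW", "(D/E)(D/E)W"),
            ("linker", 4, 10, True),
            ("motif", "ABOX", "NGYASPMS(T/S)GSYDPYSP"),
            ("linker", 0, 3, True),
        ],
    ),
    "A5": (
        "A",
        [
            ("motif", "YRLN", "YRLN"),
            ("linker", 2, 5, False),
            ("motif", "SUMO", "ΨKxE"),
            ("linker", 3, 8, True),
            ("motif", "NLS", "K(K/R)x(K/R)"),
            ("linker", 4, 10, True),
            ("motif", "DDW", "(D/E)(D/E)W"),
            ("linker", 4, 10, True),
            ("motif", "ABOX", "NGYASPMSAGSYDPYSPNG"),
            ("linker", 0, 3, True),
        ],
    ),
    "B1-1": (
        "B1",
        [
            ("linker", 2, 6, True),
            ("motif", "SRICH", "GDExSxEVSSSS"),
            ("linker", 4, 6, False),
            ("motif", "SP", "SP"),
            ("linker", 2, 6, True),
            ("motif", "DLRICH", "DIGEVDLDFWDLDL"),
            ("linker", 0, 4, True),
        ],
    ),
    "B1-2": (
        "B1",
        [
            ("motif", "TXXPSIW", "TxxΨW"),
            ("linker", 3, 5, False),
            ("motif", "SRICH", "GxESSPEVTSSS"),
            ("linker", 4, 6, False),
            ("motif", "SP", "SP"),
            ("linker", 3, 6, False),
            ("motif", "DLRICH", "DIGEVDLEFWDLDL"),
            ("linker", 0, 4, True),
        ],
    ),
    "B1-2'": (
        "B1",
        [
            ("motif", "TXXPSIW", "TxxΨW"),
            ("linker", 3, 5, False),
            ("motif", "SRICH", "EDxxxQVSSS"),
            ("linker", 1, 1, False),
            ("motif", "SP", "SP"),
            ("linker", 1, 1, False),
            ("motif", "DLRICH", "EVDLELWDLGL"),
            ("linker", 0, 4, True),
        ],
    ),
    "B1-3": (
        "B1",
        [
            ("motif", "KRRW", "(K/R)RRW"),
            ("linker", 3, 6, False),
            ("motif", "SRICH", "EESSSEVTSSS"),
            ("linker", 4, 6, False),
            ("motif", "SP", "SP"),
            ("linker", 2, 6, True),
            ("motif", "DLRICH", "DIGDVDLEFWDLDL"),
            ("linker", 0, 4, True),
        ],
    ),
    "B1-4": (
        "B1",
        [
            ("motif", "PRVPVAGV", "LQTVPRVPVAGV"),
            ("motif", "KRRW", "(K/R)RRW"),
            ("linker", 3, 8, True),
            ("motif", "SRICH", "ESSPEVSSS"),
            ("linker", 4, 6, False),
            ("motif", "SP", "SP"),
            ("linker", 2, 6, True),
            ("motif", "DLRICH", "EDLQLWDLDL"),
            ("linker", 0, 4, True),
        ],
    ),
    "B1-5": (
        "B1",
        [
            ("linker", 16, 20, False),  # N-terminal extension
            ("motif", "PRVPVAGV", "LAVPRVPVAGV"),
            ("motif", "KRRW", "(K/R)RRW"),
            ("linker", 3, 8, True),
            ("motif", "SRICH", "ESSPEVSSS"),
            ("linker", 4, 6, False),
            ("motif", "SP", "SP"),
            ("linker", 2, 6, True),
            ("motif", "DLRICH", "EDLQLWDLDL"),
            ("linker", 0, 4, True),
        ],
    ),
    "B1-6": (
        "B1",
        [
            ("motif", "KRRW", "(K/R)RRW"),
            ("linker", 3, 6, False),
            ("motif", "SRICH", "EESSSEVTSSS"),
            ("linker", 4, 6, False),
            ("motif", "SP", "SP"),
            ("linker", 2, 6, True),
            ("motif", "DLRICH", "(D/E)Y(C/G)(E/D)LWxxxxD"),
            ("linker", 0, 4, True),
        ],
    ),
}


@dataclass
class SyntheticSpec:
    template: str
    noise_rate: float = 0.0
    linker_length_range: Optional[Tuple[int, int]] = None  # free linkers only
    linker_alphabet: str = DEFAULT_LINKER_ALPHABET
    seed: int = 0

    def __post_init__(self):
        if self.template not in _T:
            raise InputError(f"unknown template {self.template!r}")
        if not 0 <= self.noise_rate <= 0.5:
            raise InputError(f"noise_rate must be in [0, 0.5], got {self.noise_rate}")
        if self.linker_length_range is not None:
            lo, hi = self.linker_length_range
            if lo < 0 or hi < lo:
                raise InputError(f"bad linker_length_range {self.linker_length_range}")


@dataclass
class Exemplar:
    sequence_id: str
    label: str
    isoform: str
    sequence: str
    ground_truth: List[MotifHit]


def realize_pattern(source: str, rng, linker_alphabet: str) -> str:
    """One concrete instance of a printed consensus string."""
    pattern = compile_pattern(source)
    out = []
    for el in pattern.elements:
        if isinstance(el, Fixed):
            out.append(el.residue)
        elif isinstance(el, Alternation):
            out.append(el.options[0])
        elif isinstance(el, ClassSymbol):
            out.append("L")
        elif isinstance(el, Wildcard):
            out.append(linker_alphabet[rng.integers(len(linker_alphabet))])
        else:  # pragma: no cover
            raise AssertionError(el)
    return "".join(out)


def make_exemplar(spec: SyntheticSpec, sequence_id: Optional[str] = None) -> Exemplar:
    """Deterministically build one exemplar with its ground-truth hits."""
    isoform, segments = _T[spec.template]
    rng = np.random.default_rng(spec.seed)
    pieces: List[str] = []
    truth: List[MotifHit] = []
    pos = 0  # 0-based running length
    motif_spans = []
    for seg in segments:
        if seg[0] == "linker":
            _, lo, hi, free = seg
            if free and spec.linker_length_range is not None:
                lo, hi = spec.linker_length_range
            length = int(rng.integers(lo, hi + 1))
            piece = "".join(
                spec.linker_alphabet[rng.integers(len(spec.linker_alphabet))]
                for _ in range(length)
            )
        else:
            _, motif_id, source = seg
            piece = realize_pattern(source, rng, spec.linker_alphabet)
            truth.append(
                MotifHit(
                    motif_id,
                    pos + 1,
                    pos + len(piece),
                    piece,
                    1.0,
                    {"template": spec.template, "source": source},
                )
            )
            motif_spans.append((pos, pos + len(piece)))
        pieces.append(piece)
        pos += len(piece)
    seq = list("".join(pieces))

    if spec.noise_rate > 0:
        for a, b in motif_spans:
            for i in range(a, b):
                if rng.random() < spec.noise_rate:
                    alternatives = [c for c in _ALL if c != seq[i]]
                    seq[i] = alternatives[rng.integers(len(alternatives))]
    sequence = "".join(seq)
    for h in truth:
        h.matched = sequence[h.start - 1 : h.end]

    if sequence_id is None:
        sequence_id = f"{sanitize_label(spec.template)}_s{spec.seed}"
    return Exemplar(
        sequence_id=sequence_id,
        label=spec.template,
        isoform=isoform,
        sequence=sequence,
        ground_truth=truth,
    )


def sanitize_label(label: str) -> str:
    return label.replace("'", "p")


def make_panel(
    templates,
    replicates: int = 1,
    noise_rate: float = 0.0,
    seed: int = 0,
    linker_length_range: Optional[Tuple[int, int]] = None,
) -> List[Exemplar]:
    """Replicated exemplars with per-sequence seeds derived from ``seed``."""
    if not templates:
        raise InputError("templates must be non-empty")
    base = np.random.default_rng(seed)
    out = []
    for template in templates:
        for r in range(replicates):
            child_seed = int(base.integers(0, 2**31 - 1))
            spec = SyntheticSpec(
                template=template,
                noise_rate=noise_rate,
                linker_length_range=linker_length_range,
                seed=child_seed,
            )
            out.append(
                make_exemplar(
                    spec, sequence_id=f"{sanitize_label(template)}_r{r}_s{child_seed}"
                )
            )
    return out


def consensus_instances(
    source: str, n: int, linker_alphabet: str = DEFAULT_LINKER_ALPHABET
) -> List[str]:
    """Noise-free instance set designed to round-trip consensus building.

    Alternation columns split just over half / just under half between
    the two printed alternatives (so the printed order is recoverable);
    wildcard and ``Ψ`` columns cycle through their allowed residues and
    collapse back to ``x``.
    """
    if n < 2:
        raise InputError("need at least two instances")
    pattern = compile_pattern(source)
    first = n // 2 + 1
    rows = []
    for i in range(n):
        row = []
        for el in pattern.elements:
            if isinstance(el, Fixed):
                row.append(el.residue)
            elif isinstance(el, Alternation):
                row.append(el.options[0] if i < first else el.options[1])
            elif isinstance(el, ClassSymbol):
                members = sorted(el.residue_class.members)
                row.append(members[i % len(members)])
            else:
                row.append(linker_alphabet[i % len(linker_alphabet)])
        rows.append("".join(row))
    return rows


def expected_consensus_recovery(source: str) -> str:
    """What :func:`consensus_instances` + consensus building should return.

    Identical to ``source`` except that ``Ψ`` columns degrade to ``x``:
    the consensus alphabet has no symbol for a seven-residue class.
    """
    pattern = compile_pattern(source)
    out = []
    for el in pattern.elements:
        if isinstance(el, ClassSymbol):
            out.append("x")
        else:
            out.append(el.render())
    return "".join(out)
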