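"""Reading and writing RNA secondary structures.

Supported on-disk formats are dot-bracket (with pseudoknot bracket
layers), CT, and BPSEQ; bare sequences travel as FASTA.  The in-memory
model is :class:`SecondaryStructure`: a sequence over {A,C,G,U} plus a
set of 0-based base pairs.  Base triples (a base in more than one pair)
are representable in memory but not in CT/BPSEQ/dot-bracket, and the
writers refuse them rather than silently dropping pairs.

Conventions: internal coordinates are 0-based (half-open for ranges);
CT and BPSEQ files are 1-based with partner 0 meaning unpaired.  ``T``
is transparently mapped to ``U`` and lowercase input is uppercased,
since sequences frequently arrive from DNA-alphabet FASTA files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "SecondaryStructure",
    "StructureError",
    "StructureParseError",
    "UnrepresentableStructureError",
    "parse_dotbracket",
    "parse_ct",
    "parse_bpseq",
    "write_structure",
    "read_fasta",
    "write_fasta",
    "read_dotbracket_file",
    "write_dotbracket_file",
]

#: Pseudoknot bracket layers in precedence order.
OPEN_BRACKETS = "([{<AB"
CLOSE_BRACKETS = ")]}>ab"
_CLOSE_OF = dict(zip(OPEN_BRACKETS, CLOSE_BRACKETS))
_OPEN_OF = dict(zip(CLOSE_BRACKETS, OPEN_BRACKETS))

_VALID_BASES = frozenset("ACGU")


class StructureError(ValueError):
    """Base class for structure I/O and validation errors."""


class StructureParseError(StructureError):
    """Raised when a structure file cannot be parsed."""


class UnrepresentableStructureError(StructureError):
    """Raised when a structure cannot be expressed in the requested format."""


def _normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    seq = seq.strip().upper().replace("T", "U")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise StructureParseError(
            f"{context} contains non-ACGU symbol(s): {sorted(bad)!r}"
        )
    return seq


@dataclass
class SecondaryStructure:
    """An RNA sequence together with its set of base pairs.

    Parameters
    ----------
    sequence:
        String over {A,C,G,U} (``T``/lowercase normalized on input paths,
        not here).
    pairs:
        Set of 0-based ``(i, j)`` tuples with ``i < j``.  A base may
        participate in more than one pair (base triples); pseudoknots
        (crossing pairs) are allowed.
    name:
        Free-text identifier.
    """

    sequence: str
    pairs: set[tuple[int, int]] = field(default_factory=set)
    name: str = ""

    def __post_init__(self) -> None:
        self.pairs = {tuple(p) for p in self.pairs}
        n = len(self.sequence)
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise StructureError(
                    f"pair ({i},{j}) out of range for length-{n} sequence"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n(self) -> int:
        return len(self.sequence)

    def partner_count(self) -> list[int]:
        """Number of pairs each base participates in."""
        counts = [0] * len(self.sequence)
        for i, j in self.pairs:
            counts[i] += 1
            counts[j] += 1
        return counts

    def is_single_partner(self) -> bool:
        """True iff no base participates in more than one pair."""
        return all(c <= 1 for c in self.partner_count())

    def partner_array(self) -> list[int]:
        """0-based partner per position, -1 for unpaired.

        Raises :class:`UnrepresentableStructureError` on base triples.
        """
        partner = [-1] * len(self.sequence)
        for i, j in sorted(self.pairs):
            if partner[i] != -1 or partner[j] != -1:
                raise UnrepresentableStructureError(
                    f"base triple at pair ({i},{j}): a base has >1 partner"
                )
            partner[i] = j
            partner[j] = i
        return partner


# ---------------------------------------------------------------------------
# dot-bracket


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket record (sequence line + bracket line).

    An optional leading ``>name`` header is accepted.  Matched brackets
    of the same layer become pairs; layers ``()``, ``[]``, ``{}``,
    ``<>``, ``Aa``, ``Bb`` may cross each other (pseudoknots).
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    name = ""
    if lines and lines[0].startswith(">"):
        name = lines[0][1:].strip()
        lines = lines[1:]
    if len(lines) != 2:
        raise StructureParseError(
            f"expected sequence and bracket lines, got {len(lines)} line(s)"
        )
    seq = _normalize_sequence(lines[0])
    db = lines[1]
    if len(db) != len(seq):
        raise StructureParseError(
            f"bracket string length {len(db)} != sequence length {len(seq)}"
        )
    stacks: dict[str, list[int]] = {b: [] for b in OPEN_BRACKETS}
    pairs: set[tuple[int, int]] = set()
    for k, ch in enumerate(db):
        if ch == ".":
            continue
        if ch in _CLOSE_OF:  # opener
            stacks[ch].append(k)
        elif ch in _OPEN_OF:  # closer
            stack = stacks[_OPEN_OF[ch]]
            if not stack:
                raise StructureParseError(
                    f"unbalanced bracket {ch!r} at position {k}"
                )
            pairs.add((stack.pop(), k))
        else:
            raise StructureParseError(
                f"unknown structure symbol {ch!r} at position {k}"
            )
    for opener, stack in stacks.items():
        if stack:
            raise StructureParseError(
                f"unbalanced bracket {opener!r} opened at position {stack[-1]}"
            )
    return SecondaryStructure(seq, pairs, name)


def _assign_layers(pairs: Iterable[tuple[int, int]]) -> dict[tuple[int, int], int]:
    """Greedy crossing-conflict coloring of pairs into bracket layers.

    Pairs are visited sorted by (i, -j); each goes to the lowest layer
    where it crosses no already-placed pair.  Nested/disjoint pairs
    share a layer; crossing pairs do not.
    """
    layers: list[list[tuple[int, int]]] = []
    assignment: dict[tuple[int, int], int] = {}
    for i, j in sorted(pairs, key=lambda p: (p[0], -p[1])):
        placed = False
        for idx, layer in enumerate(layers):
            if all(not (a < i < b < j or i < a < j < b) for a, b in layer):
                layer.append((i, j))
                assignment[(i, j)] = idx
                placed = True
                break
        if not placed:
            if len(layers) >= len(OPEN_BRACKETS):
                raise UnrepresentableStructureError(
                    "structure needs more pseudoknot layers than available"
                )
            layers.append([(i, j)])
            assignment[(i, j)] = len(layers) - 1
    return assignment


def _to_dotbracket(s: SecondaryStructure) -> str:
    partner = s.partner_array()  # rejects triples
    del partner
    assignment = _assign_layers(s.pairs)
    chars = ["."] * len(s.sequence)
    for (i, j), layer in assignment.items():
        chars[i] = OPEN_BRACKETS[layer]
        chars[j] = CLOSE_BRACKETS[layer]
    header = f">{s.name}\n" if s.name else ""
    return f"{header}{s.sequence}\n{''.join(chars)}\n"


# ---------------------------------------------------------------------------
# CT


def parse_ct(text: str) -> SecondaryStructure:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise StructureParseError("empty CT record")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError) as exc:
        raise StructureParseError(f"bad CT header: {lines[0]!r}") from exc
    name = " ".join(header[1:])
    body = lines[1:]
    if len(body) != n:
        raise StructureParseError(
            f"CT header declares {n} bases but {len(body)} lines follow"
        )
    bases = [""] * n
    partner = [0] * n
    for ln in body:
        fields = ln.split()
        if len(fields) < 5:
            raise StructureParseError(f"short CT line: {ln!r}")
        idx = int(fields[0])
        if not 1 <= idx <= n:
            raise StructureParseError(f"CT index {idx} out of range 1..{n}")
        bases[idx - 1] = fields[1]
        partner[idx - 1] = int(fields[4])
    seq = _normalize_sequence("".join(bases), context="CT sequence")
    pairs = _pairs_from_partner(partner, n, fmt="CT")
    return SecondaryStructure(seq, pairs, name)


def _pairs_from_partner(partner: list[int], n: int, fmt: str) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    for k, p in enumerate(partner, start=1):
        if p == 0:
            continue
        if not 1 <= p <= n:
            raise StructureParseError(
                f"{fmt}: base {k} has out-of-range partner {p}"
            )
        if partner[p - 1] != k:
            raise StructureParseError(
                f"{fmt}: asymmetric partners — base {k} says {p} "
                f"but base {p} says {partner[p - 1]}"
            )
        if p == k:
            raise StructureParseError(f"{fmt}: base {k} paired with itself")
        pairs.add((min(k, p) - 1, max(k, p) - 1))
    return pairs


def _to_ct(s: SecondaryStructure) -> str:
    partner = s.partner_array()
    n = len(s.sequence)
    out = [f"{n} {s.name}".rstrip()]
    for k in range(n):
        nxt = k + 2 if k + 1 < n else 0
        out.append(
            f"{k + 1} {s.sequence[k]} {k} {nxt} {partner[k] + 1} {k + 1}"
        )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# BPSEQ


def parse_bpseq(text: str) -> SecondaryStructure:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise StructureParseError("empty BPSEQ record")
    bases: list[str] = []
    partner: list[int] = []
    for k, ln in enumerate(lines, start=1):
        fields = ln.split()
        if len(fields) != 3:
            raise StructureParseError(f"malformed BPSEQ line: {ln!r}")
        idx = int(fields[0])
        if idx != k:
            raise StructureParseError(
                f"BPSEQ indices must be 1..n consecutive; got {idx} at line {k}"
            )
        bases.append(fields[1])
        partner.append(int(fields[2]))
    seq = _normalize_sequence("".join(bases), context="BPSEQ sequence")
    pairs = _pairs_from_partner(partner, len(seq), fmt="BPSEQ")
    return SecondaryStructure(seq, pairs)


def _to_bpseq(s: SecondaryStructure) -> str:
    partner = s.partner_array()
    return (
        "\n".join(
            f"{k + 1} {s.sequence[k]} {partner[k] + 1}"
            for k in range(len(s.sequence))
        )
        + "\n"
    )


# ---------------------------------------------------------------------------
# dispatch + FASTA helpers

_WRITERS = {"dotbracket": _to_dotbracket, "ct": _to_ct, "bpseq": _to_bpseq}
_PARSERS = {"dotbracket": parse_dotbracket, "ct": parse_ct, "bpseq": parse_bpseq}


def write_structure(structure: SecondaryStructure, format: str) -> str:
    """Serialize a structure to ``dotbracket``, ``ct``, or ``bpseq`` text."""
    try:
        writer = _WRITERS[format]
    except KeyError:
        raise ValueError(f"unknown structure format {format!r}") from None
    return writer(structure)


def parse_structure(text: str, format: str) -> SecondaryStructure:
    try:
        parser = _PARSERS[format]
    except KeyError:
        raise ValueError(f"unknown structure format {format!r}") from None
    return parser(text)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (name, normalized RNA sequence) tuples."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, _normalize_sequence(str(rec.seq), context=rec.id)))
    return records


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_dotbracket_file(path) -> list[SecondaryStructure]:
    """Read a multi-record dot-bracket file (``>name`` / seq / brackets)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    records: list[SecondaryStructure] = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureParseError(
                f"expected '>' header at line {i + 1} of {path}"
            )
        chunk = "\n".join(lines[i : i + 3])
        records.append(parse_dotbracket(chunk))
        i += 3
    return records


def write_dotbracket_file(path, structures: Iterable[SecondaryStructure]) -> None:
    with open(path, "w") as fh:
        for k, s in enumerate(structures):
            name = s.name or f"rna_{k}"
            fh.write(_to_dotbracket(SecondaryStructure(s.sequence, s.pairs, name)))
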