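"""Parsing and validation of RNA secondary-structure formats.

Supported inputs: dot-bracket (extended bracket alphabet, pseudoknots
allowed), CT, BPSEQ, and the lowercase characteristic-sequence dialect
in which ``a, g, c, u`` mark bases located inside base pairs.

Positions are 1-based throughout; conversion from file formats happens
only inside the parsers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

BASES = frozenset("ACGU")
CANONICAL_PAIRS = frozenset({frozenset("AU"), frozenset("GC"), frozenset("GU")})

#: opening bracket -> closing bracket, for every supported family
BRACKET_PAIRS = {"(": ")", "[": "]", "{": "}", "<": ">"}
BRACKET_PAIRS.update({chr(c): chr(c + 32) for c in range(ord("A"), ord("Z") + 1)})
_CLOSING = {v: k for k, v in BRACKET_PAIRS.items()}


class StructureFormatError(ValueError):
    """Raised when an input file cannot be parsed into a valid structure."""


class NonCanonicalPairError(StructureFormatError):
    """Raised in strict mode for pairs other than A-U, G-C, G-U."""


class NonCanonicalPairWarning(UserWarning):
    pass


def _normalize_sequence(seq: str, *, what: str = "sequence") -> str:
    norm = seq.upper().replace("T", "U")
    for pos, ch in enumerate(norm, start=1):
        if ch not in BASES:
            raise StructureFormatError(f"illegal {what} character {seq[pos - 1]!r} at position {pos}")
    return norm


@dataclass(frozen=True)
class SecondaryStructure:
    """A primary sequence plus a set of base pairs.

    ``pairs`` holds 1-based ``(i, j)`` tuples with ``i < j``; each
    position may occur in at most one pair. Crossing pairs (pseudoknots)
    are permitted.
    """

    name: str
    sequence: str
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n < 1:
            raise StructureFormatError("empty sequence")
        object.__setattr__(self, "sequence", _normalize_sequence(self.sequence))
        canon = set()
        seen: set[int] = set()
        for pair in self.pairs:
            i, j = sorted(pair)
            if not (1 <= i < j <= n):
                raise StructureFormatError(f"pair ({i}, {j}) out of range for length {n}")
            for p in (i, j):
                if p in seen:
                    raise StructureFormatError(f"position {p} occurs in more than one pair")
                seen.add(p)
            canon.add((i, j))
        object.__setattr__(self, "pairs", frozenset(canon))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def paired_positions(self) -> frozenset[int]:
        return frozenset(p for pair in self.pairs for p in pair)

    def is_pseudoknotted(self) -> bool:
        """True if some two pairs (i,j), (k,l) cross: i < k < j < l."""
        ordered = sorted(self.pairs)
        for a, (i, j) in enumerate(ordered):
            for k, l in ordered[a + 1 :]:
                if i < k < j < l:
                    return True
        return False


@dataclass(frozen=True)
class CharacteristicSequence:
    """Ordered symbols over {A, G, C, U, A', G', C', U'}.

    A primed symbol marks a base located inside a base pair. The
    lowercase dialect (``a`` for ``A'`` …) is used for text I/O.
    """

    name: str
    symbols: tuple[str, ...]

    _VALID = frozenset({b for b in BASES} | {b + "'" for b in BASES})

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise StructureFormatError("empty characteristic sequence")
        for i, s in enumerate(self.symbols, start=1):
            if s not in self._VALID:
                raise StructureFormatError(f"invalid symbol {s!r} at position {i}")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n(self) -> int:
        return len(self.symbols)

    def primed(self, i: int) -> bool:
        """Whether the 1-based position ``i`` is paired (primed)."""
        return self.symbols[i - 1].endswith("'")

    def base(self, i: int) -> str:
        """Unprimed base letter at 1-based position ``i``."""
        return self.symbols[i - 1][0]

    def unprimed_sequence(self) -> str:
        return "".join(s[0] for s in self.symbols)

    @property
    def dialect(self) -> str:
        """Lowercase-dialect text: primed symbols rendered lowercase."""
        return "".join(s[0].lower() if s.endswith("'") else s for s in self.symbols)

    @classmethod
    def from_dialect(cls, text: str, name: str = "") -> "CharacteristicSequence":
        symbols = []
        for pos, ch in enumerate(text, start=1):
            if ch in "ACGU":
                symbols.append(ch)
            elif ch in "acgu":
                symbols.append(ch.upper() + "'")
            else:
                raise StructureFormatError(f"illegal characteristic-sequence character {ch!r} at position {pos}")
        return cls(name=name, symbols=tuple(symbols))


# ---------------------------------------------------------------------------
# dot-bracket


def _match_brackets(struct: str) -> frozenset[tuple[int, int]]:
    stacks: dict[str, list[int]] = {}
    pairs = set()
    for pos, ch in enumerate(struct, start=1):
        if ch == ".":
            continue
        if ch in BRACKET_PAIRS:
            stacks.setdefault(ch, []).append(pos)
        elif ch in _CLOSING:
            opener = _CLOSING[ch]
            stack = stacks.get(opener, [])
            if not stack:
                raise StructureFormatError(f"unbalanced bracket {ch!r} at position {pos}: no matching {opener!r}")
            pairs.add((stack.pop(), pos))
        else:
            raise StructureFormatError(f"illegal structure character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise StructureFormatError(f"unbalanced bracket {opener!r} at position {stack[-1]}: never closed")
    return frozenset(pairs)


def iter_dot_bracket(text: str) -> Iterator[SecondaryStructure]:
    """Yield records from dot-bracket text.

    A record is an optional ``>``/``;`` header line, one sequence line,
    and one structure line of equal length.
    """
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln]
    i = 0
    count = 0
    while i < len(lines):
        name = ""
        if lines[i].startswith((">", ";")):
            name = lines[i][1:].strip()
            i += 1
        if i + 1 >= len(lines):
            raise StructureFormatError("truncated record: expected sequence and structure lines")
        seq_line, struct_line = lines[i], lines[i + 1]
        i += 2
        if len(seq_line) != len(struct_line):
            raise StructureFormatError(
                f"length mismatch: sequence has {len(seq_line)} characters, structure has {len(struct_line)}"
            )
        count += 1
        yield SecondaryStructure(
            name=name or f"record{count}",
            sequence=seq_line,
            pairs=_match_brackets(struct_line),
        )


def parse_dot_bracket(text: str) -> SecondaryStructure:
    """Parse a single dot-bracket record (the first one in ``text``)."""
    for record in iter_dot_bracket(text):
        return record
    raise StructureFormatError("no dot-bracket record found")


# ---------------------------------------------------------------------------
# CT (Zuker connect format)


def iter_ct(text: str) -> Iterator[SecondaryStructure]:
    lines = [ln for ln in (raw.strip() for raw in text.splitlines()) if ln and not ln.startswith("#")]
    i = 0
    count = 0
    while i < len(lines):
        header = lines[i].split()
        try:
            n = int(header[0])
        except (ValueError, IndexError):
            raise StructureFormatError(f"CT header must start with the record length: {lines[i]!r}") from None
        name = " ".join(header[1:]) if len(header) > 1 else ""
        i += 1
        rows = lines[i : i + n]
        if len(rows) != n:
            raise StructureFormatError(f"CT record declares {n} rows but {len(rows)} remain")
        i += n
        seq_chars = []
        pair_col: dict[int, int] = {}
        for k, row in enumerate(rows, start=1):
            fields = row.split()
            if len(fields) < 6:
                raise StructureFormatError(f"CT row {k} has {len(fields)} columns, expected 6")
            idx = int(fields[0])
            if idx != k:
                raise StructureFormatError(f"CT row {k} has index {idx}, expected {k}")
            seq_chars.append(fields[1])
            pair_col[k] = int(fields[4])
        pairs = _pairs_from_column(pair_col, n, fmt="CT")
        count += 1
        yield SecondaryStructure(name=name or f"record{count}", sequence="".join(seq_chars), pairs=pairs)


def parse_ct(text: str) -> SecondaryStructure:
    """Parse a single CT record (the first one in ``text``)."""
    for record in iter_ct(text):
        return record
    raise StructureFormatError("no CT record found")


def _pairs_from_column(pair_col: dict[int, int], n: int, *, fmt: str) -> frozenset[tuple[int, int]]:
    pairs = set()
    for i, j in pair_col.items():
        if j == 0:
            continue
        if not (1 <= j <= n):
            raise StructureFormatError(f"{fmt} row {i}: partner {j} out of range 1..{n}")
        if j == i:
            raise StructureFormatError(f"{fmt} row {i}: base paired with itself")
        if pair_col.get(j) != i:
            raise StructureFormatError(f"{fmt}: non-reciprocal pair — row {i} says {j} but row {j} says {pair_col.get(j)}")
        if i < j:
            pairs.add((i, j))
    return frozenset(pairs)


# ---------------------------------------------------------------------------
# BPSEQ


def iter_bpseq(text: str) -> Iterator[SecondaryStructure]:
    """Yield records from BPSEQ text; blank lines or ``>`` headers separate records."""
    blocks: list[tuple[str, list[str]]] = []
    name = ""
    current: list[str] = []
    for raw in text.splitlines():
        ln = raw.strip()
        if not ln or ln.startswith("#"):
            if not ln and current:
                blocks.append((name, current))
                name, current = "", []
            continue
        if ln.startswith(">"):
            if current:
                blocks.append((name, current))
                current = []
            name = ln[1:].strip()
            continue
        current.append(ln)
    if current:
        blocks.append((name, current))

    for count, (blk_name, rows) in enumerate(blocks, start=1):
        n = len(rows)
        seq_chars = [""] * n
        pair_col: dict[int, int] = {}
        for row in rows:
            fields = row.split()
            if len(fields) != 3:
                raise StructureFormatError(f"BPSEQ line must have 3 columns: {row!r}")
            idx, base, partner = int(fields[0]), fields[1], int(fields[2])
            if not (1 <= idx <= n):
                raise StructureFormatError(f"BPSEQ index {idx} outside 1..{n}: gap in index column")
            if idx in pair_col:
                raise StructureFormatError(f"duplicate BPSEQ index {idx}")
            seq_chars[idx - 1] = base
            pair_col[idx] = partner
        if len(pair_col) != n:
            raise StructureFormatError("gap in BPSEQ index column")
        pairs = _pairs_from_column(pair_col, n, fmt="BPSEQ")
        yield SecondaryStructure(name=blk_name or f"record{count}", sequence="".join(seq_chars), pairs=pairs)


def parse_bpseq(text: str) -> SecondaryStructure:
    """Parse a single BPSEQ record (the first one in ``text``)."""
    for record in iter_bpseq(text):
        return record
    raise StructureFormatError("no BPSEQ record found")


# ---------------------------------------------------------------------------
# encoding


def encode(structure: SecondaryStructure, strict_pairs: bool = False) -> CharacteristicSequence:
    """Prime every paired base of ``structure``.

    With ``strict_pairs`` any pair other than A-U, G-C, G-U raises
    :class:`NonCanonicalPairError`; otherwise a warning is recorded and
    the bases are primed regardless (the encoding needs only the
    paired/unpaired status).
    """
    seq = structure.sequence
    for i, j in sorted(structure.pairs):
        duo = frozenset((seq[i - 1], seq[j - 1]))
        if duo not in CANONICAL_PAIRS:
            msg = f"non-canonical pair {seq[i - 1]}-{seq[j - 1]} at ({i}, {j})"
            if strict_pairs:
                raise NonCanonicalPairError(msg)
            warnings.warn(msg, NonCanonicalPairWarning, stacklevel=2)
    paired = structure.paired_positions
    symbols = tuple(ch + "'" if pos in paired else ch for pos, ch in enumerate(seq, start=1))
    return CharacteristicSequence(name=structure.name, symbols=symbols)


# ---------------------------------------------------------------------------
# characteristic-sequence dialect I/O


def iter_characteristic(text: str) -> Iterator[CharacteristicSequence]:
    """Yield characteristic sequences from text.

    Accepts FASTA-like records (``>name`` headers, wrapped sequence
    lines) or one bare record per line.
    """
    lines = [ln for ln in (raw.strip() for raw in text.splitlines()) if ln]
    if any(ln.startswith(">") for ln in lines):
        name, chunks = None, []
        count = 0
        for ln in lines:
            if ln.startswith(">"):
                if name is not None:
                    count += 1
                    yield CharacteristicSequence.from_dialect("".join(chunks), name or f"record{count}")
                name, chunks = ln[1:].strip(), []
            else:
                if name is None:
                    raise StructureFormatError("sequence data before the first FASTA header")
                chunks.append(ln)
        if name is not None:
            count += 1
            yield CharacteristicSequence.from_dialect("".join(chunks), name or f"record{count}")
    else:
        for count, ln in enumerate(lines, start=1):
            yield CharacteristicSequence.from_dialect(ln, f"record{count}")


def parse_characteristic(text: str, name: str = "") -> CharacteristicSequence:
    """Parse a single characteristic sequence from dialect text."""
    records = list(iter_characteristic(text))
    if not records:
        raise StructureFormatError("no characteristic sequence found")
    record = records[0]
    return CharacteristicSequence(name=name or record.name, symbols=record.symbols)


def write_characteristic(cs: CharacteristicSequence, with_header: bool = False) -> str:
    """Render ``cs`` in the lowercase dialect; inverse of ``parse_characteristic``."""
    if with_header:
        return f">{cs.name}\n{cs.dialect}\n"
    return cs.dialect
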