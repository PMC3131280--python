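"""Sequence, coordinate and structure-file handling shared by all stages.

Leaders are handled as RNA (``U``); ``T`` is accepted on input and converted.
Positions are 1-based throughout. A leader may carry an *anchor*: the 1-based
index of the ``A`` of the downstream uORF AUG, which enables the negative
coordinate notation common in the uORF literature (-1 is the nucleotide
immediately 5' of the AUG; -k is the k-th nucleotide upstream of it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

ALPHABET = "ACGU"

__all__ = [
    "RnaSequence",
    "SecondaryStructure",
    "read_fasta",
    "write_fasta",
    "neg_to_index",
    "index_to_neg",
    "composition",
    "composition_percent",
    "parse_dotbracket",
    "write_dotbracket",
    "read_dotbracket",
    "write_ct",
    "read_ct",
]


class SeqFormatError(ValueError):
    """Raised for malformed sequence, coordinate or structure-file input."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence with an optional AUG anchor.

    Parameters
    ----------
    id:
        Text label.
    residues:
        Bases over ``{A, C, G, U}``. ``T`` is converted to ``U`` and case is
        normalised; IUPAC ambiguity codes are rejected (folding energies are
        undefined for them).
    anchor_index:
        1-based index of the A of the downstream uORF AUG, or ``None``.
        ``length + 1`` means the AUG begins immediately after the sequence
        (the common case for leader-only FASTA records).
    """

    id: str
    residues: str
    anchor_index: int | None = None

    def __post_init__(self) -> None:
        res = self.residues.upper().replace("T", "U")
        object.__setattr__(self, "residues", res)
        if not res:
            raise SeqFormatError(f"sequence {self.id!r} is empty")
        bad = sorted(set(res) - set(ALPHABET))
        if bad:
            raise SeqFormatError(
                f"sequence {self.id!r} contains non-ACGU character(s) "
                f"{', '.join(bad)} (ambiguity codes are not accepted)"
            )
        if self.anchor_index is not None and not (
            1 <= self.anchor_index <= len(res) + 1
        ):
            raise SeqFormatError(
                f"anchor_index {self.anchor_index} outside [1, {len(res) + 1}] "
                f"for sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, i: int) -> str:
        """1-based residue access."""
        if not 1 <= i <= len(self):
            raise IndexError(f"position {i} outside [1, {len(self)}]")
        return self.residues[i - 1]

    def subsequence(self, start: int, end: int, id: str | None = None) -> "RnaSequence":
        """Closed-interval 1-based slice. The anchor is dropped (it refers to
        the full-leader coordinate system, not to the slice)."""
        if not (1 <= start <= end <= len(self)):
            raise SeqFormatError(f"interval ({start}, {end}) outside [1, {len(self)}]")
        return RnaSequence(
            id=id or f"{self.id}:{start}-{end}",
            residues=self.residues[start - 1 : end],
        )


def neg_to_index(k: int, seq: RnaSequence) -> int:
    """Map a negative (AUG-relative) coordinate to a 1-based index.

    ``-1`` abuts the AUG, so ``index = anchor_index + k``.
    """
    if seq.anchor_index is None:
        raise SeqFormatError(f"sequence {seq.id!r} has no AUG anchor")
    if k > -1:
        raise SeqFormatError(f"negative coordinate expected, got {k}")
    idx = seq.anchor_index + k
    if not 1 <= idx <= len(seq):
        raise SeqFormatError(
            f"coordinate {k} maps to index {idx}, outside [1, {len(seq)}]"
        )
    return idx


def index_to_neg(i: int, seq: RnaSequence) -> int:
    """Inverse of :func:`neg_to_index`."""
    if seq.anchor_index is None:
        raise SeqFormatError(f"sequence {seq.id!r} has no AUG anchor")
    if not 1 <= i <= len(seq):
        raise SeqFormatError(f"index {i} outside [1, {len(seq)}]")
    return i - seq.anchor_index


def composition(seq: RnaSequence) -> dict[str, float]:
    """Exact base fractions (sum to 1 before any rounding)."""
    n = len(seq)
    return {b: seq.residues.count(b) / n for b in ALPHABET}


def composition_percent(seq: RnaSequence) -> dict[str, int]:
    """Base composition rounded to integer percent (as reported in the field)."""
    return {b: round(100 * f) for b, f in composition(seq).items()}


# ---------------------------------------------------------------------------
# FASTA

def _parse_anchor(description: str) -> int | None:
    for token in description.split():
        if token.startswith("anchor="):
            try:
                return int(token[len("anchor="):])
            except ValueError as exc:
                raise SeqFormatError(f"malformed anchor token {token!r}") from exc
    return None


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a (multi-record) FASTA file of leaders.

    An ``anchor=<int>`` token in the header sets
    :attr:`RnaSequence.anchor_index`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqFormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        out.append(
            RnaSequence(
                id=rec.id,
                residues=str(rec.seq),
                anchor_index=_parse_anchor(rec.description),
            )
        )
    return out


def write_fasta(path: str | Path, seqs: Iterable[RnaSequence]) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id}"
            if s.anchor_index is not None:
                header += f" anchor={s.anchor_index}"
            fh.write(header + "\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Secondary structure

@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free pairing of a sequence.

    ``pairs`` is a frozenset of 1-based ``(i, j)`` tuples with ``i < j``; each
    index occurs in at most one pair, pairs nest (no crossings), and every
    hairpin loop encloses at least ``min_hairpin`` unpaired nucleotides.
    """

    length: int
    pairs: frozenset[tuple[int, int]]
    energy: float | None = None
    min_hairpin: int = 3

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SeqFormatError("structure length must be >= 1")
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        seen: set[int] = set()
        for i, j in pairs:
            if not (1 <= i < j <= self.length):
                raise SeqFormatError(f"pair ({i}, {j}) outside structure of length {self.length}")
            if j - i < self.min_hairpin + 1:
                raise SeqFormatError(
                    f"pair ({i}, {j}) closes a hairpin loop shorter than "
                    f"{self.min_hairpin} nt"
                )
            if i in seen or j in seen:
                raise SeqFormatError(f"position in pair ({i}, {j}) is paired twice")
            seen.update((i, j))
        ordered = sorted(pairs)
        for a in range(len(ordered)):
            i1, j1 = ordered[a]
            for b in range(a + 1, len(ordered)):
                i2, j2 = ordered[b]
                if i2 > j1:
                    break
                if i1 < i2 < j1 < j2:
                    raise SeqFormatError(
                        f"pairs ({i1}, {j1}) and ({i2}, {j2}) cross (pseudoknot)"
                    )

    @property
    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    @property
    def pair_table(self) -> dict[int, int]:
        """Symmetric partner lookup: ``pair_table[i] == j`` and vice versa."""
        table: dict[int, int] = {}
        for i, j in self.pairs:
            table[i] = j
            table[j] = i
        return table

    def is_paired(self, i: int) -> bool:
        return i in self.pair_table

    def with_energy(self, energy: float) -> "SecondaryStructure":
        return SecondaryStructure(self.length, self.pairs, energy, self.min_hairpin)


def parse_dotbracket(
    text: str, energy: float | None = None, min_hairpin: int = 3
) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`."""
    stack: list[int] = []
    pairs = set()
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise SeqFormatError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise SeqFormatError(f"unexpected character {ch!r} at position {pos}")
    if stack:
        raise SeqFormatError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(len(text), frozenset(pairs), energy, min_hairpin)


def write_dotbracket(
    path: str | Path, seq: RnaSequence, structure: SecondaryStructure
) -> None:
    """Write a Vienna-style file: ``>id``, sequence line, structure line."""
    if structure.length != len(seq):
        raise SeqFormatError("structure length does not match sequence length")
    with open(path, "w") as fh:
        fh.write(f">{seq.id}\n{seq.residues}\n{structure.dot_bracket}")
        if structure.energy is not None:
            fh.write(f" ({structure.energy:.2f})")
        fh.write("\n")


def read_dotbracket(path: str | Path) -> tuple[RnaSequence, SecondaryStructure]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise SeqFormatError(f"{path}: expected sequence and structure lines")
    if lines[0].startswith(">"):
        name, lines = lines[0][1:].split()[0] if len(lines[0]) > 1 else "seq", lines[1:]
    else:
        name = "seq"
    if len(lines) < 2:
        raise SeqFormatError(f"{path}: expected sequence and structure lines")
    seq = RnaSequence(id=name, residues=lines[0])
    db = lines[1].split()[0]
    energy = None
    rest = lines[1][len(db):].strip()
    if rest.startswith("(") and rest.endswith(")"):
        try:
            energy = float(rest[1:-1])
        except ValueError:
            energy = None
    if len(db) != len(seq):
        raise SeqFormatError(f"{path}: structure and sequence lengths differ")
    return seq, parse_dotbracket(db, energy=energy)


def write_ct(path: str | Path, seq: RnaSequence, structure: SecondaryStructure) -> None:
    """Write a standard 6-column connectivity table."""
    if structure.length != len(seq):
        raise SeqFormatError("structure length does not match sequence length")
    table = structure.pair_table
    n = len(seq)
    with open(path, "w") as fh:
        energy = structure.energy
        header = f"{n} {seq.id}"
        if energy is not None:
            header = f"{n} ENERGY = {energy:.2f} {seq.id}"
        fh.write(header + "\n")
        for i in range(1, n + 1):
            fh.write(
                f"{i} {seq.base(i)} {i - 1} {(i + 1) if i < n else 0} "
                f"{table.get(i, 0)} {i}\n"
            )


def read_ct(path: str | Path) -> tuple[RnaSequence, SecondaryStructure]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise SeqFormatError(f"{path}: empty CT file")
    head = lines[0].split()
    try:
        n = int(head[0])
    except (IndexError, ValueError) as exc:
        raise SeqFormatError(f"{path}: malformed CT header") from exc
    energy = None
    if "ENERGY" in lines[0].upper():
        for tok in head:
            try:
                energy = float(tok)
            except ValueError:
                continue
            if tok != head[0]:
                break
    name = head[-1] if len(head) > 1 else "seq"
    if len(lines) - 1 != n:
        raise SeqFormatError(f"{path}: header says {n} rows, found {len(lines) - 1}")
    residues = []
    pairs = set()
    partner_of = {}
    for ln in lines[1:]:
        cols = ln.split()
        if len(cols) < 6:
            raise SeqFormatError(f"{path}: CT row has fewer than 6 columns: {ln!r}")
        idx, base, partner = int(cols[0]), cols[1], int(cols[4])
        if idx != len(residues) + 1:
            raise SeqFormatError(f"{path}: CT rows out of order at index {idx}")
        residues.append(base)
        if partner:
            if not 1 <= partner <= n:
                raise SeqFormatError(f"{path}: partner {partner} out of range")
            partner_of[idx] = partner
    for i, j in partner_of.items():
        if partner_of.get(j) != i:
            raise SeqFormatError(
                f"{path}: inconsistent pairing at index {i} (partner {j})"
            )
        if i < j:
            pairs.add((i, j))
    seq = RnaSequence(id=name, residues="".join(residues))
    return seq, SecondaryStructure(n, frozenset(pairs), energy)
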