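"""Multiple sequence alignments and column-wise alanine substitution.

The mutation unit of the search is an MSA column: setting a bit substitutes
every aligned homolog residue in the corresponding match column with alanine,
disrupting the coevolutionary signal AlphaFold2 reads from that position while
leaving the query sequence itself untouched.

Two dialects are supported:

* ``a3m`` — uppercase letters and ``-`` define match columns; lowercase
  letters are unaligned insertions and carry no column index.
* ``fasta`` — plain aligned FASTA where every character occupies a column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "MSA",
    "MutationMask",
    "MalformedAlignmentError",
    "read_msa",
    "write_msa",
    "residues_to_columns",
    "apply_alanine_mask",
]

Dialect = Literal["a3m", "fasta"]

GAP = "-"


class MalformedAlignmentError(ValueError):
    """Rows disagree on match-column count, or the file is empty/unusable."""


def _match_length(seq: str) -> int:
    """Number of match states: uppercase letters and gaps; lowercase are inserts."""
    return sum(1 for c in seq if c == GAP or (c.isalpha() and c.isupper()))


@dataclass
class MSA:
    """An alignment whose first row is the query.

    ``rows`` holds ``(sequence_id, aligned_sequence)`` pairs in file order.
    Match columns are indexed 1-based over uppercase/gap characters only;
    A3M lowercase insertions occupy no column.
    """

    rows: list[tuple[str, str]]
    dialect: Dialect = "a3m"

    def __post_init__(self) -> None:
        if not self.rows:
            raise MalformedAlignmentError("empty alignment: no rows")
        n = _match_length(self.rows[0][1])
        for rid, seq in self.rows:
            if _match_length(seq) != n:
                raise MalformedAlignmentError(
                    f"row {rid!r} has {_match_length(seq)} match columns, expected {n}"
                )

    @property
    def query_id(self) -> str:
        return self.rows[0][0]

    @property
    def query(self) -> str:
        return self.rows[0][1]

    @property
    def query_sequence(self) -> str:
        """Query residues with gaps and insertions removed."""
        return "".join(c for c in self.query if c.isalpha()).upper()

    @property
    def n_match_columns(self) -> int:
        return _match_length(self.query)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class MutationMask:
    """GA genome: one bit per binding-site candidate residue.

    ``residue_indices`` are 1-based query positions, strictly increasing;
    bit 1 means "substitute all homolog residues in this column with alanine".
    """

    residue_indices: list[int]
    bits: list[int]

    def __post_init__(self) -> None:
        if len(self.residue_indices) != len(self.bits):
            raise ValueError("residue_indices and bits must have equal length")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0/1")
        if any(i <= 0 for i in self.residue_indices):
            raise ValueError("residue indices are 1-based and positive")
        if any(a >= b for a, b in zip(self.residue_indices, self.residue_indices[1:])):
            raise ValueError("residue_indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.bits)

    def as_string(self) -> str:
        """Compact 0/1 string, index order — the log/trajectory encoding."""
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_string(cls, residue_indices: Sequence[int], s: str) -> "MutationMask":
        return cls(list(residue_indices), [int(c) for c in s])

    def to_table(self, path: str | Path) -> None:
        """Serialize as a two-column text file: residue_index<TAB>bit."""
        lines = [f"{i}\t{b}" for i, b in zip(self.residue_indices, self.bits)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "MutationMask":
        idx, bits = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, b = line.split()
            idx.append(int(i))
            bits.append(int(b))
        return cls(idx, bits)


def read_msa(path: str | Path, dialect: Dialect = "a3m") -> MSA:
    """Read an MSA; the first record is taken as the query.

    Raises :class:`MalformedAlignmentError` on an empty file or on rows with
    ragged match-column counts. Lowercase insertion states are preserved
    verbatim so a read→write round trip is byte-identical.
    """
    text = Path(path).read_text()
    rows: list[tuple[str, str]] = []
    rid: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):  # A3M header line (e.g. colabfold cardinality)
            continue
        if line.startswith(">"):
            if rid is not None:
                rows.append((rid, "".join(chunks)))
            rid = line[1:].strip()
            chunks = []
        elif line.strip():
            if rid is None:
                raise MalformedAlignmentError(f"{path}: sequence before first header")
            chunks.append(line.strip())
    if rid is not None:
        rows.append((rid, "".join(chunks)))
    if not rows:
        raise MalformedAlignmentError(f"{path}: empty alignment file")
    if dialect == "fasta":
        # plain aligned FASTA: every character is a column; normalise case
        width = len(rows[0][1])
        for r, seq in rows:
            if len(seq) != width:
                raise MalformedAlignmentError(
                    f"row {r!r} has length {len(seq)}, expected {width}"
                )
        rows = [(r, seq.upper()) for r, seq in rows]
    return MSA(rows=rows, dialect=dialect)


def write_msa(msa: MSA, path: str | Path) -> None:
    """Write in the MSA's own dialect (both serialise as FASTA-shaped text)."""
    out = []
    for rid, seq in msa.rows:
        out.append(f">{rid}")
        out.append(seq)
    Path(path).write_text("\n".join(out) + "\n")


def residues_to_columns(msa: MSA, residues: Iterable[int]) -> list[int]:
    """Map 1-based query residue positions to 1-based match-column indices.

    Columns where the query row carries a gap hold no query residue and are
    skipped in the numbering, so the mapping is injective.
    """
    col_of_residue: dict[int, int] = {}
    res = 0
    col = 0
    for c in msa.query:
        if c == GAP:
            col += 1
        elif c.isupper():
            col += 1
            res += 1
            col_of_residue[res] = col
        # lowercase insertion: no column, no match-state residue
    out = []
    for r in residues:
        if r not in col_of_residue:
            raise IndexError(
                f"residue {r} outside query match states (1..{res}, 1-based)"
            )
        out.append(col_of_residue[r])
    return out


def apply_alanine_mask(msa: MSA, mask: MutationMask, mutate_query: bool = False) -> MSA:
    """Substitute homolog residues with alanine in every bit-1 column.

    By default the query row is never mutated (the predicted model must keep
    the native sequence for docking); set ``mutate_query`` to include it.
    Gaps stay gaps and lowercase insertions are untouched since they occupy
    no match column. Idempotent by construction.
    """
    active_residues = [r for r, b in zip(mask.residue_indices, mask.bits) if b]
    target_cols = set(residues_to_columns(msa, active_residues))
    if not target_cols:
        return MSA(rows=list(msa.rows), dialect=msa.dialect)

    start = 0 if mutate_query else 1
    new_rows = list(msa.rows[:start])
    for rid, seq in msa.rows[start:]:
        col = 0
        chars = list(seq)
        for i, c in enumerate(chars):
            if c == GAP or (c.isalpha() and c.isupper()):
                col += 1
                if col in target_cols and c != GAP:
                    chars[i] = "A"
        new_rows.append((rid, "".join(chars)))
    return MSA(rows=new_rows, dialect=msa.dialect)
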