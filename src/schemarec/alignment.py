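"""Multiple sequence alignment handling for two-parent recombination design.

All coordinates are 1-based: alignment columns run 1..L and ungapped residue
indices run 1..n, matching the convention used when reporting recombination
sites as single alignment positions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment as _BioMSA
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
UNKNOWN = "X"
ALLOWED = AMINO_ACIDS | {GAP, UNKNOWN}


class AlignmentShapeError(ValueError):
    """Rows of an alignment do not share a common length."""


class AlignmentParseError(ValueError):
    """File could not be parsed into a valid alignment."""


class SequenceLookupError(KeyError):
    """Requested sequence id is absent from the alignment."""


@dataclass(frozen=True)
class AlignedSequence:
    """One gapped row of a multiple alignment.

    ``residues`` is an upper-case string over the 20 amino-acid letters,
    'X' for unknown residues, and '-' for gaps.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in ALLOWED:
                raise AlignmentParseError(
                    f"sequence {self.id!r}: unknown character {ch!r} at column {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


def _normalize(raw: str, seq_id: str) -> AlignedSequence:
    return AlignedSequence(seq_id, raw.upper().replace(".", GAP))


@dataclass(frozen=True)
class MultipleAlignment:
    """An ordered, rectangular set of aligned sequences."""

    sequences: tuple[AlignedSequence, ...]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise AlignmentShapeError("alignment needs at least 2 sequences")
        L = len(self.sequences[0])
        for seq in self.sequences:
            if len(seq) != L:
                raise AlignmentShapeError(
                    f"sequence {seq.id!r} has length {len(seq)}, expected {L}"
                )
        seen: set[str] = set()
        for seq in self.sequences:
            if seq.id in seen:
                raise AlignmentParseError(f"duplicate sequence id {seq.id!r}")
            seen.add(seq.id)
        for col in range(L):
            if all(s.residues[col] == GAP for s in self.sequences):
                raise AlignmentShapeError(f"column {col + 1} is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def __getitem__(self, seq_id: str) -> AlignedSequence:
        for seq in self.sequences:
            if seq.id == seq_id:
                return seq
        raise SequenceLookupError(f"sequence id {seq_id!r} not in alignment")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sequences)


@dataclass(frozen=True)
class ColumnMap:
    """Bijection between an aligned row's non-gap columns and residue indices.

    Both directions are 1-based; gap columns are absent from ``col_to_res``.
    """

    seq_id: str
    col_to_res: dict[int, int] = field(repr=False)
    res_to_col: dict[int, int] = field(repr=False)

    def column_of(self, res_index: int) -> int:
        return self.res_to_col[res_index]

    def residue_of(self, column: int) -> int:
        return self.col_to_res[column]

    @property
    def n_residues(self) -> int:
        return len(self.col_to_res)


def build_column_map(seq: AlignedSequence) -> ColumnMap:
    """Map alignment columns (1-based) to ungapped residue indices (1-based)."""
    col_to_res: dict[int, int] = {}
    res = 0
    for col, ch in enumerate(seq.residues, start=1):
        if ch != GAP:
            res += 1
            col_to_res[col] = res
    return ColumnMap(seq.id, col_to_res, {r: c for c, r in col_to_res.items()})


def columns_equal(a: str, b: str) -> bool:
    """Residue identity test used when comparing parents column-wise.

    Literal symbol equality: gap-versus-gap counts as equal, gap versus
    residue does not, and an unknown residue 'X' differs from every other
    symbol (conservatively breakable) while two 'X' tokens at the same
    column compare equal — this keeps a pure-parent chimera at exactly zero
    disruption regardless of unknowns.
    """
    return a == b


@dataclass(frozen=True)
class ParentPair:
    """The two parent rows of an alignment, with their agreeing columns."""

    parent_a: AlignedSequence
    parent_b: AlignedSequence

    def __post_init__(self) -> None:
        if len(self.parent_a) != len(self.parent_b):
            raise AlignmentShapeError("parents differ in aligned length")

    @property
    def n_columns(self) -> int:
        return len(self.parent_a)

    @property
    def identical_columns(self) -> frozenset[int]:
        return frozenset(
            c
            for c in range(1, self.n_columns + 1)
            if columns_equal(self.parent_a.residues[c - 1], self.parent_b.residues[c - 1])
        )

    @property
    def differing_columns(self) -> frozenset[int]:
        return frozenset(range(1, self.n_columns + 1)) - self.identical_columns


def extract_parents(msa: MultipleAlignment, id_a: str, id_b: str) -> ParentPair:
    """Pull the two parent rows out of an alignment."""
    return ParentPair(msa[id_a], msa[id_b])


_FORMATS = {"fasta": "fasta", "clustal": "clustal"}


def read_alignment(path, format: str = "fasta") -> MultipleAlignment:
    """Read an aligned FASTA or Clustal file.

    Lowercase letters are upper-cased and '.' is accepted as a gap alias.
    Ragged rows raise :class:`AlignmentShapeError` naming the offending id;
    unknown characters raise :class:`AlignmentParseError` with the column.
    """
    if format not in _FORMATS:
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        if format == "fasta":
            # Bio.AlignIO rejects ragged FASTA outright; parse records so we
            # can name the offending sequence instead.
            from Bio import SeqIO

            records = list(SeqIO.parse(str(path), "fasta"))
        else:
            records = list(next(AlignIO.parse(str(path), "clustal")))
    except AlignmentParseError:
        raise
    except Exception as exc:  # Biopython raises bare ValueError subclasses
        raise AlignmentParseError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records:
        raise AlignmentParseError(f"no sequences found in {path}")
    seqs = tuple(_normalize(str(r.seq), r.id) for r in records)
    return MultipleAlignment(seqs)


def write_alignment(msa: MultipleAlignment, path, format: str = "fasta") -> None:
    """Write an alignment back out (aligned FASTA or Clustal)."""
    if format not in _FORMATS:
        raise ValueError(f"unsupported alignment format {format!r}")
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in msa.sequences
    ]
    bio = _BioMSA(records)
    with open(path, "w") as fh:
        AlignIO.write(bio, fh, _FORMATS[format])


def alignment_to_string(msa: MultipleAlignment, format: str = "fasta") -> str:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in msa.sequences
    ]
    buf = io.StringIO()
    AlignIO.write(_BioMSA(records), buf, _FORMATS[format])
    return buf.getvalue()
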