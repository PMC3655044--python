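"""Materialize chimeric protein sequences from crossover schemes.

Each fragment copies the source parent's residues over the fragment's
alignment columns, drops gaps, and records where in the ungapped parent the
fragment came from. No tags or signal peptides are added or removed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import GAP, ParentPair
from .energy import CrossoverScheme

# Average residue masses (g/mol), free N/C termini add one water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153


def molecular_weight(sequence: str) -> float:
    """Average molecular mass of a peptide in g/mol (free termini)."""
    if not sequence:
        raise ValueError("empty sequence has no molecular weight")
    try:
        return sum(RESIDUE_MASS[ch] for ch in sequence) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in sequence") from exc


@dataclass(frozen=True)
class Fragment:
    source: str  # parent label 'A' or 'B'
    source_id: str
    residues: str  # ungapped
    source_span: tuple[int, int] | None  # 1-based residue span in the source parent

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ChimeraSequence:
    """An assembled hybrid protein with per-fragment provenance."""

    sequence: str
    fragments: tuple[Fragment, ...]
    scheme: CrossoverScheme

    def __post_init__(self) -> None:
        if "".join(f.residues for f in self.fragments) != self.sequence:
            raise ValueError("fragments do not concatenate to the sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def fragment_lengths(self) -> tuple[int, ...]:
        return tuple(len(f) for f in self.fragments)

    @property
    def provenance(self) -> str:
        """One source label per residue, e.g. 'AAABBBBAA'."""
        return "".join(f.source * len(f) for f in self.fragments)

    @property
    def molecular_weight(self) -> float:
        return molecular_weight(self.sequence)

    def description(self) -> str:
        xs = ",".join(str(x) for x in self.scheme.crossovers) or "none"
        frags = "+".join(str(n) for n in self.fragment_lengths)
        return (
            f"pattern={self.scheme.pattern} crossovers={xs} "
            f"fragment_lengths={frags} total={len(self)}"
        )


def build_chimera(pair: ParentPair, scheme: CrossoverScheme) -> ChimeraSequence:
    """Assemble the hybrid sequence for a crossover scheme.

    Fragment k spans alignment columns (x_{k-1}, x_k]; its residues are the
    source parent's non-gap characters over those columns.
    """
    L = pair.n_columns
    if scheme.crossovers and scheme.crossovers[-1] >= L:
        raise ValueError(
            f"crossover {scheme.crossovers[-1]} out of range for alignment length {L}"
        )
    bounds = (0,) + scheme.crossovers + (L,)
    parents = {"A": pair.parent_a, "B": pair.parent_b}
    # running ungapped residue counters per parent
    fragments: list[Fragment] = []
    for letter, lo, hi in zip(scheme.pattern, bounds, bounds[1:]):
        parent = parents[letter]
        before = sum(1 for c in range(lo) if parent.residues[c] != GAP)
        chunk = parent.residues[lo:hi].replace(GAP, "")
        span = (before + 1, before + len(chunk)) if chunk else None
        fragments.append(Fragment(letter, parent.id, chunk, span))
    sequence = "".join(f.residues for f in fragments)
    return ChimeraSequence(sequence, tuple(fragments), scheme)


def write_chimera_fasta(chimera: ChimeraSequence, path, name: str = "chimera") -> None:
    """FASTA record with provenance in the description line."""
    with open(path, "w") as fh:
        fh.write(f">{name} {chimera.description()}\n")
        seq = chimera.sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


def fragment_report_tsv(chimera: ChimeraSequence) -> str:
    lines = ["fragment\tsource\tsource_id\tlength\tsource_span"]
    for k, f in enumerate(chimera.fragments, start=1):
        span = f"{f.source_span[0]}-{f.source_span[1]}" if f.source_span else "empty"
        lines.append(f"{k}\t{f.source}\t{f.source_id}\t{len(f)}\t{span}")
    lines.append(f"total\t\t\t{len(chimera)}\t")
    return "\n".join(lines) + "\n"
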