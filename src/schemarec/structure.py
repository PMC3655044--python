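"""Structural template parsing and residue contact maps.

A contact map lists pairs of alignment columns whose residues have heavy
atoms within a distance cutoff in the template structure. The template must
be one row of the alignment; contacts found between residue indices in the
structure are lifted to alignment-column coordinates through that row's
column map.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.PDB.Polypeptide import protein_letters_3to1

from .alignment import AlignedSequence, build_column_map

# tables use e.g. "MSE" -> "M" for common modified residues; anything absent
# is masked to 'X'
_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}


class StructureParseError(ValueError):
    """PDB text could not be parsed into usable residues."""


class StructureMappingError(ValueError):
    """Structure sequence does not match the alignment template row."""


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int  # author residue number
    insertion_code: str
    one_letter: str
    coords: np.ndarray  # (n_heavy_atoms, 3), Angstroms

    def __post_init__(self) -> None:
        if self.coords.shape[0] < 1:
            raise StructureParseError(
                f"residue {self.chain}{self.number} has no heavy atoms"
            )


@dataclass(frozen=True)
class StructureResidues:
    """Ordered heavy-atom coordinates per residue for one chain, model 1."""

    residues: tuple[Residue, ...]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


def parse_structure(pdb_text: str, chain: str = "A", source_id: str = "") -> StructureResidues:
    """Extract one chain's residues from PDB text.

    First model only; for alternate locations the highest-occupancy atom is
    kept (ties resolved toward altloc 'A'); HETATM records, waters and
    hydrogens are dropped; nonstandard residue names map to 'X'.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            struct = parser.get_structure("template", io.StringIO(pdb_text))
        except Exception as exc:
            raise StructureParseError(f"malformed PDB text: {exc}") from exc
    models = list(struct)
    if not models:
        raise StructureParseError("no models in PDB text")
    model = models[0]
    if chain not in model:
        raise StructureParseError(f"chain {chain!r} absent or empty")
    residues: list[Residue] = []
    for res in model[chain]:
        hetflag = res.id[0]
        if hetflag != " ":  # HETATM (including waters)
            continue
        one = _THREE_TO_ONE.get(res.get_resname().strip().upper(), "X")
        coords = [
            atom.get_coord()
            for atom in res.get_atoms()  # DisorderedAtom yields highest occupancy
            if atom.element != "H"
        ]
        if not coords:
            continue
        residues.append(
            Residue(
                chain=chain,
                number=res.id[1],
                insertion_code=res.id[2].strip(),
                one_letter=one,
                coords=np.asarray(coords, dtype=float),
            )
        )
    if not residues:
        raise StructureParseError(f"chain {chain!r} has no polymer residues")
    return StructureResidues(tuple(residues), source_id=source_id)


def compute_contacts(
    struct: StructureResidues,
    cutoff_angstrom: float = 4.5,
    min_separation: int = 2,
) -> set[tuple[int, int]]:
    """Residue-index pairs (1-based, p < q) in heavy-atom contact.

    A pair is a contact when the minimum distance over all heavy-atom pairs
    is <= ``cutoff_angstrom`` and the ordinal separation |p - q| is at least
    ``min_separation``. Separation uses the ordinal index within the chain,
    not author numbering, so chains with missing residues stay well-defined.
    """
    if cutoff_angstrom <= 0:
        raise ValueError("cutoff must be positive")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    n = len(struct)
    contacts: set[tuple[int, int]] = set()
    coords = [r.coords for r in struct.residues]
    cut2 = cutoff_angstrom**2
    for p in range(n):
        for q in range(p + min_separation, n):
            d2 = np.sum((coords[p][:, None, :] - coords[q][None, :, :]) ** 2, axis=-1)
            if d2.min() <= cut2:
                contacts.add((p + 1, q + 1))
    return contacts


def min_residue_distance(struct: StructureResidues, p: int, q: int) -> float:
    """Minimum heavy-atom distance between residues p and q (1-based)."""
    a = struct.residues[p - 1].coords
    b = struct.residues[q - 1].coords
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min()))


@dataclass(frozen=True)
class ContactMap:
    """Unordered alignment-column contact pairs plus provenance."""

    contacts: frozenset[frozenset[int]]
    cutoff: float
    min_separation: int
    template_id: str
    n_structure_contacts: int

    def __post_init__(self) -> None:
        for pair in self.contacts:
            if len(pair) != 2:
                raise ValueError(f"contact {set(pair)} is not a pair of distinct columns")

    def __len__(self) -> int:
        return len(self.contacts)

    def as_sorted_tuples(self) -> list[tuple[int, int]]:
        return sorted((min(p), max(p)) for p in self.contacts)


def contact_map_from_pairs(
    pairs,
    cutoff: float = float("nan"),
    min_separation: int = 2,
    template_id: str = "synthetic",
) -> ContactMap:
    """Build a ContactMap directly from column pairs (synthetic fixtures)."""
    fs = frozenset(frozenset(p) for p in pairs)
    return ContactMap(fs, cutoff, min_separation, template_id, len(fs))


def lift_contacts(
    struct_contacts: set[tuple[int, int]],
    template_row: AlignedSequence,
    struct: StructureResidues,
    cutoff: float = 4.5,
    min_separation: int = 2,
) -> ContactMap:
    """Translate residue-index contacts into alignment-column pairs.

    Requires exact identity between the structure's one-letter sequence and
    the ungapped template row ('X' positions compare equal to anything, so a
    masked nonstandard residue does not break the correspondence).
    """
    ungapped = template_row.ungapped
    sseq = struct.sequence
    if len(ungapped) != len(sseq):
        raise StructureMappingError(
            f"structure has {len(sseq)} residues but template row "
            f"{template_row.id!r} has {len(ungapped)}"
        )
    for i, (a, b) in enumerate(zip(sseq, ungapped), start=1):
        if a != b and a != "X" and b != "X":
            raise StructureMappingError(
                f"sequence mismatch at residue {i}: structure {a!r} vs alignment {b!r}"
            )
    cmap = build_column_map(template_row)
    pairs = frozenset(
        frozenset((cmap.column_of(p), cmap.column_of(q))) for p, q in struct_contacts
    )
    if len(pairs) != len(struct_contacts):
        raise StructureMappingError("contact pairs collapsed during lifting")
    return ContactMap(
        contacts=pairs,
        cutoff=cutoff,
        min_separation=min_separation,
        template_id=template_row.id,
        n_structure_contacts=len(struct_contacts),
    )


def project_contacts(cmap_obj: ContactMap, template_row: AlignedSequence) -> set[tuple[int, int]]:
    """Inverse of :func:`lift_contacts`: column pairs back to residue indices."""
    colmap = build_column_map(template_row)
    out = set()
    for pair in cmap_obj.contacts:
        i, j = sorted(pair)
        out.add(tuple(sorted((colmap.residue_of(i), colmap.residue_of(j)))))
    return out


def contacts_to_tsv(cmap_obj: ContactMap, struct: StructureResidues | None,
                    template_row: AlignedSequence | None) -> str:
    """Long-form TSV (col_i, col_j, min_distance) for inspection."""
    lines = ["col_i\tcol_j\tmin_distance"]
    colmap = build_column_map(template_row) if template_row is not None else None
    for i, j in cmap_obj.as_sorted_tuples():
        if struct is not None and colmap is not None:
            d = min_residue_distance(struct, colmap.residue_of(i), colmap.residue_of(j))
            lines.append(f"{i}\t{j}\t{d:.3f}")
        else:
            lines.append(f"{i}\t{j}\tNA")
    return "\n".join(lines) + "\n"
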