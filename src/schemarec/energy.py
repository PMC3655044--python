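"""SCHEMA disruption energy for two-parent chimeras.

The disruption energy E of a chimera is the number of template contacts
{i, j} whose residue pair in the chimera occurs in neither parent. It is an
integer count of perturbed structural contacts, not a physical energy: the
lower E, the more native contacts the hybrid can retain.

For exactly two parents the definition reduces to a fast test: a contact is
disrupted iff its endpoints are sourced from different parents AND both
endpoint columns differ between the parents. ``disruption_energy`` uses that
reduction; ``oracle_energy`` materializes the chimeric sequence and applies
the literal pair-membership definition, serving as the independent check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import GAP, ParentPair, columns_equal
from .structure import ContactMap


@dataclass(frozen=True)
class CrossoverScheme:
    """A parent-assignment pattern plus the crossover columns realizing it.

    ``pattern`` is a string over {A, B}, one letter per fragment; adjacent
    letters must differ. ``crossovers`` lists alignment columns x1 < x2 < ...
    where each x is the LAST column of the preceding fragment, so fragment k
    spans columns (x_{k-1}, x_k] with x_0 = 0 and x_last = L.
    """

    pattern: str
    crossovers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - {"A", "B"}:
            raise ValueError(f"pattern must be non-empty over {{A,B}}: {self.pattern!r}")
        for a, b in zip(self.pattern, self.pattern[1:]):
            if a == b:
                raise ValueError(f"adjacent pattern letters equal in {self.pattern!r}")
        xs = tuple(self.crossovers)
        if len(xs) != len(self.pattern) - 1:
            raise ValueError(
                f"pattern {self.pattern!r} needs {len(self.pattern) - 1} crossovers, got {len(xs)}"
            )
        if any(x < 1 for x in xs):
            raise ValueError("crossover columns must be >= 1")
        if any(x2 <= x1 for x1, x2 in zip(xs, xs[1:])):
            raise ValueError(f"crossovers must be strictly increasing: {xs}")
        object.__setattr__(self, "crossovers", xs)

    def complement(self) -> "CrossoverScheme":
        swapped = self.pattern.translate(str.maketrans("AB", "BA"))
        return CrossoverScheme(swapped, self.crossovers)


def assign_columns(scheme: CrossoverScheme, L: int) -> np.ndarray:
    """Per-column parent label, as an array of 'A'/'B' of length L (0-indexed
    array position c-1 holds the label of column c)."""
    if scheme.crossovers and scheme.crossovers[-1] >= L:
        raise ValueError(
            f"crossover {scheme.crossovers[-1]} must be < alignment length {L}"
        )
    labels = np.empty(L, dtype="<U1")
    bounds = (0,) + scheme.crossovers + (L,)
    for letter, lo, hi in zip(scheme.pattern, bounds, bounds[1:]):
        labels[lo:hi] = letter
    return labels


def differing_columns_mask(pair: ParentPair) -> np.ndarray:
    """Boolean mask (index c-1 for column c): parents differ at the column.

    Gap-vs-gap is equal; gap-vs-residue differs; 'X' differs from everything.
    """
    a = pair.parent_a.residues
    b = pair.parent_b.residues
    return np.array(
        [not columns_equal(x, y) for x, y in zip(a, b)], dtype=bool
    )


def disruption_energy(pair: ParentPair, cmap: ContactMap, scheme: CrossoverScheme) -> int:
    """SCHEMA disruption energy via the two-parent reduction. Exact integer."""
    L = pair.n_columns
    labels = assign_columns(scheme, L)
    differ = differing_columns_mask(pair)
    e = 0
    for contact in cmap.contacts:
        i, j = tuple(contact)
        if labels[i - 1] != labels[j - 1] and differ[i - 1] and differ[j - 1]:
            e += 1
    return e


def chimera_columns(pair: ParentPair, scheme: CrossoverScheme) -> str:
    """The chimera's gapped residue string in alignment coordinates."""
    L = pair.n_columns
    labels = assign_columns(scheme, L)
    a = pair.parent_a.residues
    b = pair.parent_b.residues
    return "".join(a[c] if labels[c] == "A" else b[c] for c in range(L))


def oracle_energy(pair: ParentPair, cmap: ContactMap, scheme: CrossoverScheme) -> int:
    """Literal pair-membership disruption energy (independent slow path).

    Builds the full chimeric column string and counts contacts whose residue
    pair matches neither parent's residue pair at those columns.
    """
    chim = chimera_columns(pair, scheme)
    a = pair.parent_a.residues
    b = pair.parent_b.residues
    e = 0
    for contact in cmap.contacts:
        i, j = tuple(contact)
        ci, cj = chim[i - 1], chim[j - 1]
        in_a = columns_equal(ci, a[i - 1]) and columns_equal(cj, a[j - 1])
        in_b = columns_equal(ci, b[i - 1]) and columns_equal(cj, b[j - 1])
        if not (in_a or in_b):
            e += 1
    return e


def drop_parent_gap_contacts(cmap: ContactMap, pair: ParentPair) -> ContactMap:
    """Optional filter: remove contacts touching a column where either parent
    has a gap. By default such contacts are retained (the chimera simply
    inherits the gap); this switch gives the alternative convention.
    """
    gapped = {
        c + 1
        for c in range(pair.n_columns)
        if pair.parent_a.residues[c] == GAP or pair.parent_b.residues[c] == GAP
    }
    kept = frozenset(p for p in cmap.contacts if not (p & gapped))
    return ContactMap(
        kept, cmap.cutoff, cmap.min_separation, cmap.template_id, len(kept)
    )
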