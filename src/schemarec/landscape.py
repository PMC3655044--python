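"""Exhaustive disruption-energy landscapes over crossover positions.

The single-crossover scan profiles E over every cut point; the
double-crossover scan fills the triangular (x1, x2) landscape rendered as a
heat map, with the first crossover on the abscissa and the second on the
ordinate. Both scans use an exact counting decomposition: a contact {i, j}
(i < j in column order, both columns differing between the parents)
contributes to a single-alternation chimera iff exactly one of its endpoints
lies inside the middle fragment (x1, x2]. Cumulative sums over the differing
contact set make the full scan O(L^2) while remaining bit-identical to
evaluating each cell's scheme individually.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP, ParentPair
from .energy import CrossoverScheme, assign_columns, differing_columns_mask
from .structure import ContactMap

SINGLE_PATTERNS = ("AB", "BA")
DOUBLE_PATTERNS = ("ABA", "BAB")


def _differing_contact_array(pair: ParentPair, cmap: ContactMap) -> np.ndarray:
    """Contacts whose BOTH endpoint columns differ between the parents,
    as an (n, 2) array of 1-based columns with col_i < col_j."""
    differ = differing_columns_mask(pair)
    rows = []
    for contact in cmap.contacts:
        i, j = sorted(contact)
        if differ[i - 1] and differ[j - 1]:
            rows.append((i, j))
    if not rows:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(sorted(rows), dtype=np.int64)


def scan_single(pair: ParentPair, cmap: ContactMap, pattern: str = "AB") -> np.ndarray:
    """Disruption energy of the single-crossover chimera at every cut x.

    Returns an integer vector of length L-1; entry at index x-1 is E for the
    scheme with crossover column x (fragment 1 ends at x).
    """
    if pattern not in SINGLE_PATTERNS:
        raise ValueError(f"pattern must be one of {SINGLE_PATTERNS}, got {pattern!r}")
    L = pair.n_columns
    dc = _differing_contact_array(pair, cmap)
    # contact (i, j) is disrupted at crossover x iff i <= x < j
    starts = np.zeros(L + 1, dtype=np.int64)
    ends = np.zeros(L + 1, dtype=np.int64)
    for i, j in dc:
        starts[i] += 1
        ends[j] += 1
    active = np.cumsum(starts) - np.cumsum(ends)  # active[x] = #(i <= x < j)
    return active[1:L]


@dataclass(frozen=True)
class DisruptionLandscape:
    """Triangular matrix of disruption energies over (x1, x2) pairs.

    ``energies[x1 - 1, x2 - 1]`` holds E for first crossover x1 and second
    x2; ``admitted`` masks the cells satisfying 1 <= x1 < x2 <= L-1 and
    x2 - x1 >= min_middle_fragment. First crossover on the abscissa, second
    on the ordinate, in every serialized or plotted form.
    """

    pattern: str
    energies: np.ndarray = field(repr=False)
    admitted: np.ndarray = field(repr=False)
    min_middle_fragment: int
    L: int
    parent_a_id: str
    parent_b_id: str
    template_id: str
    n_contacts: int

    def energy_at(self, x1: int, x2: int) -> int:
        if not self.admitted[x1 - 1, x2 - 1]:
            raise ValueError(f"cell ({x1}, {x2}) is not admitted")
        return int(self.energies[x1 - 1, x2 - 1])

    @property
    def n_admitted(self) -> int:
        return int(self.admitted.sum())

    def min_energy(self) -> int:
        return int(self.energies[self.admitted].min())

    def to_tsv_matrix(self) -> str:
        """Matrix TSV: rows are x1 (abscissa), columns x2; masked cells empty."""
        buf = io.StringIO()
        header = "x1\\x2\t" + "\t".join(str(x2) for x2 in range(1, self.L))
        buf.write(header + "\n")
        for x1 in range(1, self.L):
            cells = [
                str(int(self.energies[x1 - 1, x2 - 1]))
                if self.admitted[x1 - 1, x2 - 1]
                else ""
                for x2 in range(1, self.L)
            ]
            buf.write(str(x1) + "\t" + "\t".join(cells) + "\n")
        return buf.getvalue()

    def to_tsv_long(self) -> str:
        """Long-form TSV (x1, x2, E) over admitted cells only."""
        lines = ["x1\tx2\tE"]
        xs1, xs2 = np.nonzero(self.admitted)
        for a, b in zip(xs1, xs2):
            lines.append(f"{a + 1}\t{b + 1}\t{int(self.energies[a, b])}")
        return "\n".join(lines) + "\n"

    def plot(self, ax=None, cmap: str = "viridis"):
        """Heat map with x1 on the abscissa and x2 on the ordinate."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        shown = np.where(self.admitted, self.energies, np.nan)
        # imshow rows run along the ordinate: transpose so x1 is horizontal
        im = ax.imshow(
            shown.T, origin="lower", aspect="equal",
            extent=(0.5, self.L - 0.5, 0.5, self.L - 0.5), cmap=cmap,
        )
        ax.set_xlabel("first crossover x1 (alignment column)")
        ax.set_ylabel("second crossover x2 (alignment column)")
        ax.set_title(f"disruption energy, pattern {self.pattern}")
        ax.figure.colorbar(im, ax=ax, label="E (contacts broken)")
        return ax


def scan_double(
    pair: ParentPair,
    cmap: ContactMap,
    pattern: str = "ABA",
    min_middle_fragment: int = 20,
) -> DisruptionLandscape:
    """Exact disruption-energy landscape for all admitted (x1, x2) pairs.

    ``min_middle_fragment`` is the minimum middle-fragment length in
    alignment columns (x2 - x1); the landscape diagonal corresponds to that
    minimum. Energies are computed by 2-D prefix sums over the differing
    contact set and are bit-identical to per-cell scheme evaluation.
    """
    if pattern not in DOUBLE_PATTERNS:
        raise ValueError(f"pattern must be one of {DOUBLE_PATTERNS}, got {pattern!r}")
    if min_middle_fragment < 1:
        raise ValueError("min_middle_fragment must be >= 1")
    L = pair.n_columns
    dc = _differing_contact_array(pair, cmap)

    # P[a, b] = number of differing contacts with i <= a and j <= b (1-based)
    grid = np.zeros((L + 1, L + 1), dtype=np.int64)
    if len(dc):
        np.add.at(grid, (dc[:, 0], dc[:, 1]), 1)
    P = grid.cumsum(axis=0).cumsum(axis=1)
    n_le = P[:, L]  # n_le[a] = #contacts with i <= a
    diag = np.diagonal(P)  # diag[a] = #contacts fully inside columns <= a

    # E(x1,x2) = #(x1 < i <= x2 < j) + #(i <= x1 < j <= x2)
    #          = n_le[x2] - diag[x2] - n_le[x1] + 2 P[x1,x2] - diag[x1]
    x = np.arange(1, L)  # candidate crossover columns 1..L-1
    energies = (
        (n_le[x] - diag[x])[None, :]
        - (n_le[x] + diag[x])[:, None]
        + 2 * P[np.ix_(x, x)]
    )
    full_e = np.zeros((L, L), dtype=np.int64)
    full_e[: L - 1, : L - 1] = energies

    x1g, x2g = np.meshgrid(np.arange(1, L + 1), np.arange(1, L + 1), indexing="ij")
    admitted = (x1g >= 1) & (x2g <= L - 1) & (x2g - x1g >= min_middle_fragment)
    full_e[~admitted] = 0
    return DisruptionLandscape(
        pattern=pattern,
        energies=full_e,
        admitted=admitted,
        min_middle_fragment=min_middle_fragment,
        L=L,
        parent_a_id=pair.parent_a.id,
        parent_b_id=pair.parent_b.id,
        template_id=cmap.template_id,
        n_contacts=len(cmap),
    )


@dataclass(frozen=True)
class ChimeraCandidate:
    """One low-disruption crossover pair, with bookkeeping for triage."""

    scheme: CrossoverScheme
    energy: int
    fragment_residue_lengths: tuple[int, ...]
    composition: dict[str, float] | None = None

    @property
    def x1(self) -> int:
        return self.scheme.crossovers[0]

    @property
    def x2(self) -> int:
        return self.scheme.crossovers[1]


def _fragment_residue_lengths(pair: ParentPair, scheme: CrossoverScheme) -> tuple[int, ...]:
    L = pair.n_columns
    bounds = (0,) + scheme.crossovers + (L,)
    out = []
    for letter, lo, hi in zip(scheme.pattern, bounds, bounds[1:]):
        parent = pair.parent_a if letter == "A" else pair.parent_b
        out.append(sum(1 for c in range(lo, hi) if parent.residues[c] != GAP))
    return tuple(out)


def find_minima(
    landscape: DisruptionLandscape,
    pair: ParentPair,
    neighborhood_radius: int = 5,
    max_candidates: int = 10,
) -> list[ChimeraCandidate]:
    """Admitted cells that are <= every admitted cell within a Chebyshev
    neighborhood, sorted by (energy, x1, x2); ties reported up to
    ``max_candidates``."""
    from scipy.ndimage import minimum_filter

    if landscape.n_admitted == 0:
        raise ValueError("landscape has no admitted cells")
    # sentinel above every attainable energy (E <= number of contacts)
    big = int(max(landscape.n_contacts, landscape.energies.max())) + 1
    padded = np.where(landscape.admitted, landscape.energies, big)
    size = 2 * neighborhood_radius + 1
    local_min = minimum_filter(padded, size=size, mode="constant", cval=big)
    is_min = landscape.admitted & (padded <= local_min)
    cells = sorted(
        (int(landscape.energies[a, b]), a + 1, b + 1) for a, b in zip(*np.nonzero(is_min))
    )
    out = []
    for e, x1, x2 in cells[:max_candidates]:
        scheme = CrossoverScheme(landscape.pattern, (x1, x2))
        out.append(
            ChimeraCandidate(
                scheme=scheme,
                energy=e,
                fragment_residue_lengths=_fragment_residue_lengths(pair, scheme),
            )
        )
    return out


def composition_stats(
    scheme: CrossoverScheme, region: tuple[int, int], pair: ParentPair
) -> dict[str, float]:
    """Fraction of a column region assigned to each parent label.

    ``region`` is an inclusive 1-based column interval (lo, hi). Used to
    filter candidates whose designated region (e.g. the catalytic core) is
    not sufficiently derived from the desired parent.
    """
    lo, hi = region
    if lo < 1 or hi > pair.n_columns or lo > hi:
        raise ValueError(f"region {region} empty or outside columns 1..{pair.n_columns}")
    labels = assign_columns(scheme, pair.n_columns)
    seg = labels[lo - 1 : hi]
    n = len(seg)
    return {
        "A": float(np.sum(seg == "A")) / n,
        "B": float(np.sum(seg == "B")) / n,
    }


def filter_candidates_by_composition(
    candidates: list[ChimeraCandidate],
    pair: ParentPair,
    region: tuple[int, int],
    parent_label: str,
    min_fraction: float,
) -> list[ChimeraCandidate]:
    """Keep candidates whose region composition for ``parent_label`` meets
    ``min_fraction``; attaches the computed composition to each survivor."""
    kept = []
    for cand in candidates:
        comp = composition_stats(cand.scheme, region, pair)
        if comp[parent_label] >= min_fraction:
            kept.append(
                ChimeraCandidate(
                    scheme=cand.scheme,
                    energy=cand.energy,
                    fragment_residue_lengths=cand.fragment_residue_lengths,
                    composition=comp,
                )
            )
    return kept


def candidates_to_tsv(candidates: list[ChimeraCandidate]) -> str:
    lines = ["x1\tx2\tE\tfragment_lengths\tfrac_A\tfrac_B"]
    for c in candidates:
        frac_a = f"{c.composition['A']:.4f}" if c.composition else "NA"
        frac_b = f"{c.composition['B']:.4f}" if c.composition else "NA"
        frags = "+".join(str(n) for n in c.fragment_residue_lengths)
        lines.append(f"{c.x1}\t{c.x2}\t{c.energy}\t{frags}\t{frac_a}\t{frac_b}")
    return "\n".join(lines) + "\n"
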