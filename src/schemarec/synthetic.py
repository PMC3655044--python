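"""Synthetic fixtures with planted ground truth.

Generates everything the pipeline consumes — divergent parent pairs inside a
gapped family alignment, toy structural templates whose contact set is known
by construction, and kinetic datasets drawn from the exact models the
fitting code assumes — so each stage can be validated against a planted
truth without any external downloads. All generators are pure functions of
their spec: the seed fixes every draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignedSequence, MultipleAlignment, ParentPair
from .energy import CrossoverScheme, oracle_energy
from .kinetics import KELVIN_OFFSET, R_GAS, diprotic_rate, michaelis_menten
from .structure import ContactMap, contact_map_from_pairs

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Family alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Recipe for a two-parent family alignment.

    ``divergence`` is the exact fraction of alignment columns at which the
    parents differ (substitutions plus gap-versus-residue columns);
    ``n_gap_events`` contiguous gap runs are carved into one parent each,
    with lengths drawn uniformly from ``gap_length_range``.
    """

    L: int = 450
    n_homologs: int = 18
    divergence: float = 0.45
    n_gap_events: int = 4
    gap_length_range: tuple[int, int] = (2, 6)
    homolog_divergence: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if self.L < 2:
            raise ValueError("alignment length must be >= 2")


@dataclass(frozen=True)
class SyntheticFamily:
    spec: SyntheticFamilySpec
    msa: MultipleAlignment
    pair: ParentPair
    differing_columns: frozenset[int]  # planted truth, 1-based


def make_parent_pair(spec: SyntheticFamilySpec) -> SyntheticFamily:
    """Two parents differing at exactly round(divergence * L) columns.

    Gap events are placed inside the differing budget (a gap opposite a
    residue is a differing column); the remaining budget becomes point
    substitutions. Homolog rows are mutated copies of parent A, so no
    alignment column is ever all-gap.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.L
    k = round(spec.divergence * L)
    a = rng.choice(list(AA20), size=L).tolist()
    b = list(a)

    # carve non-overlapping gap runs, alternating which parent gets the gap
    gap_cols: set[int] = set()
    attempts = 0
    runs: list[tuple[int, int, str]] = []  # (start0, length, parent)
    while len(runs) < spec.n_gap_events and attempts < 200:
        attempts += 1
        length = int(rng.integers(spec.gap_length_range[0], spec.gap_length_range[1] + 1))
        if len(gap_cols) + length > k:
            break
        start = int(rng.integers(0, L - length + 1))
        cols = set(range(start, start + length))
        if cols & gap_cols:
            continue
        gap_cols |= cols
        runs.append((start, length, "A" if len(runs) % 2 == 0 else "B"))
    for start, length, which in runs:
        target = a if which == "A" else b
        for c in range(start, start + length):
            target[c] = "-"

    n_subs = k - len(gap_cols)
    free = [c for c in range(L) if c not in gap_cols]
    sub_cols = rng.choice(free, size=n_subs, replace=False) if n_subs else np.array([], dtype=int)
    for c in sub_cols:
        choices = [x for x in AA20 if x != a[c]]
        b[c] = choices[int(rng.integers(0, len(choices)))]

    parent_a = AlignedSequence("parentA", "".join(a))
    parent_b = AlignedSequence("parentB", "".join(b))
    rows = [parent_a, parent_b]
    for h in range(spec.n_homologs):
        hseq = list(parent_a.residues)
        for c in range(L):
            if hseq[c] != "-" and rng.random() < spec.homolog_divergence:
                choices = [x for x in AA20 if x != hseq[c]]
                hseq[c] = choices[int(rng.integers(0, len(choices)))]
        rows.append(AlignedSequence(f"homolog{h + 1:02d}", "".join(hseq)))
    msa = MultipleAlignment(tuple(rows))
    pair = ParentPair(parent_a, parent_b)
    differing = frozenset(int(c) + 1 for c in (set(sub_cols.tolist()) | gap_cols))
    return SyntheticFamily(spec, msa, pair, differing)


def make_random_contact_map(
    L: int,
    n_contacts: int,
    seed: int = 0,
    min_separation: int = 2,
    allowed_columns: set[int] | None = None,
) -> ContactMap:
    """A random symmetric contact set over alignment columns (no geometry)."""
    rng = np.random.default_rng(seed)
    cols = sorted(allowed_columns) if allowed_columns is not None else list(range(1, L + 1))
    pairs: set[tuple[int, int]] = set()
    guard = 0
    while len(pairs) < n_contacts:
        guard += 1
        if guard > 100 * n_contacts + 1000:
            raise ValueError("cannot place that many contacts with the given constraints")
        i, j = rng.choice(len(cols), size=2, replace=False)
        ci, cj = cols[int(i)], cols[int(j)]
        if abs(ci - cj) < min_separation:
            continue
        pairs.add((min(ci, cj), max(ci, cj)))
    return contact_map_from_pairs(pairs, min_separation=min_separation)


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyStructure:
    pdb_text: str
    sequence: str  # one-letter, gapless
    planted_contacts: frozenset[tuple[int, int]]  # 1-based residue pairs, p < q


_BACKBONE = (("N", (-1.2, 0.0, 0.0)), ("CA", (0.0, 0.0, 0.0)),
             ("C", (1.2, 0.0, 0.0)), ("O", (0.0, 1.2, 0.0)))
_SPACING = 14.0  # Angstrom between residue centers: far beyond any cutoff
_CONTACT_DIST = 4.0  # planted pairs sit at ~4.0 A, inside the 4.5 A cutoff


def make_toy_structure(
    n_residues: int,
    contact_pairs: list[tuple[int, int]] | None = None,
    seed: int = 0,
) -> ToyStructure:
    """Glycine-only PDB text whose 4.5 A contact set is exactly the planted
    pairs.

    Residue centers sit on a line 14 A apart; for each planted pair (p, q)
    the carbonyl oxygen of residue q is relocated to 4.0 A from residue p's
    CA. Each residue may appear in at most one planted pair and pairs must
    have sequence separation >= 2, which guarantees no incidental contacts.
    A small seeded jitter (<= 0.05 A per coordinate) varies instances
    without crossing either distance class.
    """
    pairs = sorted(tuple(sorted(p)) for p in (contact_pairs or []))
    used: set[int] = set()
    for p, q in pairs:
        if not (1 <= p < q <= n_residues):
            raise ValueError(f"pair {(p, q)} outside residues 1..{n_residues}")
        if q - p < 2:
            raise ValueError(f"pair {(p, q)} has separation < 2")
        if p in used or q in used:
            raise ValueError(f"residue reused across planted pairs: {(p, q)}")
        used.update((p, q))
    rng = np.random.default_rng(seed)
    moved_o = {q: p for p, q in pairs}

    lines: list[str] = ["HEADER    SYNTHETIC TOY STRUCTURE"]
    serial = 0
    for r in range(1, n_residues + 1):
        center = np.array([_SPACING * (r - 1), 0.0, 0.0])
        for name, offset in _BACKBONE:
            if name == "O" and r in moved_o:
                target = np.array([_SPACING * (moved_o[r] - 1), 0.0, _CONTACT_DIST])
                pos = target
            else:
                pos = center + np.array(offset)
            pos = pos + rng.uniform(-0.05, 0.05, size=3)
            serial += 1
            lines.append(
                f"ATOM  {serial:>5d}  {name:<3s} GLY A{r:>4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00"
                f"          {name[0]:>2s}"
            )
    lines.append("END")
    return ToyStructure(
        pdb_text="\n".join(lines) + "\n",
        sequence="G" * n_residues,
        planted_contacts=frozenset(pairs),
    )


# ---------------------------------------------------------------------------
# Exhaustive energy tables
# ---------------------------------------------------------------------------

def enumerate_all_energies(
    pair: ParentPair,
    cmap: ContactMap,
    pattern: str = "ABA",
    min_middle_fragment: int = 20,
) -> pd.DataFrame:
    """Ground-truth (x1, x2, E) table via the literal oracle, one scheme per
    admitted cell. Intended for instances with at most ~10^4 admitted cells."""
    L = pair.n_columns
    rows = []
    for x1 in range(1, L):
        for x2 in range(x1 + min_middle_fragment, L):
            scheme = CrossoverScheme(pattern, (x1, x2))
            rows.append((x1, x2, oracle_energy(pair, cmap, scheme)))
    return pd.DataFrame(rows, columns=["x1", "x2", "E"])


# ---------------------------------------------------------------------------
# Kinetic datasets
# ---------------------------------------------------------------------------

MODELS = ("michaelis_menten", "diprotic_ph", "arrhenius", "thermal_optimum")


@dataclass(frozen=True)
class SyntheticKineticsSpec:
    """Recipe for one simulated assay series.

    ``noise_sd`` is the standard deviation of multiplicative Gaussian noise:
    observed = model * (1 + N(0, sd)), floored at zero.
    """

    model: str
    params: dict = field(default_factory=dict)
    design: tuple[float, ...] = ()
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; pick from {MODELS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def mm_assay_spec(noise_sd: float = 0.05, seed: int = 0) -> SyntheticKineticsSpec:
    """Initial-rate series emulating the hybrid enzyme's saturation curve:
    k_cat 0.39 s^-1, K_M 1.74 uM, 12 substrate points from 0.25 to 16 uM."""
    design = tuple(float(x) for x in np.geomspace(0.25, 16.0, 12))
    return SyntheticKineticsSpec(
        "michaelis_menten", {"v_max": 0.39, "k_m": 1.74}, design, noise_sd, seed
    )


def ph_assay_spec(noise_sd: float = 0.05, seed: int = 0) -> SyntheticKineticsSpec:
    """pH-activity bell centred at pH 3 (pKa 2 and 4), measured pH 1-6."""
    design = tuple(float(x) for x in np.arange(1.0, 6.01, 0.5))
    return SyntheticKineticsSpec(
        "diprotic_ph", {"v_opt": 1.0, "pka_acidic": 2.0, "pka_basic": 4.0},
        design, noise_sd, seed,
    )


def arrhenius_assay_spec(noise_sd: float = 0.05, seed: int = 0) -> SyntheticKineticsSpec:
    """Ascending-limb rates with activation energy 76 kJ/mol, 50-80 C."""
    design = tuple(float(x) for x in np.arange(50.0, 80.01, 5.0))
    return SyntheticKineticsSpec(
        "arrhenius", {"ea_kj_mol": 76.0, "ln_a": 24.94}, design, noise_sd, seed
    )


def thermal_profile_spec(noise_sd: float = 0.05, seed: int = 0) -> SyntheticKineticsSpec:
    """Peaked activity-temperature profile with its optimum at 85 C."""
    design = tuple(float(x) for x in np.arange(40.0, 100.01, 5.0))
    return SyntheticKineticsSpec(
        "thermal_optimum", {"t_opt": 85.0, "width": 12.0}, design, noise_sd, seed
    )


def _model_curve(spec: SyntheticKineticsSpec, x: np.ndarray) -> np.ndarray:
    p = spec.params
    if spec.model == "michaelis_menten":
        return michaelis_menten(x, p["v_max"], p["k_m"])
    if spec.model == "diprotic_ph":
        return diprotic_rate(x, p["v_opt"], p["pka_acidic"], p["pka_basic"])
    if spec.model == "arrhenius":
        t_k = x + KELVIN_OFFSET
        return np.exp(p["ln_a"] - p["ea_kj_mol"] * 1000.0 / (R_GAS * t_k))
    # thermal_optimum: Gaussian peak on the temperature axis
    return np.exp(-((x - p["t_opt"]) ** 2) / (2.0 * p["width"] ** 2))


_XCOL = {
    "michaelis_menten": "substrate_uM",
    "diprotic_ph": "pH",
    "arrhenius": "temp_C",
    "thermal_optimum": "temp_C",
}


def simulate_kinetics(spec: SyntheticKineticsSpec) -> pd.DataFrame:
    """Draw one dataset from the spec's model with multiplicative noise."""
    if not spec.design:
        raise ValueError("spec.design must list at least one point")
    rng = np.random.default_rng(spec.seed)
    x = np.asarray(spec.design, dtype=float)
    truth = _model_curve(spec, x)
    noise = 1.0 + spec.noise_sd * rng.standard_normal(len(x))
    rate = np.clip(truth * noise, 0.0, None)
    return pd.DataFrame({_XCOL[spec.model]: x, "rate": rate})
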