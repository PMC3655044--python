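# Methods

## Disruption energy

A chimera of two aligned parents A and B is specified by a pattern over
{A, B} (the parent of each fragment) and crossover columns x1 < x2 < …,
where each x is the *last* alignment column of the preceding fragment
(fragment k spans columns (x_{k−1}, x_k]). This single-integer-per-site
convention is fixed throughout: a reported crossover at column 166 means
columns 1–166 come from the first fragment's parent.

The disruption energy E of a chimera is the number of template contacts
{i, j} whose residue pair in the chimera occurs in neither parent. For
exactly two parents this reduces to: the endpoints are sourced from
different parents AND both endpoint columns differ between the parents.
`disruption_energy` implements the reduction; `oracle_energy` materializes
the full chimeric column string and applies the literal pair-membership
definition with no shortcut. The two routes are asserted equal on every
tested instance — this dual-route check is the package's central
correctness property, and E is an exact integer end to end (no floating
point anywhere on the energy path).

Consequences worth knowing:

- **Pattern symmetry.** With only two parents, E is invariant under swapping
  the parents while complementing the pattern, and in fact the ABA and BAB
  landscapes of the same pair are identical cell-by-cell: disruption depends
  only on where the source *changes*, not on which parent is which. Distinct
  hybrids (ABA vs BAB at the same sites) therefore share an E value even
  though their sequences differ. A multi-parent generalization would break
  this degeneracy; it is out of scope here.
- **Gap handling.** Alignment gaps participate as ordinary symbols:
  gap-vs-gap is equal, gap-vs-residue differs (a crossover through an indel
  region genuinely changes local composition). Contacts touching columns
  where a parent has a gap are retained by default — the chimera simply
  inherits the gap — and `drop_parent_gap_contacts` switches to the stricter
  convention of discarding them.
- **Unknown residues.** 'X' compares unequal to every other symbol, so a
  contact over an X column opposite a known residue counts as breakable
  (conservative). Two X tokens at the same column compare equal; this keeps
  the reduction exactly equivalent to the literal definition and guarantees
  E = 0 for pure-parent patterns regardless of unknowns.

## Contact maps

Contacts come from a PDB template whose sequence must match one alignment
row exactly (after masking nonstandard residues to X); silent mismatches
would corrupt every downstream energy, so no fuzzy matching is attempted.
Two residues are in contact when any pair of heavy atoms lies within a
cutoff, default **4.5 Å**, with ordinal sequence separation at least **2**
(adjacent backbone neighbours are never counted). The cutoff and separation
are exposed parameters, not claims about any particular study: 4.5 Å
heavy-atom is the convention of the recombination-design literature. Only
the first model of a multi-model file is used; alternate locations resolve
to the highest-occupancy atom (ties toward altloc 'A'); waters, other
heteroatoms and hydrogens are dropped. Separation is computed on the
ordinal index of the residue within the chain, not on author numbering, so
chains with missing residues remain well-defined. Residue-index contacts
are lifted to alignment columns through the template row's column map;
lifting preserves the contact count exactly and is invertible.

## Landscape scanning

The double-crossover scan evaluates E for every admissible (x1, x2) with
x2 − x1 ≥ `min_middle_fragment` (default **20** alignment columns, the
landscape's diagonal) and 1 ≤ x1 < x2 ≤ L−1. A contact contributes to a
single-alternation chimera iff exactly one endpoint lies in the middle
fragment (x1, x2] and both endpoint columns differ; 2-D prefix sums over the
differing-contact indicator matrix give every cell in O(L²) total, and the
result is bit-identical to evaluating each cell's scheme individually
(asserted exhaustively on toy instances and on sampled cells at full scale;
an L = 500 / 1,500-contact scan takes well under a second). Heat-map
orientation is fixed: first crossover on the abscissa, second on the
ordinate, in the matrix TSV, the long-form TSV and the plot.

Local minima are defined as admitted cells ≤ all admitted cells within
Chebyshev radius **5** (a flag); candidates are sorted by (E, x1, x2) with
all ties reported up to `max_candidates`. The radius-based definition is
this package's own — in practice designers pick minima from the heat map by
eye — so the scan also reports each candidate's fragment lengths (in
ungapped residues of the source parent) and the fraction of a designated
column region assigned to each parent, which is the quantitative form of
the judgment "the catalytic core must come from parent X". Automated choice
among the surviving candidates is deliberately out of scope.

## Chimera assembly

`build_chimera` copies each fragment's columns from its source parent,
drops gaps, and records per-fragment provenance, source residue spans and
lengths; fragment lengths always sum to the hybrid's total length.
Molecular weights use average (not monoisotopic) residue masses with free
termini; no tags or signal peptides are added or removed, since construct
decoration is a cloning decision, not a design one.

## Kinetic characterization

Three models, each a Model class whose `fit()` returns a Results object
with estimates, standard errors (from the Jacobian at the optimum) and a
`summary()`:

- **Michaelis–Menten** v = v_max·S/(K_M + S), nonlinear least squares with
  Hanes–Woolf initial guesses, tolerance 1e-10 on relative parameter
  change, at most 500 residual evaluations; non-convergence is a flag on
  the result, not an exception. Rates may be turnover numbers (s⁻¹, so
  v_max is k_cat directly) or specific activities (μmol·min⁻¹·mg⁻¹,
  converted via k_cat = v_max·M/60000 for molar mass M in g/mol).
  Unweighted least squares is the default; 1/v² weighting is available and
  is the appropriate choice when the noise is multiplicative — under
  multiplicative noise the unweighted fit's standard errors are
  systematically anticonservative, which is visible in simulation-study
  coverage, so the recovery studies shipped with the package use the
  weighted fit. k_cat/K_M is carried at full precision and displayed at two
  significant figures.
- **pH profile**: the diprotic bell v(pH) = v_opt/(1 + 10^(pKa₁−pH) +
  10^(pH−pKa₂)), whose optimum is (pKa₁+pKa₂)/2 — the ionization of two
  catalytic acidic residues. The bell is an explicit modelling choice; the
  plain argmax of the measured profile is always reported alongside, and a
  maximum at the edge of the measured pH range sets a boundary flag.
- **Arrhenius**: closed-form linear regression of ln(rate) on 1/T(K);
  E_a = −slope·R reported in kJ/mol. Only the ascending limb (temperatures
  at or below the measured optimum) is used by default, since inactivation
  dominates above it. An optional per-temperature correction factor column
  multiplies the rates before fitting (e.g. temperature-dependent readout
  intensity); no photophysical model is built in. The temperature optimum
  itself is the argmax over the measured grid, ties resolving to the lowest
  temperature with a warning, as does an optimum on the grid boundary.

## Synthetic data: what it emulates and what it does not

The generators define the package's study conditions and every test
fixture:

- **Families**: two parents differing at exactly round(divergence·L)
  columns (default L = 450, divergence 0.45, emulating a divergent but
  alignable homolog pair), with contiguous gap runs (default 4 events of
  2–6 columns) counted inside the differing budget, plus mutated homolog
  rows (default 18, matching a typical family alignment's depth). Columns
  are i.i.d.; there is no phylogeny, no conservation gradient and no
  spatial correlation between sequence divergence and structural contacts,
  so synthetic landscapes lack the biologically structured minima of real
  families — their minima sit near the landscape borders where chimeras are
  nearly pure parents. Passing tests therefore demonstrate exact
  combinatorial correctness of the scan, not that any particular biological
  minimum is recovered.
- **Toy structures**: glycine-only chains, four heavy atoms per residue,
  14 Å apart along a line, with planted contacts created by relocating one
  atom to 4.0 Å from the partner residue (versus ≥ 7 Å for everything
  else, against the 4.5 Å cutoff). Each residue joins at most one planted
  pair, which makes the true contact set exact by construction; a ≤ 0.05 Å
  seeded jitter varies instances without crossing either distance class.
  The geometry is deliberately unphysical — it exercises parsing, contact
  detection and lifting, not molecular realism.
- **Kinetics**: datasets drawn from the exact fitted models with
  multiplicative Gaussian noise (default sd 5%). Default conditions are the
  characterization targets of the motivating study: k_cat 0.39 s⁻¹ and
  K_M 1.74 μM over 12 substrate points (0.25–16 μM); pKa 2.0/4.0 (pH
  optimum 3.0) over pH 1–6; activation energy 76 kJ/mol over 50–80 °C; a
  peaked thermal profile with its optimum at 85 °C. Because data are drawn
  from the same model families that are fitted, recovery tests measure
  estimator correctness and calibration, not model adequacy on real assay
  traces.

All generators are pure functions of their spec including the seed;
re-running with the same spec is byte-identical.

## Problem sizes

The shipped tests and the acceptance script use alignments of 12–500
columns, contact maps of 5–1,500 pairs, exhaustive enumeration up to a few
thousand cells, 200+ randomized oracle cross-checks per run and
100-replicate fit-coverage studies; the complete suite runs in a few
seconds on one CPU. These sizes were chosen so every expensive claim is
verified exhaustively where exhaustiveness is feasible and by sampling
where it is not.

## Known limitations

- Two parents only; no library (multi-crossover, multi-parent) optimization
  and no folding free-energy estimates.
- The contact criterion of any specific published design cannot be assumed;
  cutoff, atom subset and separation are parameters the user must own.
- Alignments are consumed, never computed; results are only as good as the
  supplied alignment, and fragment lengths reported for published designs
  depend on the exact alignment used there.
- The pH bell assumes exactly two ionizations and the Arrhenius fit assumes
  a single rate-limiting step below the optimum.
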