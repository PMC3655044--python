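# schemarec

Tools for designing two-parent chimeric enzymes by structure-guided
recombination, and for characterizing the resulting variants kinetically.

Given two homologous parent proteins in a multiple sequence alignment and a
structural template for the family, `schemarec` scores every possible
single- and double-crossover hybrid by its **disruption energy** E: the
number of residue–residue contacts in the template structure whose
amino-acid pairing in the chimera occurs in neither parent. E is an exact
integer count — a proxy for fold disruption, not a physical energy — and the
working hypothesis of recombination-based design is that hybrids with low E
are more likely to fold and retain function. The package was built around a
concrete use case: fusing a thermoacidophilic archaeal endoglucanase with a
thermophilic bacterial one (glycoside hydrolase family 12) so that the
hybrid keeps the acid-tolerant catalytic core of one parent inside the
better-behaved scaffold of the other.

For a contact {i, j} (alignment columns) and a chimera assembled from
parents A and B, the contact is counted as disrupted exactly when the two
endpoint residues are sourced from different parents *and* both columns
differ between the parents:

    E(x⃗, pattern) = #{ {i,j} ∈ contacts :
                        label(i) ≠ label(j), A_i ≠ B_i, A_j ≠ B_j }

The package scans E over all crossover placements (the two-crossover case
yields a triangular heat-map landscape over (x1, x2)), reports local minima
as candidate designs, filters them by which parent dominates a designated
region (e.g. the catalytic core), assembles the chimeric sequences, and fits
the standard kinetic characterization of a purified variant: the
Michaelis–Menten saturation curve (k_cat, K_M and k_cat/K_M), a diprotic
bell-shaped pH–activity profile (two pKa values, pH optimum at their
midpoint), the temperature optimum, and an Arrhenius estimate of the
activation energy from the ascending limb of the temperature profile.

## Worked example

Everything below runs on synthetic data generated by `schemarec.synthetic`,
so it is fully reproducible without downloads:

```python
from schemarec.synthetic import (SyntheticFamilySpec, make_parent_pair,
                                 make_random_contact_map)
from schemarec.landscape import (scan_double, find_minima,
                                 filter_candidates_by_composition,
                                 candidates_to_tsv)
from schemarec.chimera import build_chimera

fam = make_parent_pair(SyntheticFamilySpec(L=450, divergence=0.45, seed=0))
cmap = make_random_contact_map(450, 1200, seed=1)

land = scan_double(fam.pair, cmap, "ABA", min_middle_fragment=20)
print("admitted cells:", land.n_admitted, " min E:", land.min_energy())

cands = find_minima(land, fam.pair, neighborhood_radius=5, max_candidates=10)
kept = filter_candidates_by_composition(cands, fam.pair, region=(150, 300),
                                        parent_label="B", min_fraction=0.8)
print(candidates_to_tsv(kept))

chim = build_chimera(fam.pair, kept[0].scheme)
print(chim.description())
print(f"molecular weight: {chim.molecular_weight/1000:.1f} kDa")
```

prints

```
admitted cells: 92235  min E: 2
x1	x2	E	fragment_lengths	frac_A	frac_B
1	449	2	1+439+1	0.0000	1.0000
1	439	7	1+429+11	0.0000	1.0000

pattern=ABA crossovers=1,449 fragment_lengths=1+439+1 total=441
molecular weight: 52.3 kDa
```

Reading the output: the scan admitted 92,235 (x1, x2) cells (middle fragment
at least 20 columns) and the lowest disruption anywhere is E = 2. The
surviving candidates illustrate a standard pathology of unconstrained
minimization — the best cells sit at the extreme corners of the landscape,
where the chimera is nearly a pure parent (fragments 1+439+1) and trivially
breaks almost nothing. In a real design round these are exactly the
candidates one rejects by judgment or by tightening the composition filter
and minimum fragment lengths; the filter columns `frac_A`/`frac_B` show each
candidate's parent composition over the designated core region to support
that decision.

Fitting a saturation curve (here simulated noise-free at the default study
conditions, k_cat 0.39 s⁻¹ and K_M 1.74 μM):

```python
from schemarec.kinetics import MichaelisMentenModel
from schemarec.synthetic import mm_assay_spec, simulate_kinetics

df = simulate_kinetics(mm_assay_spec(noise_sd=0.0))
print(MichaelisMentenModel(df["substrate_uM"], df["rate"]).fit().summary())
```

```
Michaelis-Menten fit
  n observations : 12
  v_max          : 0.39 +/- 8.3e-17 s^-1
  K_M            : 1.74 +/- 1.2e-15 uM
  k_cat          : 0.39 s^-1
  k_cat/K_M      : 0.2241 s^-1 uM^-1 (displays as 0.22)
  RSS            : 8.763e-32
  converged      : True
```

The same models are reachable from the shell via the `schemarec` console
script (`schemarec contacts|scan|build|kinetics|simulate --help`), which
reads aligned FASTA/Clustal alignments, PDB templates and TSV assay tables,
and writes every result as TSV next to a resolved-config provenance file.

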