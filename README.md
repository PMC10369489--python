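# dimergrow

Growth-mode analysis of protein dimer interfaces: does a given dimer, if it
keeps adding monomers through the same interface, grow into an unlimited
(fibril-competent) polymer or close upon itself?

Protein aggregation often starts from dimers, and the same protein can form
many distinct dimer interfaces ("binding modes"), each with its own fate:
some propagate into long helical or linear chains, others fold straight back
onto themselves (head-to-head) or close into rings (doughnuts). `dimergrow`
predicts that fate from the interface geometry alone, for any dimer with one
chain per monomer — no simulation required. The approach was developed for
amyloidogenic beta-2-microglobulin conformers with compact cores and
detached, unstructured termini, but applies to any homodimer.

## The model

A dimer (monomers A and B) is summarized by four measured points: the
geometric centers of the monomers, GC_A and GC_B, and the geometric centers
of the interfacial residues of each side, GC_IA and GC_IB. Interface
residues are detected from solvent accessibility: a residue is interfacial
when complexation buries more than 10% of its maximum solvent-accessible
surface area (SASA computed by Shrake–Rupley sampling; the buried area is
SASA of the isolated monomer minus SASA within the complex).

Two angles encode the interface geometry:

* the **polymerization angle**
  `theta_pol = angle(GC_IA − GC_A, GC_IA − GC_B)` — how much a replicated
  chain bends per step (180° for a straight head-on interface);
* the **polymerization dihedral** `phi_pol`, the angle between the normals
  `P_A = (GC_B − GC_A) × (GC_IB − GC_A)` and
  `P_B = (GC_A − GC_B) × (GC_IA − GC_B)` — how much consecutive monomers
  twist relative to each other.

Monomer shape is quantified by the gyration tensor: with eigenvalues
`lambda_1 >= lambda_2 >= lambda_3` and mean `lambda_bar`, the asphericity is

```
A_s = (3/2) * sum_i (lambda_i - lambda_bar)^2 / (sum_i lambda_i)^2
```

(0 for an ideal sphere, 1 for a rod) and the sphericity is
`psi = (1 − A_s) × 100`.

**Sphere model.** Reducing monomers to tangent unit spheres (A at the
origin, B at (−2, 0, 0)), any (theta_pol, phi_pol) pair defines a dimer and
a propagation screw — here, the screw of the center chain with bond length
2, bond angle theta_pol and backbone torsion phi_pol. Iterating the screw
32 times and checking whether non-adjacent spheres overlap classifies the
growth mode as *limited* or *unlimited*. Scanning a 5° grid over both
angles yields the **growth landscape**: everything below theta_pol = 60° is
limited (the gap-2 center distance is 4·sin(theta/2), which drops below the
sphere diameter exactly at 60°), and the limited/unlimited transition
theta\*(phi) is fitted with `a·exp(b·phi) + c`, with an uncertain band of
±10° around it where the sphere approximation should not be trusted.

**Atomic replication.** For dimers in the uncertain band (or on request)
the atomic structure is replicated directly: the rigid transform
superposing monomer A's core Cα atoms onto monomer B's is applied
iteratively to build an n-monomer chain, and heavy-atom clashes between
non-adjacent monomers decide the verdict. Subtypes (head-to-head,
doughnut, linear, helical) follow from the screw decomposition of the
propagation transform and the overlap pattern.

## Worked example

```python
from dimergrow import classify_sphere_growth, scan_landscape

for theta, phi in [(81, 160), (123, 16), (38, 24), (78, 20)]:
    c = classify_sphere_growth(theta, phi, n=32)
    print(theta, phi, c.mode, c.subtype, round(c.min_nonadjacent_distance, 2))

ls = scan_landscape(step=5.0, n=32)
print(ls.smallest_unlimited_theta(), ls.fit_params)
```

prints

```
81 160 unlimited linear 2.6
123 16 unlimited helical 2.99
38 24 limited h2h 0.72
78 20 limited doughnut 1.35
60.0 (104.97, -0.0406, 54.15)
```

The (81°, 160°) interface extends into an open zigzag (closest non-adjacent
approach 2.6 sphere radii — no self-collision); (123°, 16°) winds into a
wide clash-free helix; (38°, 24°) folds back head-to-head (spheres 0 and 2
collide at 0.72 radii); (78°, 20°) closes into a ring. The landscape scan
confirms that no interface below theta_pol = 60° can grow without limit,
and the fitted boundary decays from ~159° at phi = 0 to a ~55° plateau.

The `examples/` scripts walk through each capability (sphere model,
landscape, SASA interface measurement, atomic replication) on synthetic
inputs generated by `dimergrow.fixtures`; the `dimergrow` command-line tool
exposes the same operations on PDB files:

```
dimergrow classify --pdb dimer.pdb --chains A,B
dimergrow landscape --step 5 --out-grid landscape.tsv --plot landscape.png
```

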