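# Methods

This note documents the models, conventions and numerical choices behind
`dimergrow`, in the order the pipeline uses them: interface detection,
interface geometry, the sphere growth model, the landscape, atomic
replication, and the synthetic-data generators the tests run on.

## Interface detection (module `interface`)

**SASA.** Solvent-accessible surface area is computed with Shrake–Rupley
sphere-point sampling: each atom's solvent-expanded sphere (van der Waals
radius + probe radius) carries a deterministic golden-spiral point set, and
its accessible fraction is the fraction of points outside every neighbor's
expanded sphere. Defaults: probe 1.4 Å (water), 960 points per atom,
Bondi-style radii (C 1.70, N 1.55, O 1.52, S 1.80 Å, ...) with per-call
overrides and an optional fallback radius; an element without a radius
raises. At 960 points the total SASA of small clusters agrees with a dense
(10^4 points/atom) random-sampling reference within ~1–3%; both routes are
exercised in the tests, plus a cross-check against biotite's independent
implementation with identical per-atom radii.

**Interfacial area.** For a two-chain dimer, each residue's interfacial
area is its SASA in the isolated monomer minus its SASA in the complex,
clamped at zero (point sampling can make the difference marginally
negative). The relative (percent) area divides by a per-residue-type
maximum SASA. The reference normalization observed across a simulation
ensemble is not reproducible without trajectories, so the default is a
fixed table of theoretical Gly-X-Gly maxima for the 20 amino acids;
residue types absent from the table (e.g. the generator's pseudo-residues)
fall back to the residue's own isolated-monomer SASA, and an explicit
ensemble-max mode recomputes the per-residue maximum across the models of
a multi-model input. Relative areas are clipped to [0, 100].

**Descriptor.** Residues above the threshold (default 10%) form the
interface sets of A and B. Geometric centers (GC_A, GC_B, GC_IA, GC_IB)
are unweighted means over heavy atoms — "geometric center" is taken
literally; a Cα-only mode exists because coarse analyses sometimes prefer
it. If either interface set is empty the descriptor is flagged
"no interface" and every downstream angle computation rejects it rather
than returning a default: silent zeros would contaminate landscape
statistics. Interface conservation between two descriptors of the same
topology is the fraction of reference interface residues (by chain and
index, over both sides) still interfacial in the second descriptor — a
binary membership measure that ignores area magnitudes.

## Interface geometry (module `geometry`)

theta_pol is the angle at GC_IA between the directions toward it from
GC_A and from GC_B; phi_pol is the angle between the plane normals
P_A = (GC_B − GC_A) × (GC_IB − GC_A) and P_B = (GC_A − GC_B) × (GC_IA −
GC_B). "Mapping a centroid onto the partner's surface" is radial
normalization from the partner's center; it rescales lengths, never
directions, so angles are computed from raw direction vectors and the
mapping is kept only as a tested invariant. phi_pol is reported unsigned
in [0, 180]°: the sign depends on an arbitrary orientation convention and
all reference values are unsigned. Degenerate configurations (coincident
points, collapsed planes) raise instead of returning 0.

The gyration-tensor asphericity uses the relative-shape-anisotropy form
A_s = (3/2) Σ(λ_i − λ̄)² / (Σλ_i)², the standard choice satisfying
A_s = 0 for three equal principal radii, A_s = 1 for collinear points and
0 ≤ A_s ≤ 1 always; sphericity is ψ = (1 − A_s)·100. Weighting is
uniform by default (geometric), with a mass-weighted option. Superposition
is Kabsch (SVD with a determinant correction, proper rotations only); rank
< 2 configurations raise. An independent quaternion characteristic-
polynomial oracle pins the RMSD in the tests to 1e-9 Å.

## Sphere growth model (module `spheremodel`)

Monomers become tangent unit spheres: A at the origin, B at (−2, 0, 0).
The pair (theta_pol, phi_pol) does not by itself pin all six rigid degrees
of freedom of the propagation transform; the construction adopted here
closes the gap with a backbone convention:

* the chain of sphere centers is the screw-generated chain with bond
  length 2, bond angle theta_pol at every center and constant backbone
  torsion phi_pol (internal-coordinate placement of four consecutive
  centers; the propagation transform T maps the first center triple onto
  the next and is obtained by exact superposition);
* the interface marker of A sits on its sphere at the polar angle
  `alpha_A = 180° − theta − arcsin(sin(theta)/2)` from the bond direction
  (the unique surface point whose measured angle is theta, by the sine
  rule in the triangle center_A–marker–center_B), in the +y half of the
  xy-plane;
* the marker of B sits at the mirrored polar position rotated by
  `psi = 180° − phi` about the inter-center axis, which measures exactly
  phi. Both relations are closed-form, so the build→measure round trip is
  exact to machine precision.

theta = 180° degenerates to a pure translation (straight chain) and
theta = 0° to a half-turn fold-back; both are handled analytically.

This convention makes the headline boundary analytic: the distance between
centers two steps apart is 4·sin(theta/2) regardless of the torsion, so
every interface below 60° collides at the (0, 2) sphere pair — the
head-to-head regime — and the 60° limited/unlimited boundary emerges
rather than being imposed. The remaining structure of the landscape
(rings at small dihedrals up to high theta, helices and zigzags
elsewhere) follows from the screw parameters.

**Overlap.** A chain of n monomers (default 32, the chain length used for
visual comparison) is *limited* when any sphere pair with index gap ≥ 2
approaches closer than 2·(1 − δ) radii, δ = 0.05 by default: consecutive
spheres are tangent by construction and must not count, and exact
tangency of non-adjacent spheres (e.g. closed rings of integer period) is
an overlap only beyond the tolerance.

**Subtypes.** The screw decomposition (Chasles: rotation ω about an axis,
pitch p along it) plus the overlap pattern yields the taxonomy:

* *h2h* — limited with first overlap at pair (0, 2): the chain folds back
  on itself immediately;
* *doughnut* — limited with |p| < 0.5 radii/step: the chain closes into a
  ring (threshold chosen so the known ring regime near (78°, 20°), pitch
  ≈ 0.3, is captured while fold-backs keep precedence);
* *linear* — unlimited with ω < 15° or helix cylinder radius < 1 sphere
  radius: the chain advances along its axis within its own width. The
  radius criterion matters: a tight planar zigzag has ω near 180° yet
  looks and grows like a straight rod, e.g. (81°, 160°) with ω ≈ 167°
  but radius ≈ 0.77;
* *helical* — any other unlimited chain, e.g. (123°, 16°) with radius
  ≈ 2.0;
* *generic* — limited chains matching neither special pattern.

Only the limited/unlimited mode is a sharp model prediction; the subtype
thresholds digitize what is fundamentally a visual taxonomy and are all
keyword-configurable.

## Growth landscape (module `landscape`)

The scan classifies every cell of a step° grid (default 5°, i.e. 37×37
cells) deterministically. Transition points — per dihedral column, the
largest theta still limited — are fitted with theta\*(phi) = a·e^{b·phi} + c
by least squares (three parameters; theta is the response variable because
the transition is single-valued in theta per column). On the default scan
the fit residual RMS is ≈ 2.9°, below the grid step; the boundary decays
from ≈ 159° at phi = 0 to a ≈ 55° plateau. Points within ±10° of the
fitted boundary (a configurable half-width; the band is drawn, not derived)
are *uncertain* — there the sphere approximation is least trustworthy and
the atomic replication protocol decides. The ensemble representative of a
set of (theta, phi) samples is the member closest (Euclidean, arithmetic
mean — observed angles sit well inside [0, 180], so circular statistics
would be overkill) to the component-wise mean, ties to the lowest index.

## Atomic replication (module `replicate`)

The propagation transform of a real dimer is the least-squares
superposition of monomer A's core Cα atoms onto monomer B's; its fit RMSD
doubles as a homodimer-similarity diagnostic. The default core (residues
23–27, 36–39, 51–55, 62–66, 78–82, author numbering) is the
beta-2-microglobulin beta-sandwich core, chosen to exclude loops and the
mobile termini; it is a plain parameter for other proteins. Heterodimers
(differing core residue sets) are rejected. Monomer k of the polymer is
T^k applied to monomer A's full atom set — no relaxation, by design: the
chain shows what the interface geometry alone implies.

Clashes are heavy-atom pairs from monomers with index gap ≥ 2 closer than
2.0 Å (k-d-tree neighbor search, near-linear cost). The verdict tolerates
a budget of clashes — 0.5% of the non-adjacent atom pairs within a 6 Å
contact shell — because near-boundary chains often show a few contacts
that small side-chain rearrangements would relieve; a zero-tolerance rule
would misclassify marginally viable helices. Subtypes reuse the sphere
taxonomy on the atomic screw with lengths in units of half the
inter-monomer spacing (the atomic stand-in for the sphere radius). The
atomic verdict is invoked automatically in the uncertain band and on
request (`force_atomic`).

## Synthetic data (module `fixtures`)

`make_monomer` emulates the studied monomer morphology: a quasi-uniform
ball of carbon-like pseudo-atoms (one per residue, named CA so core
selections work; 3.2 Å minimum separation, matching Cα packing), with
sphericity ψ > 90 guaranteed by deterministic resampling; the
`with-termini` variant appends two protruding residue strings emerging
from neighboring surface points, which lowers ψ (to ≈ 66 at the default
sizes, the range observed for partially unstructured conformers) and
displaces the geometric center off the core.

`make_dimer` poses two copies so the *measured* angles — through the
actual SASA → centroid → angle pipeline — hit prescribed targets. A
geometric fact shapes this generator: two quasi-spherical bodies in
contact form an axially symmetric pair, so their interface centroids lie
on the inter-center axis and theta_pol is pinned near 180°; likewise,
when both centroids coincide at the contact point the dihedral's defining
vectors are coplanar and phi_pol degenerates to 0/180°. Mid-range angles
therefore require monomers whose termini participate in the interface —
exactly the mechanism by which detached termini produce mid-range angles
in real conformers. The pose family drapes each copy's arms toward the
partner (tilt γ from the inter-core axis) at independent azimuths
(β_A, β_B) around it; γ steers theta, the azimuth separation steers phi.
Because interface membership is discrete, the measured-angle response is
rough, so the inverse problem is solved by a deterministic coarse scan
over (γ, β_A, β_B) followed by Nelder–Mead polish at increasing SASA
resolution, verified at the full default resolution (960 points). Default
tolerance 5°; targets with theta ≥ 168° are judged on theta alone (the
dihedral is undefined in the colinear limit). Not every angle pair is
reachable — notably low theta with low phi, where arm-dominated
interfaces pin phi near 180° — and unreachable targets raise an error
reporting the best achieved angles. `place_dimer` complements this with
exact posing by an explicit transform (e.g. a scaled sphere-model screw)
when the propagation geometry, not the measured angles, must be
controlled.

What passing tests on these fixtures do and do not show: they validate
the full measurement chain (SASA differences, centroid geometry, angle
recovery, replication, clash counting) on structures with realistic sizes,
packing and asphericity, but say nothing about conformational dynamics,
side-chain chemistry, or interfaces stabilized by specific interactions —
real dimers sample angle distributions over time, while each fixture is a
single rigid pose.

## Problem sizes and determinism

Default problem sizes — 37×37 landscape cells × 32-monomer chains,
~50–80-atom pseudo-monomers, 960-point SASA — keep the full test suite
and the acceptance script in the seconds-to-minutes range on one CPU
while matching the scales the reference analysis used (5° grid,
32-monomer chains). Every stochastic path takes an explicit integer seed
(numpy `default_rng`); scans, fits and poses are bit-for-bit
deterministic given their inputs.

## Known limitations

* The sphere model ignores monomer shape entirely; its verdict degrades
  as sphericity falls (that is what the uncertain band and the atomic
  override are for).
* Replication carries monomer A's conformation unchanged: induced fit,
  relaxation, and cross-beta restructuring are out of scope.
* The uncertain band half-width and all subtype thresholds are
  conventions, not derived quantities.
* The per-residue normalization table applies to standard amino acids;
  nonstandard residues silently fall back to isolated-monomer
  normalization.
* `make_dimer` covers a large but not exhaustive region of the angle
  plane; unreachable targets fail loudly.
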