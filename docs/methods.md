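# Methods

## The chain model

A CSA chain of N monomers alternates glucuronic acid (GLA, odd 1-based
positions) and N-acetyl-galactosamine-4-sulfate (GAL, even positions),
so an odd-length chain starts and ends with GLA (N = 21 gives 11 GLA +
10 GAL).  Each monomer carries exactly one −1 e group — the GLA
carboxylate (SQ5n bead) or the GAL sulfate (Q4n bead) — making the net
chain charge −N exactly.  Chain charges are never rescaled; the
electronic continuum correction applies to salt ions only.

Each pyranose ring is represented by three beads joined by distance
constraints (rigid rings do not sample a harmonic well, so constraints
rather than bonds) plus one massless TC4 virtual site at the unweighted
ring-bead centroid, used as the monomer reference point in all
inter-residue geometry.  Substituents (sulfate, acetamido,
hydroxymethyl) attach with harmonic bonds.  Glycosidic junctions
(β1,3 GLA→GAL, β1,4 GAL→GLA) insert one bond, two angles, and one
periodic dihedral between template "ports".  Function types — harmonic
bonds, cosine-harmonic angles, single periodic dihedrals — are
conventions of this package, configurable per term in the template
files, since at this resolution the functional form is a modelling
choice rather than a derived quantity.

Bead size classes carry fixed van der Waals radii (regular 0.264 nm,
small 0.23 nm, tiny 0.191 nm) and masses (72/54/36 u); virtual sites
are massless.  The 0.264 nm figure is treated as the *radius* of a
regular bead, consistent with the radius list used for surface
calculations.

### Mapping-boundary convention (why the repeat unit covers 53 atoms)

The strict residue-owned atom count of the internal GLA+GAL pair
(charged carboxylate and sulfate, each glycosidic bridging oxygen
counted once) is 49.  Our mapping tables additionally assign to the
β1,4 linkage beads the junction atoms of the flanking residues — the
anomeric C1/H1 of the preceding GAL enters the GLA acceptor bead, and
the bridging O4 plus acceptor C4 of the following GLA enter the GAL
donor bead — so each glycosidic junction is represented at full C–O–C
resolution within the unit.  Sharing link atoms across a junction is
standard practice in coarse-grained carbohydrate mappings; with this
convention the internal pair covers exactly 53 distinct atoms mapped
onto 11 particles (9 atom-mapped beads + 2 ring virtual sites).
Cross-residue references are written `-X`/`+X` in the template YAML and
resolve to the previous/next residue at mapping time; terminal ("w")
variants drop them and cap both glycosidic positions with hydroxyls.
Because the two-variant template scheme cannot distinguish the
reducing from the non-reducing end, users mapping real chain-end
coordinates should prune the cap that is absent — the templates are
editable data, and bead layout, charges, and all counting invariants
are unaffected.

## Parametrization workflow

Forward mapping is by unweighted center of geometry (the procedure is
named after it); ring virtual sites are centers of the six ring atoms.
Distances use the minimum image for orthorhombic boxes; angles are
`arccos` of the normalized dot product; dihedrals follow the IUPAC
signed-`atan2` convention (cis = 0°, right-handed positive) in mapping,
fitting, and synthetic sampling alike.  Frames with degenerate geometry
are excluded from the affected term with a warning.

Boltzmann inversion: equilibrium = sample mean (circular mean for
dihedrals), force constant `k = k_B·T/σ²` with the variance in nm² or
rad², default T = 303.15 K.  Zero-variance samples yield constraints.
Multimodal dihedral references are fitted to the dominant circular mode
only (samples are assigned to the nearest histogram peak and the
heaviest peak wins, with a warning when > 1 % of frames are discarded):
minor anti-conformer peaks are not representable by a single periodic
term at this resolution.  Intra-ring constraint lengths are set to
1.10× the mapped reference mean (default `ring_scaling`), recovering
the molecular volume that center-of-geometry mapping of a ring
systematically shrinks.

Histogram comparison uses the Jensen–Shannon *distance* (square root
of the base-2 divergence) by default — 0 for identical, 1 for disjoint
histograms; the divergence form is available by flag and shares both
endpoints.  Bin widths follow the Freedman–Diaconis rule
`2·IQR·n^(−1/3)` with type-7 (linear-interpolation) quartiles,
falling back to the Scott-like `3.49·σ·n^(−1/3)` when the IQR is zero
and to a single bin when the sample is constant.  Shared edges span
both samples' supports padded by one bin width.  When `js_divergence`
builds its own spec the width comes from the pooled samples so the
score is exactly symmetric; `compare_model` pins the width to the
reference sample, which is the behaviour wanted when one side is the
ground truth.

## Polymer estimators

ETE is measured between the first and last ring virtual sites, Rg over
all chain beads unweighted (mass weighting by flag, which then skips
the massless virtual sites).  The characteristic ratio divides
⟨ETE²⟩ by N·b_v² with b_v = 0.52 nm, the reference monomer spacing,
kept configurable.  The Flory fit is an unweighted nonlinear least
squares of b·s^ν over all separations s ≥ 1 of the frame- and
pair-averaged ⟨d_ij⟩ profile (log–log linear fit available); it is an
exact interpolator on noise-free power-law input.

The bond autocorrelation C(x) averages cosines between monomer-site
bond vectors over all origins and frames, with x = k·⟨bond length⟩.
`lp_halflife` linearly interpolates the first downward crossing of
C = 0.5 and is flagged undefined (None, never silently zero) when C
stays above 0.5, as for a rigid rod.  `lp_expfit` is the decay length
of a least-squares `exp(−x/λ)` fit; for a discrete worm-like chain
C(k) = ⟨cos θ⟩^k exactly, so the two estimators differ by ln 2 on
exponential data.  `lp_wlc` = ⟨ETE²⟩/(2L) takes an explicit contour
length when known (synthetic fixed-bond chains use (N−1)·b) and falls
back to the frame-0 ETE, appropriate for trajectories started from the
extended conformation.  Rg = 1.5·Rh is applied as a fixed conversion
for linear monodisperse chains; no hydrodynamics beyond it.

## Surfaces, contacts, rupture

SASA is a deterministic Shrake–Rupley-style quadrature: 960
Fibonacci-spiral points per particle on the probe-expanded sphere
(probe 0.191 nm default), a point being buried when strictly inside a
neighbour's expanded sphere.  Exactly coincident identical particles
are collapsed to one so shared surface is not double-counted — this
makes the exposure ratio of two coincident chains exactly 0.5.  The
quadrature is written in-package because no installed library accepts
arbitrary per-particle radii for coarse-grained beads; it converges to
the same surface as lattice-based implementations, and the fixed point
set makes results deterministic (rigid-motion invariance holds to
quadrature accuracy, ~0.5 % at the default density).  The exposure
ratio computes each chain's S_a with the other chains deleted (true
isolated-chain SASA).  Contacts use strict `<` at 0.45 nm on
minimum-image distances.  RDFs are shell histograms normalized by the
ideal-gas density (orthorhombic boxes; self-pairs excluded when
reference and selection overlap).  Rupture analysis reads two-column
traces, takes the first sample where the interdomain distance reaches
5 nm, and reports the maximal force within a *centered* window of
total width 10 ns (both thresholds configurable).

## Synthetic fixtures

The generators emulate the statistical structure of chain conformers —
ideal-chain scaling, fixed bond lengths, tunable bending stiffness —
but none of the physics that only MD provides: no excluded volume, no
electrostatics, no solvent.  Estimator tests on them therefore verify
*estimator correctness* (recovering known generating parameters), not
the model's physical predictions.  The worm-like-chain sampler draws
bend angles from P(θ) ∝ exp(κ·cos θ)·sin θ by inverse CDF, with κ
solved from the exact relation ⟨cos θ⟩ = coth κ − 1/κ by bisection to
1e−10 so that ⟨cos θ⟩ = exp(−b/l_p) holds exactly.  Every chain draws
from an independent substream keyed (seed, chain index), so enlarging
an ensemble never reshuffles earlier chains.  Multi-chain placement
translates rigid copies onto a cubic grid with a guaranteed pairwise
minimum distance.

Problem sizes used in tests and in `scripts/acceptance.py` — 2000
chains of 64 monomers for ideal-chain scaling, 2000 worm-like chains
of 101 monomers at l_p = 10·b — were chosen so that sampling error sits
well inside the stated tolerances (ν within ±0.03, l_p within 10 %)
while a full run stays in the tens of seconds.  The worm-like-chain
consistency band ⟨ETE²⟩/(2·l_p·L) ∈ [0.85, 1.15] presumes L ≫ l_p:
the exact discrete value is 0.80 at L = 5·l_p and 0.90 at L = 10·l_p,
so the check is run at L = 10·l_p where the relation is meaningfully
testable.

## Known limitations

* Shipped bonded equilibria/force constants and local bead geometries
  are starting-guess template data meant to be refitted against a
  user's atomistic reference; they are not validated force-field
  parameters.
* Periodic handling assumes orthorhombic boxes.
* The scheme classifier encodes an empirical aggregation taxonomy of
  eight ion/electrostatics combinations; it does not extrapolate to
  other charges or bead sizes.
* Emitted run settings are advisory text for an external MD engine;
  the package runs no dynamics.
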