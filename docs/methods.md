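# Methods

This note documents the models implemented in `redoxpath`, the parameter
choices behind them, what the synthetic fixtures do and do not emulate, and
the numerical conventions that make results reproducible.

## Coordinate handling

Structures are read with gemmi (PDB and mmCIF) into a flat list of atom
records carrying author residue numbering, occupancy and isotropic B-factor;
no renumbering, no symmetry expansion. Alternate locations are collapsed to
one record per physical atom, by default the highest-occupancy variant with
ties broken alphabetically — the usual crystallographic convention at
moderate resolution. Structures are assumed heavy-atom-only (typical of
~3 Å crystallography); hydrogens, if present, are retained in the atom list
but excluded from surface, contact and graph computations. The PDB writer
emits fixed-column v3.3 with coordinates to 3 decimals and B-factors to 2,
and is byte-idempotent under write∘read∘write.

The Matthews relation `solvent fraction = 1 − 1.23/Vm` uses the conventional
protein-volume constant 1.23 Å³/Da (partial specific volume 0.74 cm³/g);
published solvent contents computed with in-house masses can differ from it
by on the order of a percentage point.

## Surface areas

SASA is Shrake–Rupley with a 1.4 Å probe: each atom carries a golden-section
spiral of sample points (default 960) on its expanded sphere; a point is
accessible if it lies inside no neighbour's expanded sphere. The sampling is
deterministic — no RNG — so areas are exactly reproducible; 960 points keep
the total within ~1% of a 4000-point run on our fixtures and within 1% of
the analytic sphere for an isolated atom. The van der Waals radii (C 1.70,
N 1.55, O 1.52, S 1.80, Fe 1.40, Mg 1.73 Å) ship as an editable table
because published interface areas rarely state their radii set; swapping the
table changes buried areas by a few percent. Waters and hydrogens are
excluded by default; cofactors are included.

Buried area is `SASA(A) + SASA(B) − SASA(A∪B)`; since the literature is
inconsistent about whether a printed "contact area" means this total or its
per-face half, both numbers are always reported.

## Interface contacts

Hydrogen bonds are detected purely geometrically on heavy atoms: N/O/S
atoms, one from each side, at 2.2–3.5 Å. Without hydrogens an angular
criterion would be guesswork, so none is applied; the price is occasional
false positives at the long end of the window. Bonds at ≤ 3.0 Å are labelled
strong; the boundary is configurable and is a convention, not a measured
quantity. Donor/acceptor roles come from a sidechain template (e.g. Trp NE1
donates only, carboxylates accept only, hydroxyls do both); pairs the
template cannot orient are kept and labelled "ambiguous" rather than
guessed.

## Superposition and deviation profiles

Rigid superposition is the Kabsch least-squares fit (via scipy's
`Rotation.align_vectors`, proper rotation enforced). Deviation profiles fit
the transform on an *anchor* selection and apply it, without re-fitting, to
a disjoint reported selection — the construction needed to measure how far a
subunit moves against a rigid scaffold; re-fitting on the reported atoms
would absorb exactly the motion being measured. Atoms are paired across
structures by (chain, residue number, insertion code, atom name), and
unmatched atoms are an error by default.

Plane fits are total-least-squares (smallest principal axis); the normal
sign convention (positive z, ties by x then y) makes signed out-of-plane
deviations reproducible. Macrocycle bend is the angle between the planes of
a reference pyrrole ring and its diagonal partner (I–III or II–IV), folded
to [0°, 90°]; this captures the dominant "folding" distortion of a bent heme
without a full normal-structural decomposition into ruffling/saddling modes,
which is out of scope.

## Tunneling pathways

The decay-product model assigns each step a factor ε and scores a route by
∏ε. We use the standard parameterization: ε = 0.6 per covalent bond;
ε = 0.6² · exp(−1.7(d − 2.8)) per hydrogen bond; ε = 0.5 · 0.6 ·
exp(−1.7(d − 1.4)) per through-space jump (d in Å, β = 1.7 Å⁻¹). All
parameters are exposed because published analyses that cite "standard
parameters" rarely print them. Covalent bonds are detected geometrically
(distance ≤ covalent-radius sum + 0.4 Å slack) with metal radii chosen so
Fe–S cluster and Fe–N porphyrin coordination count as covalent — required
for conduction *through* a cofactor. Through-space edges are pruned beyond
6 Å to bound graph size; enlarging the cutoff can only add edges and
therefore never lowers the best coupling (a tested invariant). Conjugated
macrocycle atoms are ordinary covalent nodes; the model is atom-level and
assigns no special aromatic factor.

The search runs Dijkstra under the additive weight −ln ε, strictly positive
because every ε < 1 (a clamp at 1 − 10⁻¹² guards pathological overlapping
inputs), so optimal paths are simple. Exact coupling ties are common — any
two routes with the same number of covalent steps tie — so the heap priority
is the pair (cost, serial sequence): among equal-cost labels the
lexicographically smallest atom-serial path settles first. Because all
predecessors of an equal-cost label settle strictly earlier, the first label
to settle at a node is the lexicographic minimum among minimum-cost paths,
by induction along predecessors; the test suite verifies exact path and
coupling agreement with exhaustive simple-path enumeration on hundreds of
random graphs. A donor/acceptor pair with no route returns an explicit
disconnected result rather than raising.

Donor-atom ranking scores each candidate exit atom of a donor cofactor with
the *other* donor-group atoms removed from the graph: otherwise every atom
of an internally conducting cluster would inherit the best atom's route and
the ranking would be flat. This is a package design choice; it matches the
question the ranking answers ("which atom of the cluster hands the electron
over?").

## Rate ruler

The exergonic branch `log₁₀ k = 13 − (1.2 − 0.8ρ)(R − 3.6) −
3.1(ΔG + λ)²/λ` takes R as the edge-to-edge distance in Å, ΔG in eV
(negative downhill), λ in eV, and ρ the packing density of the intervening
medium in (0, 1]. At van der Waals contact (R = 3.6 Å) and activationless
driving force (ΔG = −λ) it reaches the 10¹³ s⁻¹ ceiling. The expression is
calibrated for R ≥ 3.6 Å; smaller R is accepted but outside the fitted
range.

Endergonic steps use detailed balance: the uphill rate is the reverse
(downhill) rate attenuated by 10^(−ΔG/0.06) — one decade per 0.06 eV at
298 K (the decade constant is configurable). Evaluating a +ΔG step directly
in the exergonic expression instead would misprice it by orders of magnitude,
because that expression's quadratic term describes activation, not the
equilibrium penalty of climbing ΔG. The two branches join continuously at
ΔG = 0, the identity `log₁₀k(+ΔG) − log₁₀k(−ΔG) = −ΔG/0.06` holds exactly,
and the maximum over ΔG at fixed R sits at ΔG = −λ; all three are tested.
With representative uphill-step inputs (R = 6.5 Å, ΔG = +0.33 eV from
potentials +340/+10 mV, λ = 0.7 eV, ρ = 0.77) the ruler gives
1.6 × 10⁵ s⁻¹.

ΔG is computed from one-electron midpoint potentials as E_donor −
E_acceptor, with no membrane-potential or electrostatic corrections. Chain
reports leave rate columns empty for steps missing a potential rather than
substituting guesses.

## Synthetic fixtures

The generators produce the study conditions for every test, with ground
truth by construction:

* **chain molecule** — n covalent C–C bonds at 1.54 Å on a line; the only
  tunneling route is the chain, coupling 0.6ⁿ.
* **donor–bridge–acceptor** — two 3-carbon chains, edge atoms exactly `gap`
  apart, optional relay atom at gap/2 (requires gap ≥ 4.2 Å so the relay
  stays non-covalent); with gap 7 Å the two 3.5 Å hops beat the direct jump.
* **porphyrin** — idealized planar 24-atom macrocycle (four pentagonal
  rings, radius 1.15 Å, centers at 3.0 Å; four meso carbons at 3.4 Å);
  rings III–IV and the meso carbon between them rotate rigidly about the
  I–III diagonal, so the applied bend equals the inter-plane angle exactly.
* **two-body complex** — two jittered cubic lattices (3.5 Å spacing, ±0.15 Å
  jitter, ≥ 2.9 Å heavy-atom separation) of single-carbon residues, facing
  k×k surfaces; one designed Thr-hydroxyl/Trp-indole pair at the face
  centers, realized at the requested H-bond distance only while the bodies
  are within bonding range (protrusion ≤ 1 Å) so that large separations
  yield zero buried area and no spurious bond; per-residue B-factors follow
  B = 5 + 2·|x| with x the distance from the interface midplane.
* **rigid + noise copies** — a seeded uniform random rotation (quaternion
  method), a translation in [−10, 10]³ Å, then i.i.d. Gaussian noise of
  σ per coordinate; expected recovered RMSD σ√3.

Each generator consumes one `numpy.random.default_rng(seed)` stream in a
fixed documented order, so outputs are byte-stable across runs. The blobs
are *not* proteins: no stereochemistry, no rotamers, no force-field
relaxation. Passing tests therefore demonstrate the correctness of the
geometric and model logic, not robustness to real-structure pathologies
(alternate conformations at interfaces, missing atoms, metal sites with
unusual coordination), which only real coordinate files exercise.

## Problem sizes and verification

The test suite and acceptance script run on fixture-scale inputs chosen for
tight oracles: 200 random graphs of ≤ 12 atoms for exhaustive path
enumeration, 500-atom clouds for noise-recovery RMSD, 5-point sets for the
SO(3) grid-search superposition oracle, ~50–130-atom bodies for surface
areas (cross-checked against an independent Shrake–Rupley implementation and
a seeded 5×10⁵-point Monte-Carlo integration). The pipeline applies
identical code paths to full-size structures; runtime grows roughly linearly
in atom count for surfaces and with the through-space edge count for graphs.

## Known limitations

* No Connolly (molecular) surface, no electrostatics.
* H-bond detection has no angular term and no protonation-state logic.
* Single best path per donor/acceptor pair; no multi-path interference.
* The rate ruler is an empirical average over protein media; ±1 decade
  scatter around it is typical of real systems.
* Chain/cofactor identities are taken from explicit configuration, never
  inferred from file contents.
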