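# Methods

This note documents the models, conventions and numerical choices behind
`quartersite`, and what the synthetic-ensemble validation does and does not
establish.

## Coordinate conventions

**Quarter-site frame.** A 20-bp response element is Q1–Q4 left to right on
the reference strand.  Each quarter has a *monomer-local* sense strand
reading RRRCW 5′→3′: the reference strand for Q1/Q3, the complementary
strand for Q2/Q4.  Table-style column labels are therefore 1…5 for Q1/Q3
and 5′…1′ for Q2/Q4; an unprimed local position addresses the sense-strand
base, a primed position its Watson–Crick partner in the same column.
Position 0 is the base pair immediately 5′ of position 1 *in the local
orientation* (one bp by default; the offset is configurable because the
role of the flanking cap sequence in anchoring is not settled).  For Q1 of
a bare 20-mer, position 0 falls outside the element and requires explicit
flanking sequence — the synthetic templates carry the ATAATT/ATTAA caps, so
it always resolves there.

**DNA numbering.** Both strands are numbered 1..n in their own 5′→3′
direction; reference residue *c* pairs with complementary residue
*n + 1 − c*.  All chain/residue bindings live in a `MappingConfig` (TOML)
rather than being guessed from the coordinates.

## Hydrogen bonds and salt bridges

A contact is formed in a frame when the minimum donor–acceptor heavy-atom
distance is ≤ 3.5 Å.  There is no donor–H–acceptor angle term: the
criterion is purely distance-based, matching how occupancy percentages for
these interfaces are conventionally defined.  The boundary rule is ≤ (a
distance exactly at the cutoff counts as bonded); it is configurable
(`boundary="lt"`) because prose ("less than") and footnote ("cutoff of
3.5 Å") conventions differ.  Major-groove acceptors by base: G → {O6, N7}
(both within cutoff = three-centered bond), A → {N7}, T → {O4}, C → none
(rows for cytosine are structural zeros, annotated as such).  Equivalent
guanidinium nitrogens are aggregated by the min-pair rule; the NH1–O6 /
NH2–N7 per-pair series and their average are also emitted for the Arg280
contact.  Salt bridge A (DNA–R280) is the specific base contact against the
G4′ acceptors; D (R273–DNA) uses phosphate O1P/O2P of the quarter's
sense-strand residues (the backbone atom set is configurable).

**Windows.** Occupancies default to the final 2/3 of the trajectory and
fluctuation analyses to the final 1/6, mirroring the last-20-ns /
final-5-ns conventions of 30-ns runs.  A tail fraction *f* resolves to
frames [⌈(1−f)·n⌉, n); an epsilon guards exact fractions and the start is
clamped to n−1 so a one-frame ensemble is its own tail.

## Geometry descriptors

Superposition is the standard SVD (Kabsch) solution with a determinant
correction; it refuses fewer than three atoms or collinear references.
RMSF is computed about the windowed mean structure after per-frame
superposition (two-pass: align to the first window frame, average,
re-align to the mean).  The alternative reading — deviation from the
initial structure — is available via `reference="initial"`; the default is
the standard mean-referenced RMSF.  The organizational angle/dihedral is
reported both per frame and evaluated on the window-average structure; the
average-structure value is the tabulation convention, and the two differ on
fluctuating ensembles, so both are always emitted.  Dihedral signs follow
the IUPAC convention (verified against MDAnalysis).

## DNA model and bend metric

Ideal B-DNA is assembled from the standard base reference-frame coordinates
(embedded as constants), rise 3.38 Å and twist 36°/bp; the complementary
base is the standard geometry rotated 180° about x.  This reproduces
canonical Watson–Crick N1–N3 distances (~3.0 Å) and the 6.1 Å
N7(A)–O4(T) major-groove acceptor spacing without any fitted parameters.
Backbone atoms (C1′, C3′, P, O1P, O2P) are placed at B-DNA-like radii but
are otherwise approximate: they serve distance plumbing and descriptor
anchors, not helical analysis.

Base-pair frames are obtained by least-squares fitting each base's standard
ring geometry to the observed ring atoms and averaging the two (the
complementary rotation flipped), orthonormalized by SVD.  The **bend
angle** fits a straight principal axis to the base-pair origins of the
first and last ⌈n/3⌉ pairs (configurable), orients both 5′→3′, and reports
the angle between them.  Degenerate (coincident-origin) segments report 0°
with a flag.  This is deliberately not the Curves curvilinear axis:
absolute values are not comparable with Curves output, and published
trajectory-derived bend tables are *not* reproduction targets here — the
metric is validated on planted kinks (10–45°, recovered within 2°) and is
intended for ensemble-relative comparisons.

## Cross-correlation maps

The "covariance map" is the normalized dynamic cross-correlation of
displacement vectors about the windowed mean after superposition (same fit
convention as RMSF — a documented coupling).  The raw ⟨Δr·Δr⟩ block-trace
matrix is available behind `raw=True`.  Atoms with numerically zero
variance (≤ 1e-18 Å², the float-noise floor of an identity superposition)
get NaN rows/columns — undefined, never silently 0.

## The synthetic generator: the stated world

The generator emulates the *statistical* structure of interface
trajectories, not their physics (no force field, no sterics):

* **Bonding.** Each planted contact is independently bonded per frame with
  its probability.  Bonded distances ~ N(2.9, 0.15) Å truncated below
  2.4 Å; unbonded ~ N(5.5, 0.5) truncated below cutoff + 0.2 Å.  With
  these distributions the 3.5 Å rule misclassifies a drawn state at a rate
  below 0.1 % (tested), dominated by the ~3·10⁻⁵ upper-tail mass of the
  bonded distribution.
* **Placement.** Donor atoms are re-placed each frame at the drawn distance
  from the (jittered) acceptor along a direction chosen at template-build
  time by a deterministic Fibonacci-sphere search maximizing clearance from
  every *competing* acceptor in both regimes — this keeps neighbouring
  fingerprint rows clean (spurious occupancy ≲ 0.1 %).  Chained contacts
  (R280 → E281 → R273) are placed in network order, so each link realizes
  its own drawn distance.
* **Lys120 multi-position planting.** One physical NZ donor serves
  positions 1–3.  When several positions are planted, states are drawn
  independently and frames with ≥ 2 bonded positions are resolved by
  Gauss–Newton trilateration.  Adjacent positions (acceptors ~3.5–4 Å
  apart) are exactly satisfiable and recover cleanly; simultaneous bonding
  at positions 1 *and* 3 (~7 Å apart) is geometrically infeasible for one
  donor and degrades recovery by roughly the joint probability — a physical
  constraint, not a bug.  The default truth plants one dominant position
  per quarter, which is exactly recoverable.
* **Defaults are the published world.** The default truth reproduces the
  14-3-3σ first half site: Lys120 position 2 at 0.87 (Q1) and position 1
  at 0.91 (Q2), salt bridges 1.0/0/0.96/0.91 (Q1) and 0/1.0/0.70/0 (Q2),
  and an 18.80° bend.  Arg248 levels (0.85/0.55) are untabulated anywhere
  and were chosen once as plausible ejected-then-backbone-docked values.
  Positional jitter is σ = 0.3 Å per coordinate (crystallographic-B-factor
  scale).  The planted anti-correlated Cα pair (residues 120 vs 180,
  loop-vs-dimerization-interface) uses a 2 Å shared mode against the 0.3 Å
  jitter, i.e. a true correlation of −amp²/(amp² + 3σ²) ≈ −0.94: the
  planted coupling is strong by construction, and recovering C < −0.8 tests
  the estimator, not the noise.
* **Bend.** The second DNA half (and the monomer bound to it) is rigidly
  rotated about a roll axis through the midpoint base pair; contacts follow
  because donors are re-placed relative to current acceptor positions.
* **Reproducibility.** One `numpy` Generator per ensemble; identical seeds
  give bit-identical coordinate arrays and files, distinct seeds distinct
  files (checksummed in tests).

**What a green test establishes.** Recovery tests prove the analysis stack
measures what was planted, under Gaussian noise and Bernoulli bonding.
They do not establish anything about real interface energetics, water
mediation, correlated bond lifetimes (frames are i.i.d. unless a coupling
is planted), force-field behaviour, or the published trajectory-derived
values — those require the original (undeposited) simulations.

## Pipeline determinism

Reports are TSV with a fixed `%.6f` float format plus sorted-key JSON;
manifests record file names (not paths) and SHA-256 checksums of inputs and
outputs.  Two simulate+fingerprint runs with the same seed are
byte-identical, which the acceptance suite asserts.

## Known limitations

* Pseudo-protein monomers are minimal anchor-atom sets; analyses that need
  full backbones (secondary-structure-aware fits, real per-residue RMSF
  profiles) will see only the anchor spine.
* The bend metric and the base-pair frames are convention-compatible but
  not numerically interchangeable with Curves/3DNA outputs.
* Multi-model PDB is the only trajectory container; binary formats are out
  of scope by design.
* The occupancy criterion is distance-only; an angular filter would need a
  hydrogen-atom model the ensembles do not carry.
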