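# Methods

`tfdimer` reconstructs the structure of a symmetric, dynamic protein
homodimer from solution-NMR and biophysical observables.  The motivating
system is the *E. coli* chaperone Trigger Factor (TF), a 432-residue,
three-domain protein (ribosome-binding domain RBD, substrate-binding domain
SBD, peptidyl-prolyl isomerase domain PPD) that forms a head-to-tail dimer
at micromolar concentrations.  The package implements the full inference
chain — equilibrium and kinetic characterization, interface mapping,
distance-restraint derivation, and restrained symmetric annealing — together
with a ground-truth synthetic-data generator so that every stage can be
validated end to end without experimental spectra.

## Monomer–dimer equilibrium (SEC–MALS)

For a fast two-state equilibrium 2M ⇌ M₂ with dissociation constant K_D,
the weight-averaged molar mass at monomer-equivalent concentration [M] is

    M_w = 2M − M · (−K_D + √(K_D² + 8[M]K_D)) / (4[M]).

`fit_kd` fits log₁₀K_D by weighted nonlinear least squares with the monomer
mass fixed from sequence; the bounds [10⁻³, 10⁵] µM reflect the
orders-of-magnitude spread of affinities across domain constructs.  The 95%
CI comes from the linearized covariance on the log scale, which keeps the
interval positive and approximately log-symmetric.  A curve whose total M_w
rise is below 3σ of the fractional mass noise (default σ = 1%,
representative of MALS mass errors) is reported as a lower limit
K_D > c_max rather than a point estimate, mirroring how non-dimerizing
constructs are tabulated.  Simulation at the default design (12 points,
0.2–200 µM, 1% noise) gives median |bias| < 5% and CI coverage within
[90%, 99%] over 200 replicates; both are recomputed by the test suite.

## Dimer lifetime from spin-label mixing

Equal pools of isotope-labeled and spin-labeled protomers, each fully
dimeric, are mixed at t = 0.  Each dimer dissociates with rate constant
k_off, and re-association is treated as instantaneous relative to
dissociation (at 50 µM protein and K_D ≈ 2.5 µM the free-monomer pool is
small).  A tagged protomer's partner identity therefore randomizes at rate
k_off, with equilibrium probability ½ of a spin-labeled partner, giving the
exactly mono-exponential observable

    I(t) = I_∞ + (I₀ − I_∞)·e^(−t/τ),  τ = 1/k_off,
    I_∞ = I₀ (1 + β)/2,

where β (default 0.3, a free simulator parameter) is the intensity
attenuation of an isotope-labeled protomer whose partner carries the spin
label.  The deterministic simulator evaluates this closed form; the
stochastic simulator is an exact event-driven realization in which a
dissociating dimer releases its protomers into a small explicit free-monomer
pool and two uniformly random pool members re-pair instantly.  The
deterministic trace is the oracle: the stochastic mean converges to it as
1/√n, and a three-parameter exponential fit recovers k_off within 2% at
n = 10⁵ dimers observed for six lifetimes.  Dead times of 140–160 s between
mixing and the first usable point are carried as trace metadata for the five
temperatures (15–35 °C) of the experimental design.

## Chemical-shift analysis

Amide perturbations combine as Δδ_HN = √(Δδ(¹H)² + (0.2·Δδ(¹⁵N))²).
Significance uses "corrected-to-zero" statistics: values above
mean + 3·SD are excluded iteratively until stable, and the threshold is the
retained mean + k·SD (k = 1 for docking-active residues, k = 2 for display).
Residues broadened beyond detection carry a flag instead of a magnitude and
are always treated as interface (active) residues; overlapped peaks are
unusable and excluded.  Passive residues are the non-active residues whose
CA lies within 6.5 Å of any active-residue heavy atom.  Secondary ¹³C
shifts are (ΔδCA − ΔδCB) relative to a built-in random-coil table (standard
published CA/CB values; user-replaceable), optionally smoothed with a 1-2-1
window whose weights renormalize at gaps and termini.  The ΔδCA − ΔδCB
combination is a documented package choice; glycines use the CA term alone.

## PRE rates and distance restraints

Peak-volume ratios convert to rates and distances via

    V_ox/V_red = exp(−PRE · 2τ_INEPT),
    r = [ K/PRE · (4τ_c + 3τ_c/(1 + ω_h²τ_c²)) ]^(1/6),

with τ_c = 42 ns (global tumbling), ω_h the proton Larmor frequency at
700 MHz, and K = 1.23·10⁻³² cm⁶ s⁻².  The total transfer delay 2τ_INEPT is
not published; it is calibrated once so that ratio 0.15 maps to 16.12 Å
(the published boundary), which fixes the other boundary at 24.28 Å because
r(0.85)/r(0.15) = (ln 0.15/ln 0.85)^(1/6) = 1.5062 independently of all
constants.  The calibrated delay (≈16.1 ms) is recorded in exported
restraint metadata.  Volume noise propagates to first order through both
equations; the analytic σ_r agrees with Monte-Carlo propagation within 5%
at ratio 0.5 and diverges as ratio → 1, where the distance becomes
insensitive.

Classification follows the three published classes: ratios in (0.15, 0.85)
give a bounded restraint at the computed distance with ±4 Å margins
(absorbing spin-label tag flexibility), kept only if σ_r < 1 Å; ratios
≤ 0.15 or broadened peaks give an upper-limit restraint [1.8, 20.12] Å;
ratios ≥ 0.85 give a lower-limit restraint ≥ 20.28 Å applied to both the
intra- and the intermolecular pairing.  Bounded and upper restraints are
ambiguous between the pairings and are evaluated with the standard
r⁻⁶-summed effective distance — which is also exactly the quantity the
forward model produces when the two label copies' rates add, so a truth
pose scores zero restraint energy against its own noise-free restraints.
Restraints against the monomer structure separate intra- from
intermolecular effects with a 25 Å explanation cutoff (the label's
detection range).  The label-site endpoint is the mutated residue's Cβ; no
explicit tag atom is modeled.

Elastic-fold-network (EFN) restraints preserve local geometry: every CA–CA
pair at 3–15 Å with sequence separation ≤ 10, excluding pairs touching or
spanning the flexible linkers (112–115, 149–155, 241–261 in TF numbering),
restrained to its reference distance ± 0.5 Å, static throughout.
Distance-symmetry restraints enforce d(A_i, B_j) = d(B_i, A_j).  Note that
these equalities are blind to translations perpendicular to the two-fold
axis (which merely relocate the axis); only the annealer's symmetric move
set makes the symmetry exact rather than penalized.

## Two-phase symmetric annealing

The docking/annealing engine replaces torsion-angle dynamics with
rigid-domain Metropolis Monte Carlo.  Protomer A is split into rigid bodies
at the flexible linkers (linker residues join the nearer body; one virtual
CA–CA bond per junction is capped at 4.0 Å per peptide step, an
extended-chain bound).  Chain B is regenerated every step as the exact
180°-rotation image of chain A about a fixed axis, so C2 and
non-crystallographic symmetry hold by construction.  The energy is the sum
of flat-bottom harmonic restraint terms (weights: PRE classes 1.0, EFN 0.5
since rigidity already enforces most local geometry, AIR 1.0), a
soft-sphere CA repulsion below 3.5 Å, and the linker-connectivity terms.
Ambiguous interface restraints (AIR) from CSP-active residues bound the
r⁻⁶-pooled heavy-atom effective distance to the partner's active∪passive
set by 3 Å.

Phase 1 (docking) uses AIR + symmetry + repulsion from random initial
placements; its best model can seed phase 2, which activates the full
PRE + EFN set.  Each run cools geometrically (default 100 → 0.05 over 3000
steps) with move amplitudes tied to the temperature (whole-protomer or
single-domain moves, 25°/5 Å at the start).  Because the flat-bottom
potential leaves a degenerate zero-energy basin several Å across, the
acceptance rule includes a weakly weighted (0.05) "center term" — the mean
squared deviation of bounded-class effective distances from their targets —
and each run ends with a greedy small-step polish on the same composite
score.  The targets of the bounded class are the measured distances; the
±4 Å margins exist to absorb tag flexibility, so preferring the basin's
most target-consistent pose is a tie-break, not a reweighting of the data.
Models are returned sorted by (restraint energy, center term, run index);
`select_models` keeps the n lowest-energy models (default 10 of 100).
All randomness derives from one master seed by fixed splitting, and per-run
seeds are recorded in each model's provenance; identical inputs and seed
reproduce models bit-for-bit.

## Synthetic data and what it does (not) show

`make_toy_protomer` builds protomers at CA/CB/amide-H pseudo-atom
resolution: each domain is a compact self-avoiding CA trace (3.8 Å steps,
≥3.5 Å non-bonded separation) grown with a drifting bias that yields
roughly 2:1 prolate shapes — globular proteins are rarely spherical, and
near-spherical toy domains leave the restraint set degenerate under the
±4 Å margins.  Domains are joined by extended linkers; every residue
carries the three endpoint types the restraint chain uses.
`place_head_to_tail` positions the protomer so its C2 image forms the
avidity arrangement (head domain of each chain against the tail domain of
the other, 4.5 Å minimum CA gap).  Six label sites (two per domain, chosen
among the eight most interface-proximal residues to maximize spatial
spread, mirroring the experimental probe-placement strategy) generate peak
tables through the forward model with additive intra+inter rates; ratios
below 0.05 are emitted as broadened (a generator convention distinct from
the 0.15 classification boundary), and the labeled residue itself is
skipped.  SEC–MALS curves, CSP-like active-residue sets (true contacts
< 5 Å), and mixing decays at the five temperatures complete the bundle;
every artifact carries its generating parameters and regenerates
bit-identically from the seed.

The generator emulates restraint geometry and observable statistics, not
spectroscopy: no line shapes, no chemical-exchange broadening, no tag
rotamers, no assignment ambiguity beyond the intra/inter pairing.  Passing
the recovery tests therefore demonstrates that the inference chain is
self-consistent and correctly implemented at the stated noise levels — not
that real spectra of comparable information content would determine a real
dimer to the same precision.

## Numerical choices and problem sizes

Superposition uses Kabsch least squares; rotation angles come from the
matrix trace, reported in [0°, 180°].  Domain rotations between two models
align on one range's CA atoms and measure the second transform's angle and
centroid displacement — one defensible convention among several; agreement
with values measured by other conventions on deposited coordinate sets is
expected to be approximate.  PDB I/O keeps the first altloc and first model
unless a model is requested.  The default test and acceptance studies use a
3×36-residue protomer with 4-residue linkers, 6 label sites, 20 annealing
runs of 2500 + 800 steps, 200 K_D replicates, and 10⁵-dimer stochastic
traces; these sizes make the full validation run in minutes on one core
while leaving every recovery criterion comfortably determined.

## Known limitations

- The zero-energy basin of the flat-bottom potential genuinely spans a few
  Å; single runs land anywhere in it, and only the center-term tie-break
  plus best-of-N selection give Å-level pose accuracy.
- Lower-limit ("both pairings") restraints carry no attractive information;
  fixtures whose interface produces mostly weak PREs are underdetermined.
- The equilibrium fit assumes the monomer mass is known exactly and noise
  is multiplicative Gaussian; correlated elution-dependent errors are not
  modeled.
- The stochastic mixing fit shows a small (< 1%) systematic underestimate
  of k_off from the autocorrelated population noise and the finite
  monomer-pool residence; it is well inside the 2% validation band.
- No explicit-solvent refinement, force-field energetics, or ensemble
  reweighting: the engine stops at restraint-consistent rigid-domain
  models.
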