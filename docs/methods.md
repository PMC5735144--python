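# Methods

## Scope and data model

The package post-processes *stripped-solute* snapshot data: a per-atom
topology (residue, protein/ligand group, partial charge in e, LJ σ in Å and
ε in kcal/mol, mass) plus frames of Cartesian coordinates in Å with times
in ps. It deliberately does not run dynamics, derive charges, solve the
Poisson–Boltzmann equation or diagonalize Hessians; polar solvation
(ΔG_pb) and normal-mode entropies enter as externally computed numbers.
The topology is a plain delimited table of our own dialect rather than a
force-field file: the analysis needs nothing beyond charges, LJ parameters
and grouping, and a text table keeps the format inspectable and
round-trippable at full precision. Multi-model PDB (read/written through
biotite) is the trajectory interchange format; a long-format XYZ/CSV table
is accepted where PDB's three-decimal coordinates would lose precision.
Frame stride is taken from the input file as-is; the code never resamples.

## Interaction energies

Only inter-group (protein × ligand) pairs are summed — the groups share no
bonds, so no exclusions arise. Electrostatics: k·q_iq_j/r with
k = 332.0637 kcal·Å/(mol·e²). Van der Waals: 4ε[(σ/r)¹² − (σ/r)⁶] with
Lorentz–Berthelot combining (ε_ij geometric, σ_ij arithmetic). Default is
all pairs, no cutoff and no periodicity: post-processing operates on the
stripped solute, and at desk scale reproducibility beats speed; a cutoff
flag exists. AMBER-style R_min/2 parameters must be pre-converted to σ
(σ = R_min/2^{1/6}); only one convention is stored. Alternative charge
sets (e.g. polarization-adapted per-system charges) are simply different
topology files — the pipeline is charge-set-agnostic. Coincident
protein/ligand atoms raise a geometry error naming the pair.

The per-residue decomposition assigns each protein residue the
frame-averaged sum of its atoms' pair energies with all ligand atoms; the
entries sum to the mean inter-group total to 1e−6 kcal/mol (asserted in
tests). The polar-solvation part of a published per-residue spectrum is
not reproducible without a PB solver; the surface term is attributed per
residue by its share of buried SASA instead (below).

## Interaction entropy

−TΔS = kT ln⟨e^{βΔE}⟩ over the fluctuations ΔE = E − ⟨E⟩ of the total
interaction energy, β = 1/kT, with k = 0.0019872041 kcal/(mol·K) and
T = 300 K by default (kT = 0.59616 kcal/mol); both are configurable since
the constants matter at the second decimal. The exponential average is
always computed in the log domain with a max shift (`logsumexp`), and the
running trace accumulates `logaddexp`, so fluctuations of even 10³ kT
cannot overflow. Jensen's inequality guarantees the estimate is
nonnegative; values within floating noise below zero are clamped to zero.

Known limitation, surfaced rather than hidden: for fluctuation SD σ above
about 2 kT the exponential average is dominated by rare high-energy frames
and converges extremely slowly; a RuntimeWarning fires. The Gaussian
closed form σ²/(2kT) makes this quantitative — the Monte-Carlo relative SE
of the exponential average is √((e^{(σ/kT)²} − 1)/N), which the tests use
to set tolerances per σ.

Uncertainty: the block SD cuts the series into contiguous equal blocks
(default 10; remainder frames dropped from the end), estimates IE per
block with that block's own mean, and reports the sample SD (n−1).
Published IE uncertainties rarely state their procedure, so this is the
package's own, documented choice.

## Nonpolar solvation

Shrake–Rupley SASA with deterministic Fibonacci-spiral sphere points
(default 960; quadrature error on an isolated sphere < 0.5 %, halving with
each doubling of points). Atom radii come from an element table (C 1.7,
N 1.55, O 1.52, H 1.2, S 1.8, P 1.8 Å — overridable, since the radii set
behind published surface areas is rarely stated) or from the topology's LJ
σ (r = 2^{1/6}σ/2). Probe radius 1.4 Å.

ΔG_np = γ·ΔSASA + β with γ = 0.00542 kcal mol⁻¹ Å⁻², β = 0.92 kcal/mol.
ΔSASA = SASA(complex) − SASA(protein) − SASA(ligand), frame-averaged.
The offset β is added **once** per evaluation: applying the linear formula
to each species separately would contribute −β to the difference instead,
and a `beta_mode="per_species"` option provides exactly that alternative
reading. Per-residue attribution is γ times the residue's summed atom
ΔSASA; β is reported separately and never attributed.

## Free-energy bookkeeping

`combine` fills the identity chain ΔG_sol = ΔG_pb + ΔG_np,
ΔG_gas = (ΔE_ele + ΔE_vdw + ΔE_int) + (−TΔS), ΔG_bind = ΔG_gas + ΔG_sol,
and every constructed breakdown re-validates the identities to 1e−9.
The single scheme forces ΔE_int = 0 (rigid-body assumption); supplying a
nonzero strain term there is a scheme error, not a silent pass-through.
The triple scheme differences complex/protein/ligand component tables and
takes ΔE_int and −TΔS as external inputs: the internal-energy change is a
bonded quantity that cannot be derived from inter-group terms. Group
statistics over snapshot sets use the sample SD with the n−1 denominator
(the convention behind published spreads is unstated; n = 20 groups makes
the choice material, so it is documented here). Groups are taken as
disjoint contiguous blocks.

## Structural analyses

Superposition is the closed-form optimal rotation (SVD with a
determinant/reflection guard). RMSD is reported for the selection
(backbone = atoms named N/CA/C) after per-frame superposition onto the
reference. B-factors superpose frames onto their mean structure, iterate
the mean twice so the reference is self-consistent, then report
(8π²/3)·⟨|r − ⟨r⟩|²⟩ — directly comparable to crystallographic B columns.

Hydrogen bonds: heavy-atom donor–acceptor distance ≤ 3.5 Å AND
donor–H–acceptor angle ≥ 120° with the vertex at the hydrogen. The
H-vertex convention is the default because published angle traces
fluctuating in the 120–170° band are consistent with it; a donor-vertex
option exists. Geometry means are over all frames by default with a
formed-frames-only flag (published tables do not state which average they
print). Native-bond detection for the fractional-native-bond trace uses
element rules: protein N/O with a hydrogen within 1.2 Å donate; protein
N/O accept; the native set is fixed from the reference frame and each
trajectory frame reports the fraction still satisfying the criteria.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their spec (seed included).

* **Gaussian energy series** emulate the fluctuation statistics of an
  equilibrated interaction-energy trace with chosen mean and σ — i.i.d. by
  default because that admits the exact σ²/(2kT) oracle; an AR(1) mode
  with chosen lag-1 correlation probes IE convergence under correlated
  sampling. Defaults (mean −44.19 kcal/mol, dt = 0.01 ps) mirror a densely
  sampled production window. Real traces have slow drifts,
  non-Gaussian tails and state switching that these series do not.
* **Toy complexes** place one donor–H–acceptor site per designed bond,
  20 Å apart, with formed geometry 2.8 Å/165° and broken geometry 5.0 Å
  (or 90°) — comfortably inside/outside the 3.5 Å/120° criteria, so
  scheduled occupancies are exact by construction. Optional per-atom
  Gaussian jitter and per-frame rigid motion support the RMSD/B-factor
  invariance tests. These fixtures have no sterics, no secondary
  structure and no competing bond networks.
* **Component tables** draw snapshot-group free-energy components around
  fixed means with known SDs (defaults sized like published triple-scheme
  spreads: SDs of 1.7–4.2 kcal/mol per component) for the group-statistics
  machinery.

Passing tests on these inputs validate the estimators and bookkeeping,
not force-field accuracy or sampling adequacy on real systems.

## Problem sizes and numerics

The default suite and the acceptance script use 10⁶-frame energy series
for IE oracles, 10⁴-frame/50-atom fixtures for B-factor recovery,
100–200-frame toy complexes for occupancy, and ≤ 12-atom systems for the
brute-force energy and rotation-search oracles — sizes chosen so every
closed form is sharp while the whole suite runs in seconds. Tolerances:
energy oracles 1e−10 (relative where LJ magnitudes blow up), identity
chains 1e−9, quadrature 0.5 %, Monte-Carlo checks at 3 standard errors.
Ties and degenerate inputs fail loudly: zero-length vectors, empty series,
single-frame B-factors, schedules that do not tile the frame range and
mixed-scheme group statistics all raise typed errors.

## Known limitations

* ΔG_pb and normal-mode −TΔS are inputs; their quality bounds the final
  ΔG_bind regardless of anything computed here.
* IE at large σ (≳ 2 kT) is a property of the estimator, not of the
  implementation; the warning is the honest surface for it.
* No periodic boundary handling, Ewald sums, or bonded terms: the package
  assumes pre-imaged, stripped solute coordinates.
* The trypsin-scale published observables (mean RMSDs, real occupancy
  tables, 10⁶-frame IE values) require the original long trajectories;
  here they function as fixed component inputs to the bookkeeping stage.
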