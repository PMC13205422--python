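# Methods

`gelmesh` analyses drug retention and release in chemically cross-linked
P(NIPAM-co-AAc) nanogels: it builds explicit network topologies, measures
the pore geometry that controls steric sieving, extracts transport and
interaction statistics from trajectories, and connects those descriptors
to release kinetics. Because the molecular-dynamics trajectories and raw
release measurements for such systems are rarely deposited, every analysis
stage is exercised against seeded synthetic inputs whose ground truth is
known analytically; the published per-system summary tables (descriptor
and kinetic-parameter tables for the sixteen PN-0/CA-5/CA-15/CA-20 ×
pH × temperature systems) are shipped as package data and serve as
generating parameters and join keys.

## Network construction

A nanogel model is a representative local cross-linked domain, not a whole
particle. Four pre-polymerized linear chains (degree of polymerization 20,
carrying 0/1/3/4 acrylic-acid units → 0/5/15/20 mol% AAc) and 50
N,N′-methylenebisacrylamide (BIS) cross-linkers are packed into a cubic
periodic box sized so the total mass over volume equals 0.8 g cm⁻³, by
seeded rigid-body insertion with rejection until every intermolecular atom
pair clears a 2.0 Å tolerance under the minimum-image convention
(largest molecules first; a configurable attempt budget guards against
infeasible densities).

Monomers are represented at united-atom resolution: heavy atoms carry
implicit hydrogens (CH = 13.019, CH₂ = 14.027, CH₃ = 15.035 g/mol), so
formula masses are exact (NIPAM 113.16, protonated AAc 72.06, BIS
154.17 g/mol) while the atom count stays small. The analyses downstream
need topology and geometry only, so no force-field typing or charge
assignment is attempted.

Cross-linking is iterative and template-based. At each cycle, candidate
pairs of unreacted reactive sites on different molecules within the
current distance cutoff are collected and screened against pre-reaction
connectivity templates (the depth-1 bonded neighborhood of each endpoint,
as an element + neighbor-class multiset, must equal the template for its
monomer type — a site whose connectivity has already changed no longer
matches). Accepted pairs are bonded greedily in ascending-distance order,
one reaction per site per cycle with ties broken by atom id, after which
the structure is relaxed. The cutoff ladder runs 3.5 → 5.0 Å in 0.5 Å
steps with three searches per cutoff, stopping at 80% reactive-site
conversion or ladder exhaustion. Unreacted BIS molecules are then pruned.
Design choices the protocol leaves open were resolved as follows:

* **Conversion denominator** — all flagged reactive sites (one per chain
  monomer plus both BIS vinyls).
* **Pair rules** — BIS–BIS reactions are forbidden by default
  (configurable); chain–BIS and chain–chain are allowed.
* **Relaxation** — bounded-step steepest descent on a surrogate energy
  (harmonic bonds at element-pair rest lengths + purely repulsive
  soft-sphere contacts at 2.0 Å onset), with backtracking so the energy is
  provably non-increasing and the topology untouched.

A deterministic minimizer cannot emulate the thermal shuffling of an MD
equilibration, so at study-scale packing the ladder typically exhausts
with conversion well below the 80% target; this is recorded per cycle in
the cross-link report rather than treated as an error. Conversion is
monotone and the whole construction is reproducible from its seed. Acidic
and basic protonation models (two-state: all carboxyls –COOH at pH 2.75,
all –COO⁻ at pH 7.4, pKa 4.75; justified by the Henderson–Hasselbalch
estimate of 0.99% vs 99.8% deprotonation) yield identical topology and
differ only in flags.

## Pore geometry

The box is discretized into a cubic lattice (default spacing 0.4 Å,
convergence-tested on phantoms) and each node is assigned its
minimum-image distance to the nearest atomic van der Waals surface (Bondi
radii by element, configurable). The **maximum pore diameter (MPD)** is
twice the largest clearance — the largest spherical probe that fits
anywhere. The **pore limiting diameter (PLD)** is the diameter of the
largest probe that can percolate through the pore network across the
periodic boundaries: nodes with clearance ≥ d/2 are cluster-labeled
(6-connectivity) and merged across periodic faces by a union-find that
tracks lattice-image offsets — a cluster whose merge constraints close a
cycle with non-zero net offset wraps the box and percolates
(Hoshen–Kopelman with periodic extension). Percolation along any one
dimension suffices by default. Because the percolation indicator can only
change at node clearance values, the supremum is located by bisection over
the sorted unique clearances, which is exact to the grid resolution; an
exhaustive threshold sweep is kept as a test oracle. Probe clearances are
capped at half the smallest box edge, so an empty box reports PLD = MPD =
box edge. The convention is center-accessible (probe centers travel on
lattice nodes).

Steric accessibility compares (PLD, MPD) against the drug's principal-axis
dimensions (ibuprofen: X = 6.78, Y = 7.47, Z = 12.03 Å, carried as
constants from a quantum-chemical electron-density surface rather than
recomputed from hard spheres). The published three-scenario description
overlaps for bottleneck-confined systems with large pockets, so the
classifier resolves it with an explicit rule order producing four labels:
MPD > Z with PLD < Y → `bottleneck_with_free_pockets` (confined yet
releasable), MPD > Z with PLD ≥ Y → `free`, Y < MPD ≤ Z with PLD ≥ Y →
`transition`, otherwise `bottleneck_limited`. Per-trajectory aggregation
samples 20 frames uniformly from the final 10 ns and reports mean ±
(unbiased) SD; PLD ≤ MPD holds frame-wise by construction and for all
sixteen published descriptor rows.

## Trajectory statistics

* **Dissociated fraction** — for each of the drug molecules (50 in the
  study conditions), the atom–atom minimum-image minimum distance to the
  polymer is averaged over the final-10 ns window; a molecule whose
  average *exceeds* 5 Å (strictly; equality stays associated) is
  dissociated, and the fraction is reported in percent. With 50 molecules
  every attainable value is a multiple of 2%, which the published
  fractions all satisfy.
* **Diffusion** — center-of-mass MSD per molecule, averaged over molecules
  and all sliding time origins (an FFT formulation keeps this O(n log n)).
  The default lag grid stops at one tenth of the trajectory span: at lag τ
  a span-T trajectory holds only ~T/τ independent displacement segments,
  and for the study-scale ensembles (50 molecules, 10 ns at 1 ps) the
  τ ≤ T/10 rule keeps the per-run sampling SD of the fitted D near 5%,
  whereas fitting near τ ~ T/2 inflates it to ~15% and makes the Einstein
  fit statistically useless. D = slope/6 from an ordinary least-squares
  fit over the final 10% of lags by default, converted via
  1 Å²/ps = 10³ × 10⁻⁷ cm² s⁻¹. Wrapped coordinates are rejected rather
  than silently unwrapped.
* **Radial density** — drug-molecule COM distances to the polymer COM,
  binned to half the box diagonal so per-frame counts conserve the
  molecule number exactly; shell-volume-normalized density is also
  reported.
* **Hydrogen bonds** — geometric criterion d(D···A) ≤ 3.5 Å and
  H–D···A angle ≤ 35° (the common reading of the criterion; the
  D–H···A ≥ 145° dialect can be configured), both cutoffs closed with a
  10⁻⁹ floating-point guard. Counts are categorized by the donor/acceptor
  group pair (polymer–polymer, polymer–drug, polymer–water) and averaged
  over the window.

## Release kinetics and correlation

Cumulative release from sampled medium concentrations supports both the
literal running-sum formula Σ Cₜ·V/M·100 and (default) the standard
sample-and-replenish withdrawal correction with 1 mL withdrawn; the mode
is recorded in the profile. Four kinetic models are fitted on fractional
release (cumulative %/100, M∞ fixed at the loaded mass): zero order
(k₀t) and Higuchi (k_H√t) in closed form through the origin — which is
why their R² can be negative — and first order (1−e^(−k₁t)) and
Korsmeyer–Peppas (k_KP·tⁿ) by nonlinear least squares on the
untransformed forms (log–log initialization; a log–log fit is available
as a flag). The exponent classifies transport: n < 0.5 Fickian, n = 0.5
the Higuchi boundary, n > 0.5 anomalous.

Release performance is summarized as the trapezoidal AUC of the
cumulative-release curve over 1–24 h (exact on piecewise-linear
profiles, endpoints interpolated). Before correlation, every variable is
centered within material (per-composition mean subtracted; idempotent),
and monotone association is measured by Spearman rank correlation
(mid-ranks, two-sided p from the t-approximation with n−2 degrees of
freedom, via scipy; a from-first-principles mid-rank implementation
backs it in the tests).

## Synthetic data

Generators provide every input class with attached ground truth:
Brownian walkers with per-step variance 2·D·dt per dimension around a
static decoy polymer; dissociation scenarios placing exactly n_free of
n_total molecules at cutoff ± margin with mean-centered jitter so window
averages are exact; release curves from any of the four models with
replicate Gaussian noise truncated to [0, 100]%; pore phantoms (carved
cylindrical channel, sealed cavity, simple-cubic sphere packing with
closed-form face-window/body-center gaps, vacuum); and donor–H–acceptor
triplets at exact requested geometry. Defaults mirror the study scale
(50 drug molecules, 10 ns windows at 1 ps, triplicates), so statistic
granularity (2% steps) is reproduced. All randomness flows from explicit
seeds, and the diffusion unit constant is defined once and round-trip
tested, since an error there would silently corrupt every D.

What the generators deliberately do **not** emulate: real polymer
dynamics (the polymer is static), solvent and electrostatics, correlated
drug motion, or instrument noise structure in release assays. Passing
tests therefore demonstrate that the estimators recover known ground
truth under the study's sampling conditions — not that the physical
systems behave as the generators do.

## Problem sizes and numerical choices

The bundled analyses and acceptance computations use: full-scale network
builds (4 × DP-20 + 50 BIS, ≈ 1200 united atoms, sub-second per build);
pore grids at 0.4 Å over 16–35 Å boxes; diffusion recovery over
10 seeds × 50 molecules × 10⁴ steps per published extreme (seconds via
the FFT estimator); and the sixteen-system kinetic sweep on a 1–24 h
grid. Degenerate inputs are handled explicitly: empty frames give capped
clearance sentinels, a fully blocked box gives PLD = MPD = 0, zero drug
molecules raise rather than return NaN, coincident atoms in molecular
sizing warn, and two published parameter rows whose Korsmeyer–Peppas
curves exceed 100% at 24 h are truncated with a warning (their refitted
exponents remain below 0.5).

## Known limitations

The cross-linker reaches topological plausibility, not thermodynamic
realism; conversion targets met by MD-equilibrated protocols are
generally unreachable by its deterministic relaxation. Pore descriptors
assume orthorhombic boxes and hard-sphere surfaces. The correlation
analysis in the bundled drivers joins published descriptors to AUCs
computed from *synthetic* release curves (generated from the published
kinetic parameters), because the raw experimental profiles are not
deposited — its correlation magnitudes are exercises of the machinery,
not reproductions of the published association.
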