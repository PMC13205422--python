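# gelmesh

Analysis pipeline for drug retention and release in pH/temperature
dual-responsive **P(NIPAM-co-AAc) nanogels**, with ibuprofen as the model
drug. The package is aimed at simulators and formulation scientists who
want to connect molecular-scale descriptors of a cross-linked hydrogel
network — pore geometry, drug mobility, hydrogen bonding — with
macroscopic release behavior.

The scientific core:

* **Network construction.** Explicitly cross-linked topologies are built
  by iterative distance-plus-template reactions: candidate reactive pairs
  within a cutoff ladder (3.5 → 5.0 Å) are screened against pre-reaction
  connectivity templates, bonded greedily, and relaxed, until 80% of
  reactive sites have reacted or the ladder is exhausted. Acidic/basic
  media are modeled as two-state protonation
  (Henderson–Hasselbalch: 100/(1+10^(pKa−pH)) percent deprotonated).
* **Pore descriptors.** On a periodic distance grid, the *maximum pore
  diameter* MPD = 2·max clearance, and the *pore limiting diameter* PLD is
  the largest probe diameter whose accessible nodes still percolate across
  the periodic box (Hoshen–Kopelman cluster labeling with image-offset
  tracking). (PLD, MPD) against the drug dimensions (X ≤ Y ≤ Z) yields a
  steric-sieving state: bottleneck-limited, bottleneck-with-free-pockets,
  transition, or free.
* **Trajectory metrics.** Einstein diffusion D = (1/6)·d⟨MSD⟩/dt from
  multi-origin mean-squared displacements; the dissociated fraction
  f_det = N_det/N_drug·100% under a 5 Å average-minimum-distance
  criterion; radial number density ρ(r) about the polymer center of mass;
  hydrogen bonds by the (3.5 Å, 35°) geometric criterion, categorized as
  polymer–polymer, polymer–drug or polymer–water.
* **Release kinetics & correlation.** Zero-order, first-order, Higuchi
  and Korsmeyer–Peppas (Mt/M∞ = k·tⁿ) fits with Fickian classification
  (n < 0.5); trapezoidal AUC₁–₂₄ₕ summaries; within-material centering and
  Spearman rank correlation of descriptors with release.

Every stage runs on seeded synthetic data with known ground truth (module
`gelmesh.synthetic`), so the whole pipeline is testable without any
external download. The published sixteen-system descriptor and kinetics
tables ship as package data (`gelmesh.datasets`).

## Worked example

```python
from gelmesh.synthetic import gen_brownian, gen_dissociation_scenario, gen_release_curve
from gelmesh.trajectory import dissociated_fraction, fit_diffusion, msd
from gelmesh.release import fit_kinetics
from gelmesh.topology import henderson_hasselbalch_fraction

print(f"deprotonated at pH 2.75: {henderson_hasselbalch_fraction(2.75, 4.75):.2f}%")
print(f"deprotonated at pH 7.4:  {henderson_hasselbalch_fraction(7.4, 4.75):.1f}%")

traj = gen_dissociation_scenario(n_total=50, n_free=11, cutoff=5.0, margin=1.0, seed=1)
frac, labels = dissociated_fraction(traj, cutoff=5.0)
print(f"dissociated fraction: {frac:.1f}% ({int(labels.sum())}/50 molecules)")

walk = gen_brownian(D=0.92, n_mol=50, dt=1.0, n_steps=10_000, seed=1)
est = fit_diffusion(msd(walk))
print(f"recovered D: {est.D:.3f} x 1e-7 cm^2/s (generated 0.92, fit r^2 {est.r_squared:.4f})")

prof = gen_release_curve("korsmeyer_peppas", {"kKP": 0.370, "n": 0.256},
                         times_h=(1, 2, 4, 8, 12, 24), noise_sd=0.0, seed=1)
fit = fit_kinetics(prof, "korsmeyer_peppas")
print(f"refit exponent n = {fit.params['n']:.3f} -> {fit.mechanism} transport")
```

prints

```
deprotonated at pH 2.75: 0.99%
deprotonated at pH 7.4:  99.8%
dissociated fraction: 22.0% (11/50 molecules)
recovered D: 0.933 x 1e-7 cm^2/s (generated 0.92, fit r^2 1.0000)
refit exponent n = 0.256 -> Fickian transport
```

Reading: under acidic conditions the carboxyls are essentially protonated
(0.99% deprotonated) and under weakly basic conditions essentially
deprotonated (99.8%) — the basis of the two-state protonation models. A
constructed final analysis window with 11 of 50 drug molecules beyond the
5 Å contact criterion yields exactly f_det = 22%. A 10 ns Brownian
ensemble generated at D = 0.92 × 10⁻⁷ cm² s⁻¹ is recovered by the
MSD/Einstein estimator within sampling error on one seed (1.4% here), and a
noiseless power-law release curve refits its generating exponent
n = 0.256 exactly — diffusion-controlled (Fickian) release.

## Analysis drivers

Numbered scripts under `analysis/` rerun the study-shaped analyses and
write tables under `results/`:

| script | what it does |
|---|---|
| `01_build_networks.py` | builds all four compositions × both protonation models, records conversion histories |
| `02_pore_descriptors.py` | validates PLD/MPD on analytic phantoms, measures built networks, classifies the sixteen published (PLD, MPD) pairs |
| `03_trajectory_metrics.py` | diffusion recovery at the published extremes, dissociation worked example, hydrogen-bond criteria sweep |
| `04_release_kinetics.py` | four-model fits of release curves synthesized from the published Korsmeyer–Peppas parameters |
| `05_descriptor_correlation.py` | within-material-centered Spearman correlation of descriptors with (synthetic) AUC₁–₂₄ₕ |

Each takes an optional seed argument (`python analysis/01_build_networks.py 1`).
A CLI exposes the same functionality on files
(`gelmesh build|pores|metrics|kinetics|correlate|synth|run`), and
`gelmesh run --config cfg.yaml` executes the configured end-to-end
pipeline with a reproducibility manifest.

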