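# tfdimer

Inference of symmetric, dynamic protein homodimer structures from
solution-NMR and biophysical observables.

Many weakly bound homodimers — the storage form of the ribosome-associated
chaperone Trigger Factor (TF) is the motivating case — cannot be
crystallized in their biologically relevant arrangement and are too dynamic
for NOE-based structure determination.  `tfdimer` implements the inference
chain that solves such systems in solution:

- **Equilibrium**: mass-action fits of SEC–MALS weight-averaged molar mass,
  `M_w = 2M − M(−K_D + √(K_D² + 8[M]K_D))/(4[M])`, giving K_D with 95%
  confidence intervals or lower limits for non-dimerizing constructs.
- **Exchange kinetics**: the dimer lifetime τ = 1/k_off from real-time
  spin-label mixing, where the signal decays mono-exponentially,
  `I(t) = I_∞ + (I₀ − I_∞)e^(−t/τ)`, with an exact stochastic simulator as
  independent oracle.
- **Interface mapping**: chemical-shift perturbations
  `Δδ_HN = √(Δδ(¹H)² + (0.2·Δδ(¹⁵N))²)` with corrected-to-zero significance
  thresholds; active/passive residue selection for docking.
- **Distance restraints**: paramagnetic relaxation enhancements converted
  through `V_ox/V_red = exp(−PRE·2τ_INEPT)` and the Solomon–Bloembergen
  relation `r = [K/PRE·(4τ_c + 3τ_c/(1+ω_h²τ_c²))]^(1/6)` into three
  restraint classes (bounded ±4 Å, upper-limit, lower-limit), with
  first-order error propagation and intra/intermolecular classification
  against the monomer structure; elastic-fold-network and distance-symmetry
  restraints.
- **Structure calculation**: two-phase C2-symmetric rigid-domain Monte
  Carlo — CSP-driven docking, then PRE/EFN-restrained annealing — with
  exact two-fold symmetry, 100 runs / 10 lowest-energy selection,
  violation reports and interface-contact tables.
- **Synthetic data**: toy multi-domain protomers, exact C2 truth dimers,
  and forward-simulated peak tables, binding curves and decay traces with
  known ground truth, so the whole chain is testable end to end.

## Worked example

```python
import tfdimer as t

# a complete synthetic study with known ground truth
bundle = t.make_full_fixture(seed=7)

# equilibrium: K_D from the simulated SEC-MALS curve
est = t.fit_kd(bundle.binding_curve)
print(f"K_D = {est.kd_uM:.2f} uM (95% CI {est.ci95_uM[0]:.2f}-{est.ci95_uM[1]:.2f})")

# kinetics: dimer lifetime from the 25 C mixing trace
fit = t.fit_lifetime(bundle.decay_traces[25])
print(f"tau = {fit.tau_s:.0f} s, k_off = {fit.k_off_per_s:.2e} s^-1")

# restraints: classify the PRE peak table
rs, counts = t.classify_peak_table(bundle.peak_table, bundle.pre_config)
print({k: counts[k] for k in ("bounded", "upper", "lower", "discarded")})

# annealing: recover the dimer pose from the restraints
efn = t.build_efn(bundle.protomer, bundle.domain_map)
cfg = t.AnnealConfig(seed=17, n_runs=20, n_keep=10)
models = t.anneal_dimer(bundle.protomer, bundle.domain_map, rs + efn, cfg)
print(f"best energy {models[0].total_energy:.3f}, "
      f"interface RMSD {t.interface_ca_rmsd(models[0], bundle.truth_dimer):.2f} A")
```

prints (annealing omitted for brevity):

```
K_D = 2.55 uM (95% CI 2.39-2.73)        # generating value 2.5 uM
tau = 952 s, k_off = 1.05e-03 s^-1      # generating k_off 1.05e-3 s^-1
{'bounded': 158, 'upper': 218, 'lower': 314, 'discarded': 0}
```

The K_D estimate brackets the generating value at the default 1% mass
noise; the lifetime fit is exact on a noise-free trace; and the peak table
partitions completely into the three restraint classes.  The PRE distance
calibration itself is parameter-free once anchored: a volume ratio of 0.15
corresponds to 16.12 Å, which forces ratio 0.85 to 24.28 Å because the
boundary-distance ratio `(ln 0.15/ln 0.85)^(1/6) = 1.5062` is independent
of the INEPT delay.  Lifetimes of 15.8 min and 2.6 min convert to
k_off = 0.0011 s⁻¹ and 0.006 s⁻¹.

A thin CLI exposes the pipeline stages
(`tfdimer simulate|dock|anneal|report`); see `tfdimer --help`.

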