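# pairswitch

Thermodynamics and kinetics of base-pair association–dissociation
switching from trajectory observables.

When a miRNA seed base pairs with its mRNA target inside an Argonaute
protein, the terminal base pair breathes: it switches between a closed
(association) state and an open (dissociation) state through brief
transition episodes. Long trajectories of this switching — typically
high-temperature MD of the RNA·protein complex — encode both the
equilibrium thermodynamics and the barrier kinetics of the process.
`pairswitch` is the analysis chain that extracts them, for structural
bioinformaticians who have such trajectories (or want a controlled
synthetic stand-in with known ground truth):

1. **Features** — per-frame RMSD of the guide/target bases relative to
   the starting structure and the backbone torsion
   ζ = C3′(n)–O3′(n)–P(n+1)–O5′(n+1), from coordinate tables or via
   MDAnalysis (`pairswitch.features`).
2. **States** — a hard classification into association `A` (RMSD ≤ 2 Å,
   ζ ∈ [−100°, −50°]), dissociation `D` (RMSD > 2 Å, ζ ∈ [50°, 100°])
   and transition `T` (open-like RMSD, closed-like ζ), with transition
   episodes annotated `ata`/`dtd` (failed) or `atd`/`dta` (successful)
   (`pairswitch.classify`).
3. **Dwell statistics** — occupancies `p_x = Σ τ_i^x / τ`, mean
   lifetimes `τ_ave = Σ τ_i / N`, lifetime histograms and mean
   transition-path times (`pairswitch.dwell`).
4. **Thermodynamics** — the van't Hoff line
   `ln(p_d/p_a) = (ΔH/k_B)(1/T) − ΔS/k_B` across temperatures, giving
   ΔH, ΔS and the extrapolated ΔG(310 K) = ΔH − 310·ΔS
   (`pairswitch.thermo`).
5. **Kinetics** — rates `k₊ = 1/τ_ave^d`, `k₋ = 1/τ_ave^a`; the Kramers
   forward model `t_a = 2π e^{β|ΔG_a|}/(β D* ω* ω_a)`,
   `t_tp = ln(2 e^γ β|ΔG|)/(β D* ω*²)`; and the barrier decomposition
   `ΔG = ΔG_a − ΔG_d` with an entropic association barrier
   `ΔG_d = TΔS̃`, fitted from the D*-free ratio curves `t_a/t_tp^{a→d}`
   and `t_d/t_tp^{d→a}` (`pairswitch.kinetics`).

A seeded synthetic generator (`pairswitch.synthetic`) — a
continuous-time Markov switcher with Boltzmann-consistent lifetimes and
state-conditional feature emissions — provides ground truth for every
stage, so the whole chain is validated by parameter recovery. The model
details, defaults and caveats are in [docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
synthetic ensemble (four temperatures × 400 ns at 2 ps frames,
ΔH = −4.95 kcal/mol, ΔS = −6.78 eu ground truth). Per-frame tables go
to `scratch/run/`, summary tables to `results/`:

```sh
python analysis/01_simulate_ensemble.py --seed 1
python analysis/02_classify_states.py
python analysis/03_dwell_statistics.py
python analysis/04_vant_hoff.py
python analysis/05_barrier_decomposition.py
```

Output of steps 03–05 (seed 1):

```
T530K_seed1: p_a=0.706 p_d=0.184 p_t=0.110; tau_a=55.7 ps tau_d=15.5 ps; t_tp(d->a)=5.25 ps (2774 crossings)
T580K_seed1: p_a=0.604 p_d=0.251 p_t=0.144; tau_a=36.6 ps tau_d=15.9 ps; t_tp(d->a)=5.31 ps (3719 crossings)

van't Hoff fit over 4 temperatures (R^2 = 0.9685):
  dH = -5.317 kcal/mol   (generator truth -4.950, error +7.4%)
  dS = -7.439 eu          (generator truth -6.780, error +9.7%)
  dG(310 K) = -3.011 kcal/mol

530 K: k+ = 64.4/ns, k- = 17.9/ns, k(t->a) = 176/ns
580 K: k+ = 63.0/ns, k- = 27.3/ns, k(t->a) = 183/ns
barrier decomposition: dS~ = -8.72 eu, w*/w_a = 0.0169, w*/w_d = 0.0164
  dG_a averages -6.025 kcal/mol across T (van't Hoff dH = -5.317)
```

Reading it: the closed-state lifetime τ_a falls steeply with
temperature while the open-state lifetime τ_d stays flat, so the
association rate k₊ is nearly temperature independent — the signature
of an entropic association barrier. The van't Hoff slope/intercept
recover the generator's enthalpy and entropy within the sampling error
of ~5×10³ switching cycles per temperature, and the barrier
decomposition's ΔG_a tracks the fitted ΔH (exactly so on noiseless
ratio curves; see the identifiability caveat in the methods note).

The same chain runs as one command on either synthetic or user-supplied
feature TSVs:

```sh
pairswitch run-all --seed 1 --total-time-ns 400 --out scratch/demo
pairswitch stats scratch/demo/trajectory_T530K_seed1.tsv --out scratch/stats.json
```

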