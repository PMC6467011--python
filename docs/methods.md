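# Methods

## Scope and model

`pairswitch` analyses trajectories of a terminal (seed-region) base pair
that switches between an **association** basin `A` (closed: bases paired
and stacked) and a **dissociation** basin `D` (open: the target base
flipped into solvent), passing through brief **transition** episodes `T`.
The observables are per-frame features a structural trajectory provides:
the RMSD of the guide base, the target base and the pair relative to the
starting structure (Å), and the backbone torsion ζ of each strand
(degrees), defined over the four atoms C3′(n)–O3′(n)–P(n+1)–O5′(n+1).

Classification is a hard partition of the (RMSD, ζ_target) plane:

| label | RMSD (pair) | ζ_target |
|---|---|---|
| A | ≤ 2 Å | [−100°, −50°] |
| D | > 2 Å | [50°, 100°] |
| T | > 2 Å | [−100°, −50°] |
| U | anything else | |

The A-state upper RMSD bound is taken as the open threshold (2 Å) rather
than a band around the 0.7 Å closed mode so that the RMSD axis has no
dead zone; frames whose ζ falls outside both windows are unassigned
(`U`), a convention this package owns — a hard four-way partition leaves
no frame unlabelled and keeps occupancies summing to one. Classification
uses the pair RMSD and the target-strand ζ because the guide base is
preorganised (it barely leaves its closed-like geometry even when the
target base dissociates); a switch to the target-base RMSD is available
(`ClassifierThresholds(use_target_rmsd=True)`).

Maximal `T` runs are annotated by their flanking basins: `ata`/`dtd` are
failed crossings that fall back into the originating basin, `atd`/`dta`
are successful transition paths. `U` runs are transparent when locating
the flanks; a `T` run that reaches a sequence boundary is `edge` and is
excluded from kinetic averages. Optional smoothing (off by default, as
the state criteria themselves involve no filtering): `max_gap_frames`
bridges short `U` gaps between identical labels; `min_dwell_frames`
debounces runs shorter than the threshold into the longer neighbour
(ties to the preceding run).

## Statistics

Occupancies are time fractions, `p_x = Σ_i τ_i^x / τ` with τ the total
observation time; transition time counts toward `p_t` only (no
re-attribution to basins). Mean lifetimes are arithmetic means
`τ_ave = Σ τ_i / N`. Dwells touching the start or end of the
observation window are censored from lifetime averages (they are
right/left truncated) but retained for occupancy, following standard
dwell-time practice. Standard errors come from a seeded
per-segment bootstrap (default 1000 resamples; the pipeline default is
200 for speed). Lifetime histograms default to logarithmic binning from
the shortest to the longest observed dwell. Transition-path times are
the mean durations of *successful* crossings: `t_tp^{d→a}` from `dta`
episodes and `t_tp^{a→d}` from `atd`.

## Thermodynamics

The two-state free-energy difference is `ΔG(T) = k_B T ln(p_d/p_a)`
(`k_B = 1.987×10⁻³ kcal mol⁻¹ K⁻¹`), with `p_t`/`p_u` excluded from the
ratio rather than renormalised — the transition states occupy negligible
probability, so a two-state treatment applies. With `ΔG = ΔH − TΔS`,

    ln(p_d/p_a) = (ΔH/k_B)(1/T) − ΔS/k_B ,

so an ordinary least-squares fit of `ln(p_d/p_a)` on `1/T` (the quantity
actually plotted in a van't Hoff analysis, fitted unweighted by default;
inverse-variance weighting by bootstrap errors is available) yields
`ΔH = slope·k_B` and `ΔS = −intercept·k_B`. Entropies are reported in
entropy units (eu = cal mol⁻¹ K⁻¹). Extrapolation to physiological
temperature is `ΔG(310 K) = ΔH − 310·ΔS`; the with-protein parameters
(ΔH = −4.95 kcal/mol, ΔS = −6.78 eu) give −2.85 kcal/mol and the
no-protein parameters (ΔH = −7.3, ΔS = −18.5) give −1.56 kcal/mol,
which double as unit audits in the test suite.

## Kinetics and barrier decomposition

Rates are reciprocal mean lifetimes: `k₊ = 1/τ_ave^d`, `k₋ = 1/τ_ave^a`,
and transition-state exit rates `k_{t→a} = 1/τ_ave^{ata}`,
`k_{t→d} = 1/τ_ave^{dtd}`. This conventional mapping is implemented
as is even though `ata` episodes end in `a`; the
alternative pairing with successful crossings is available
(`transition_mapping="crossing"`).

On a 1-D free-energy surface with barrier-top diffusion coefficient D*
and curvatures (ω*)², (ω_a)², (ω_d)², the high-barrier Kramers dwell
times and the mean transition-path times are

    t_a = 2π e^{β|ΔG_a|} / (β D* ω* ω_a)        (t_d analogous with ΔG_d, ω_d)
    t_tp^{d→a} = ln(2 e^γ β|ΔG_d|) / (β D* ω*²)  (a→d analogous with ΔG_a)

with β = 1/(k_B T) and γ Euler's constant. The prefactor is read as
2π/(β D* ω* ω_a) — the standard Kramers high-barrier escape time, the
only reading under which times decrease with faster diffusion. Sign
convention: the decomposition `ΔG = ΔG_a − ΔG_d` can make the
book-kept barrier values negative; magnitudes enter the exponential and
the logarithm where a height is physically required, and both signed
and magnitude values appear in reports. β|ΔG| must exceed 1/(2e^γ)
≈ 0.28 for the transition-path logarithm to be positive; smaller
barriers are rejected with an explicit error.

The ratios `r_a = t_a/t_tp^{a→d}` and `r_d = t_d/t_tp^{d→a}` are
independent of D* and of the absolute curvature scale; only the ratios
ω*/ω_a and ω*/ω_d are identifiable and no attempt is made to estimate
D* or ω* individually. (The pairing of each basin lifetime with the
transition path *leaving* that basin is adopted throughout; notation
in the literature sometimes swaps the subscripts.) Under an
entropic association barrier `ΔG_d = TΔS̃` (which makes βΔG_d, hence
r_d, temperature independent — the observed behaviour) and the
constraint `ΔG_a = ΔG(T) + ΔG_d` from the van't Hoff fit, the two ratio
curves determine (ΔS̃, ω*/ω_a, ω*/ω_d). When ΔS̃ equals the van't Hoff
ΔS, `ΔG_a(T) = ΔH` identically — the algebraic self-consistency the
tests enforce to 10⁻⁹.

**Fitting.** Residuals are on the log-ratio scale. The two amplitude
parameters enter linearly in log space and are profiled out in closed
form; the remaining one-dimensional problem in |ΔS̃| is bracketed on a
geometric grid and minimised by bounded Brent search, then polished
with bounded Levenberg–Marquardt restarts (seeded). A plain 3-parameter
damped least squares was tried first and abandoned: the amplitudes
trade off against the barrier entropy almost exactly (only the slowly
varying ln ln term breaks the degeneracy), so the joint problem has a
long flat valley in which LM stalls or runs away; profiling makes the
noiseless round trip exact to ~10⁻¹³ and the noisy fit stable within
the entropy bounds (default 0.05–60 eu).

**Identifiability caveat.** On noiseless model-generated curves all
three parameters are recovered to better than 10⁻⁶ relative. On
*measured* ratio curves the barrier entropy is weakly identified: its
parametric-bootstrap confidence interval spans an order of magnitude at
the study's sampling depth. The end-to-end test therefore checks
calibration (the generating values lie inside the bootstrap CI), not
sharpness. Any single-point ΔS̃ from noisy data should be quoted with
that CI.

## Synthetic generator

The generator is a continuous-time Markov model, not a diffusive
dynamics on an explicit surface: basin dwells are exponential, every
basin exit enters an exponential `T` episode (mean `tau_tp_ns`) that
falls back to its origin with probability `p_fail` and otherwise
commits. Emissions are state-conditional truncated distributions chosen
to match the observed feature distributions while remaining separable:

* closed-like RMSD ~ Normal(0.7, 0.15) Å truncated to (0, 2];
* open-like RMSD ~ 2 + Gamma(shape 2, scale 0.8) Å truncated to (2, 12];
* closed-like ζ ~ Normal(−75°, 8°) on [−100°, −50°]; open-like
  ζ ~ Normal(70°, 10°) on [50°, 100°];
* `T` frames combine open-like RMSD with closed-like ζ; the guide base
  emits closed-like features in every state (seed preorganisation).

Temperature enters twice. The association lifetime follows an Arrhenius
law `τ_a(T) = τ_ref exp[(E_a/k_B)(1/T − 1/T_ref)]`, and the open-state
lifetime is implied by Boltzmann equilibrium,
`τ_d(T) = τ_a(T)·exp[(ΔH − TΔS)/(k_B T)]`, so ground-truth occupancies
obey the configured thermodynamics at every temperature. The default
activation energy equals |ΔH| (4.95 kcal/mol), which makes τ_d nearly
temperature independent — reproducing the strong/weak temperature
asymmetry between the closing and opening lifetimes. Transition-episode
durations are temperature independent, consistent with their observed
weak temperature dependence.

Defaults are the study conditions: temperatures {530, 540, 560, 580} K,
frames every 2 ps, ΔH = −4.95 kcal/mol, ΔS = −6.78 eu, and 4000 ns per
temperature. Basin lifetime scales are free parameters of the
generator; the package sets `τ_a(530 K) = 50 ps` and `tau_tp = 4 ps` with `p_fail = 0.3`:
short enough that a few hundred nanoseconds contain thousands of
complete switching cycles (dense dwell statistics at desk scale), long
enough that dwells span many frames and the τ_a ≫ τ_tp separation
holds. The analysis scripts and acceptance run use 400 ns per
temperature — at these lifetimes that yields ~5×10³ cycles per
temperature, enough for the enthalpy to be recovered to better than
~10%.

RNG streams are named per (seed, temperature, purpose), so adding a
temperature to an ensemble never perturbs existing members. Angles are
stored in degrees in (−180°, 180°].

**What the generator does not emulate.** No force-field physics,
solvent, or protein atoms; no intra-basin autocorrelation (frames are
conditionally independent given the state); no diffusive recrossing
structure inside transition episodes (episode durations are exponential
rather than Kramers-path distributed); discrete 2 ps sampling censors
episodes shorter than a frame, which biases *frame-based* t_tp upward —
ground-truth-path statistics carry no such bias, and occupancy (hence
the van't Hoff route) is unbiased either way. Passing recovery tests
therefore validates the analysis chain's correctness, not the realism
of any particular molecular system.

## Feature extraction

Torsions use the standard atan2 two-plane-normal construction with the
IUPAC sign convention (cis = 0°, trans = 180°), anchored in tests by
the trans example, an independently coded projection formula (1e-6°)
and MDAnalysis's implementation. Degenerate geometries (coincident
points, collinear triples) raise rather than returning 0. RMSD performs
**no superposition by default**: the analysed complex is position
restrained except for the two nucleotides of interest, so the lab frame
is the reference frame; Kabsch alignment is available behind
`superpose=True` for unrestrained systems. Heavy-atom selections are
the intended default (hydrogens contribute little signal and are
often unresolved). Coordinates are read either from plain TSV tables
(frame/atom/x/y/z) with no extra dependencies or through MDAnalysis.

## Numerical and format choices

* Boltzmann constant 1.987×10⁻³ kcal mol⁻¹ K⁻¹; Euler's constant
  0.5772156649; eu = cal mol⁻¹ K⁻¹ (confirmed by the −2.85 kcal/mol
  worked example).
* Report tables print floats at 6 significant digits (bit-stable
  diffs); ground-truth paths at 12 (ps-scale dwells on a µs axis), and
  re-reading rebuilds segment starts cumulatively so contiguity is
  exact after rounding.
* Truncated-normal sampling via `scipy.stats.truncnorm`; truncated
  shifted-gamma by rejection (the discarded tail mass is ~10⁻⁴).
* The van't Hoff fit runs on ln(p_d/p_a), not on ΔG, so the fitted
  line is exactly the plotted quantity.
* Pipelines re-run byte-identically from an identical config + seed;
  the manifest records output digests to make that checkable.

## Known limitations

* The barrier-entropy identifiability issue above: kinetic barrier
  parameters from a single study-sized data set carry wide intervals.
* Frame-quantised episode durations: with 2 ps frames and ~4-6 ps
  transition paths, measured t_tp is coarse (0, 1 or 2 frames resolve
  most episodes); use finer frame intervals when transition-path times
  are the quantity of interest.
* The classifier is a hard partition; no probabilistic (HMM) smoothing
  is attempted; the criteria are a deterministic partition by design.
* Dwell distributions are summarised by mean, count and histogram; no
  survival-model fitting beyond that.
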