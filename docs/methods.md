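# Methods

## Mechanism model

The simulator integrates a deterministic mass-action network describing
one catalytic cycle of clamp loading and unloading at a primer/template
(P/T) junction, with species resolved by clamp label (acceptor-labeled /
unlabeled), by mechanistic stage, and by loader population. Units are nM
and seconds; time zero is the completion of the final stopped-flow mix.

States per (population, label): solution loader, solution clamp, open
encounter complex on DNA, notched (spiral, high-FRET) complex, released
complex (ring closed, loader still resident), and — depending on the
design — holoenzyme (clamp + polymerase on DNA, terminal), lone DNA-bound
loader after capture, and slide-off / subunit-exchange sinks.

Key structural choices:

* **Two pre-existing loader populations.** Biphasic dissociation is
  modeled as two loader forms (fractions `p_fast` = 0.83 and 0.17), each
  retaining its departure rate (`k_off_fast` = 0.40 s⁻¹,
  `k_off_slow` = 0.039 s⁻¹) through the whole cycle. The alternative — a
  single loader branching at ring closure — is biexponential only for a
  single turnover: at loading equilibrium the slow branch accumulates in
  proportion to its residence time and would predict a ~40/60 fast/slow
  amplitude split for the unloading trace, whereas the observed split is
  83/17. With pre-existing forms the equilibrium bound ensemble carries
  the population fractions directly (essentially all loader is DNA-bound
  at the working concentrations), reproducing 83/17 in both pulse-chase
  and equilibrium-unloading designs.
* **Instantaneous DNA binding.** Bimolecular association of the
  loader·clamp complex with DNA is unresolvably fast in the data; it is
  realized as a fast effective rate (100 nM⁻¹ s⁻¹, i.e. pseudo-first-order
  ≥ 10³ s⁻¹ at working concentrations), so the observed rise rate equals
  `k_conf`. A finite `k_on_dna` can be supplied for sensitivity studies.
* **Instantaneous solution partitioning.** The loader/clamp interaction
  in solution (K_d ≈ 0.2 nM, ≥ 500-fold below working concentrations) is
  not integrated; the loading rate law partitions solution loader among
  clamp pools as `rfc · C_L / (ΣC + K_d)`. Unloading returns loader and
  clamp to solution in one joint step (the process is rate-limited by
  loader dissociation; no clamp is left behind).
* **Capture occludes unloading.** Polymerase capture converts a released
  complex to a terminal holoenzyme with no outgoing reaction; the
  resident loader remains DNA-bound (as a separate bookkeeping species)
  and departs at its population rate, so capture does not perturb the
  observed loader-dissociation kinetics. The default
  `k_capture` = 1.0 nM⁻¹ s⁻¹ makes capture fast and non-limiting
  (≥ 50 s⁻¹ at stoichiometric polymerase, two orders above unloading);
  with a slower, rate-comparable capture a large fraction of initially
  loaded clamp escapes capture on its first residence, which would
  contradict the observed stoichiometric (ratio = 1.0) capture.
* **Leak channels.** Slide-off over an unblocked DNA end (`k_slide`,
  default 0; the end-block is a design flag, not a species) and clamp
  subunit exchange (`k_subunit_exchange`, default 0 — never observed in
  the presence of ATP) drain DNA-bound clamp to sinks. Pre-equilibration
  of pre-assembled complexes runs with leak channels frozen: the
  pre-assembly step is defined by its loaded endpoint, not by the fully
  disassembled state the leaks drain toward on much longer timescales.
* **Hydrolysis toggle.** `hydrolysis_enabled=False` (the ATPγS condition)
  forces ring closure and the hydrolysis-dependent fast departure to
  zero: loading halts at the notched high-FRET state (traces become
  monotone non-decreasing) and unloading proceeds only by subunit
  exchange when that channel is enabled.

FRET weights per labeled DNA-bound stage default to 0.5 (open), 1.0
(notched), 0.6 (released, holoenzyme); true per-stage transfer
efficiencies are not known, and these conventions reproduce the observed
dead-time jump, rise, decrease and plateau. The observable is
`baseline + scale · Σ w_s c_s(t)` with defaults baseline 0.1 a.u. and
scale 0.01 a.u./nM.

Integration uses LSODA with rtol 1e-8 / atol 1e-10; conservation of DNA,
loader, clamp (per label) and polymerase holds to relative 1e-6 on every
trajectory, verified against a closed-form sequential-kinetics oracle and
by explicit totals in the tests. Pre-equilibration integrates the pre-mix
in growing windows until max|dc/dt| falls below 1e-9 of the concentration
scale per second.

## Synthetic data

Designs are declarative: syringe contents in pre-mix concentrations, 1:1
mixing halves everything, an instrument dead time censors samples before
`dead_time` (default 2 ms — an instrument property, any positive value
exercises the dead-phase bookkeeping), and sampling follows the
instrument schedules (loading: 5000 points over the first 10 s plus 3000
over the remainder; unloading: 1000 points per 60 s). Pulse-chase designs
integrate the pulse stage for 37 ms before the chase mix, with time reset
at the final mix. Noise is additive i.i.d. Gaussian, seeded, with default
σ = 1% of the clean trace's full-scale amplitude; titration members
derive their seeds as `seed + index`.

What the generator does **not** emulate: photophysics (bleaching,
blinking), shot noise, baseline drift, temperature effects, finite mixing
efficiency, or nucleotide-concentration dependence beyond the
hydrolysis on/off toggle. Passing recovery tests therefore demonstrate
correctness of the analysis chain under the stated noise model, not
robustness to instrument artifacts.

## Trace fitting

The trace model is `y(t) = Σᵢ Aᵢ e^(−kᵢ t) + c′` with signed amplitudes
(rises negative), fitted by variable projection: amplitudes and offset
are solved linearly for trial rates; log-rates are optimized by
trust-region least squares from a deterministic multi-start set (all
ascending n-subsets of 7–8 log-spaced candidate rates spanning the data
window), best residual wins. Optima whose amplitudes exceed 20× the
observed signal range mark a collapsed (unidentifiable) phase pair and
are only accepted when nothing better converges. Phase collapse — two
rates within 5%, or a phase with negligible amplitude — raises a warning
recommending one fewer phase. Standard errors come from the full
(rates, amplitudes, offset) Jacobian at the optimum. Phase counts can be
selected automatically by an extra-sum-of-squares F-test at α = 0.01.
Fits are unweighted; convergence tolerances are 1e-12 on the scaled
step/residual with at most 200·(n+1) evaluations per start.

The dead-time amplitude is `A_dead = c′ + ΣAᵢ − y₀`: the fitted model's
value at time zero minus the zero-FRET level `y₀` of a loader-free
control — the portion of the signal change completed before the first
observable sample. (In the convention where phase amplitudes are quoted
as positive magnitudes this is the familiar `c′ − y₀ − A_inc − A_dec`
bookkeeping.)

Total amplitude A_T sums phase magnitudes, optionally plus |A_dead|.
Relative amplitudes are percentages of the resolved phases only.

## Stoichiometry

Amplitude ratios use A_T = Σ|Aᵢ| for the unloading (decay) trace. For
reload (rise) traces anchored by a control `y₀`, the total is the net
change `c′ − y₀`: the labeled rise passes through the fast assembly
steps, producing early curvature a double exponential cannot represent —
its backward extrapolation to time zero is biased by several percent (and
the 0.25-labeled-fraction member is outright degenerate), while `c′ − y₀`
measures the physical quantity (labeled clamp gained on DNA) robustly.
The regression of ratio on labeled fraction is ordinary least squares;
the titration break point is a continuous rising-line-plus-plateau least
squares fit with the junction scanned at the data abscissae and refined
by golden-section search. A series that a straight line explains equally
well is reported as unbounded (no plateau); an all-flat series is flagged
with the junction at the first point.

## Known limitations and systematics

* At loading equilibrium ~12% of bound clamp transits the open/notched
  states; their 1.4 s⁻¹ decay blends into the fast unloading phase, so a
  double-exponential fit of the full mechanism's unloading trace returns
  ~0.43 s⁻¹ / ~85% rather than the microscopic 0.40 s⁻¹ / 83%. The
  parameter-recovery driver quantifies this.
* Under instantaneous solution partitioning, the label-exchange
  relaxation in the reload design is faster than the loader-departure
  rate (the solution pool is comparable in size to the bound pool), so
  fitted reload rise rates exceed the unloading rates even though the
  endpoint amplitudes are exact. Net-change amplitude accounting (above)
  makes the stoichiometric ratios insensitive to this.
* The chase-control trace is not exactly flat: the labeled clamp competes
  with the trap at ~1:20 and slowly accumulates a few percent of the
  matched loading amplitude, as expected for a passive trap.
* Problem sizes follow the instrument schedules (8000-point loading
  traces, 1000–3000-point unloading traces); the seeded recovery study
  uses 30 seeds per condition and the estimator-coverage check 100 seeds.
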