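# Methods

## The estimation problem

Proteasome inhibition perturbs growth-factor signaling at several levels
at once: it reduces activation of the upstream kinase MEK *and* elevates
the activity of phosphatases acting on ERK, because short-lived
dual-specificity phosphatases (DUSPs/MKPs) are stabilized when their
degradation is blocked. Given quantified immunoblot time courses of
phospho-MEK (pMEK) and phospho-ERK (pERK) under a dose × treatment
factorial, the package separates the two effects and estimates the
**fold-upregulation of ERK-directed phosphatase activity**, written
`phi`, in inhibitor-treated cells.

The strategy is deliberately semi-mechanistic. Everything upstream of
MEK is summarized phenomenologically; only the ERK
phosphorylation/dephosphorylation layer is modeled mechanistically,
because that is the layer the question concerns and the layer the data
can constrain.

## Stage 1 — phenomenological MEK input

Each measured pMEK course (one per condition) is fit independently to

    u(t) = M0 + A · (1 − e^(−t/τr)) · e^(−t/τd)

with basal level `M0` (a.u.), amplitude `A` (a.u.), rise time `τr`
(min) and adaptation time `τd` (min), all non-negative. This is the
simplest form with the observed transient rise-and-adapt shape; it is
*not* claimed to be mechanistic, and it sits behind a single evaluation
function so an alternative (e.g. data interpolation) could be swapped
in. Fitting minimizes the SEM-weighted sum of squares (unweighted when
any SEM is zero, as for noise-free synthetic data) by bounded
trust-region least squares from a fixed 3⁴-point multistart grid spanning
two decades around data-driven heuristics, plus an explicit nested
flat-model candidate (`A = 0`); the result is deterministic for a given
dataset. Fitting per condition matters because the inhibitor perturbs
MEK activation itself — forcing a shared input would bias `phi`.

## Stage 2 — two-site ERK model

ERK fractions x0/x1/x2 (un-, mono-, dual-phosphorylated; total
normalized to 1) evolve by distributive two-step
phosphorylation/dephosphorylation with independent Michaelis–Menten
terms:

    dx0/dt = −kc1·u(t)·x0/(K1+x0) + φ·Vp1·x1/(P1+x1)
    dx2/dt =  kc2·u(t)·x1/(K2+x1) − φ·Vp2·x2/(P2+x2)
    dx1/dt = −(dx0/dt + dx2/dt)

Assumptions, in order of importance:

- **Kinase Vmax ∝ measured pMEK.** `kc1·u(t)`, `kc2·u(t)` make the
  fitted input the time-varying kinase capacity.
- **One fold-factor on both sites.** `phi` multiplies both
  dephosphorylation Vmax terms equally, is 1 in control arms, and is a
  single shared free parameter across all inhibited arms (both doses).
- **Observable is x2 only.** The pERK antibody is dual-site
  (pThr202/pTyr204), so predictions are `scale · x2(t)` with one fitted
  scale factor absorbing blot normalization; total-ERK conservation is
  justified because total ERK is not perturbed by the treatment.
- **Initial condition** is the pre-stimulus steady state under the
  basal input `u(0)`, found by root finding on the reduced (x1, x2)
  system to residual < 1e-10.

The public simulator integrates the full three-state system with scipy
LSODA at rtol 1e-8 / atol 1e-10 and checks mass conservation to 1e-6.
The fitting hot path uses a numba-compiled adaptive Cash–Karp RK45 on
the reduced two-state system with an analytic-Jacobian Newton steady
state; the two routes agree to ~1e-6 per component and the test suite
asserts it. The compiled integrator caps work at 2000 step attempts per
trajectory: parameter vectors so stiff that an explicit method cannot
traverse them (effective rates ≳10³/min, far faster than anything the
5-min sampling grid can distinguish) are assigned the penalty cost
rather than integrated, which truncates physically meaningless corners
of the sampling box.

## Stage 3 — ensemble fitting

The objective is the SEM-weighted chi-square over all pERK points, with
SEMs floored at 5% of the dataset-wide maximum pERK mean so noise-free
or lucky points cannot acquire infinite weight. Nine kinetic/scale
parameters are shared across all four time courses; `phi` is the tenth
free parameter. All parameters are sampled in log10 space within bounds
[1e-4, 1e4] (rates and Michaelis constants), [0.1, 100] (`phi`), and
[0.01, 100] (`scale`).

Rather than a single best fit, the method compiles an ensemble of
parameter sets that fit nearly equally well:

1. **Annealing.** A Metropolis walk perturbing one round-robin-chosen
   parameter per step (Gaussian in log10 space), with 50 temperatures
   cooling geometrically from 100 to 1 and 500 steps each; per-parameter
   step sizes adapt toward 20–40% acceptance. Two independent chains are
   run from deterministic sub-seeds and the better kept — a single chain
   occasionally freezes in a secondary basin. A deterministic
   Nelder-Mead polish then settles the basin floor, so the good-fit
   threshold is anchored at the true optimum rather than at sampling
   noise.
2. **Harvest.** A fixed-temperature Metropolis chain from the polished
   optimum with the adapted (frozen) step sizes. The acceptance ratio is
   `exp(−Δχ²/2)`, i.e. the chain samples the Gaussian likelihood
   `exp(−χ²/2)`; every 10th visited state with
   `χ² ≤ χ²_best + Δ` is retained until the target ensemble size
   (default 10⁴) is reached. `Δ` is the 95% chi-square quantile for the
   number of free parameters (18.3 for 10) — the confidence-region
   increment under Gaussian errors. The threshold definition is a
   configurable stand-in, surfaced in `SamplerConfig`, not hard-coded.

For each retained set the model output is recalculated; per-parameter
means, SDs and CVs and per-(condition, time) trajectory means and SDs
summarize the ensemble. The CV of a parameter over the ensemble is the
identifiability diagnostic: sloppy parameters span their bounds (large
CV, reported, not an error), while a well-constrained parameter — by
design of the study, `phi` — shows a small CV. `phi` is reported as
ensemble mean ± SD.

One top-level seed derives the annealing and harvest seeds through
`numpy.random.SeedSequence`, so a run is bit-reproducible on one
platform.

## Synthetic data generator

The quantified experimental data exist only as published figures, so
validation is by parameter recovery on synthetic data emulating the
design: 2 doses × {control, inhibited} × times {0, 5, 15, 30, 60, 120}
min × 3 replicates, readouts in total-ERK-normalized arbitrary units,
multiplicative lognormal noise with CV 0.10 (mean-preserving
parameterization — densitometry error scales with band intensity and
stays positive). Stored means and SEMs are computed across replicates;
the generating parameters and raw replicate draws are emitted in a
separate ground-truth record.

Defaults (`paper_like_config`): the generating fold-factor is 3.61, the
study's reported point estimate, so recovery tests target it. The
generating kinetics are not published; they were chosen once so that
noiseless trajectories reproduce the figures' qualitative signatures —
transient pMEK peak near 5–15 min adapting by 120 min, reduced
high-dose pMEK amplitude in the inhibited arm, pERK suppressed in the
inhibited arm at both doses — and so that `phi` is tightly constrained
by the design (the control arm runs near kinase-dominated saturation;
the inhibited response sits mid-range where it is steep in `phi`),
matching the reported 4% CV regime. Inhibited-arm MEK inputs are
independent ground-truth curves, not derived from control ones.

What the generator does **not** emulate: inter-experiment normalization
drift, gel-position artifacts, correlated replicate errors, and any
deviation of the real (unknown) noise law from lognormal. Passing
recovery tests therefore demonstrates the pipeline's correctness and
the design's identifiability under the stated noise model, not the
accuracy of the published estimate for the real cells.

## Numerical choices and problem sizes

- Default recovery studies use 10³-set ensembles (the full default is
  10⁴); across ten generator seeds the ensemble mean of `phi` lands
  within 10% of truth in ≥9/10 studies, at roughly a minute per study.
- The ensemble mean of `phi` carries a small positive bias (~+2–5% at
  noise CV 0.10) relative to the generating value: the likelihood's
  `phi` marginal is right-skewed (suppression saturates as `phi` grows,
  so the upper flank is flatter), and averaging a skewed marginal sits
  above its mode. This mirrors reporting an ensemble mean rather than a
  maximum-likelihood point.
- Ties/degeneracies: a cost surface flat in some parameter leaves the
  chain diffusing over that parameter's bounds; this is reported via a
  large CV.
- Integration failures during sampling map to a large finite penalty
  (1e12), so chains move away instead of crashing.
- The harvest chain raises a diagnostic error if its acceptance rate
  drops below 1% over a 1000-step window, or if the target ensemble
  cannot be collected within 50× the nominal step budget.

## Known limitations

- The exact functional forms used in the original supplementary methods
  are unavailable; the input curve and the independent-MM model here
  are explicit minimal interpretations, and no equivalence is claimed.
- No competition of the three ERK species for shared kinase/phosphatase
  pools; a shared-enzyme variant would change the meaning of the
  Michaelis constants.
- No negative feedback from ERK to MEK (absorbed phenomenologically in
  the fitted inputs), no basal kinase activity beyond `u(0)`, no
  processive phosphorylation variant.
- The ensemble is a threshold-filtered likelihood sample, not a
  Bayesian posterior with declared priors; bounds act as implicit
  log-uniform priors for unidentifiable directions.
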