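# Methods

This note documents the models, numerical choices and conventions behind
`identestim`, and what the bundled synthetic benchmarks do and do not
demonstrate.

## Model class and units

A `KineticModel` is a set of mass balances

    dC/dt = N · r(C, θ) − μ·C + f(t, C)

over named metabolite concentrations (mM), with named rate laws
(mM·s⁻¹), a signed stoichiometric map `N`, a constant specific growth
rate μ (s⁻¹) applied as a dilution term to every intracellular state
(states may be declared extracellular, e.g. medium glucose, and are then
exempt), and optional forcing terms (feed, pulse). Units are fixed at mM
and seconds; there is no unit-conversion layer. μ is an input, not a
modelled quantity — the package deliberately has no biomass/growth
sub-model.

Initial conditions may be flagged *unknown*. Such states enter the
estimation problem as pseudo-parameters named `ic_<state>`; their
starting estimates come from the zero-start bootstrap (below).

### Integration

LSODA (the pathways mix second-scale turnover with slow extracellular
dynamics, so a stiff-capable, order-adaptive method is the right
default), driven through `scipy.integrate.odeint` so the step loop runs
in compiled code — the selection procedure performs thousands of short
integrations and the generic python driver would dominate the runtime.
Default `rtol = 1e-6`, `atol = 1e-9`, both configurable per call; other
methods go through `solve_ivp`.

Three guards convert numerical pathology into a *typed*
`IntegrationFailure` that the selection procedure treats as an
estimation failure rather than a crash:

* non-finite derivatives or trajectories;
* **step-size collapse**, implemented as a budget of 20 000 right-hand-side
  evaluations per integration (a healthy desk-scale integration uses a
  few hundred; optimizer-proposed pathological parameters can otherwise
  grind the stiff solver nearly indefinitely);
* **negative concentrations** beyond `−100·(atol + rtol·max|y|)`. States
  are clipped at zero for rate evaluation only — the stored trajectory is
  never clipped, so a parameter set that genuinely drives a balance
  negative is detected instead of being silently sanitised. The
  tolerance-scaled band exists because a state that touches zero
  legitimately undershoots by the solver's local error, which scales with
  `rtol·|y|`, not with `atol` alone.

### Bootstrap of unknown initial conditions

Unmeasured intracellular pools should not be pinned at zero — that tends
to break integration or bias predictions. Instead the unknown states are
held at zero, the model is integrated over one short step (default 10⁻³
of the first observation interval), and the resulting values become the
initial *estimates* of those concentrations, which then join the
parameter vector as `ic_*` pseudo-parameters and are refined like any
kinetic parameter. Estimates scale linearly with the chosen step at
first order; the downstream procedure treats them only as starting
points, and the parameter-recovery tests confirm the final estimates do
not depend on this choice. A state with zero net inflow from the zero
start is floored at `atol` (with a warning) rather than returned as an
exact zero.

## Sensitivities and the collinearity screen

Local sensitivities `∂y_i/∂θ_j` are finite differences of the observed
model outputs, one parameter at a time: forward differences by default,
central optionally, with step `h = 1e-6 · max(|θ_j|, 0.1)`. The 0.1 mM
magnitude floor matters: a parameter that has collapsed toward zero would
otherwise receive a step below integration noise and produce a garbage
column — which then either masks true degeneracy or poisons the
conditioning tests with noise. Initial-condition pseudo-parameters are
perturbed exactly like kinetic parameters.

The normalized matrix B_N rescales entry (i, j) by `θ_j / y_i` so that
outputs and parameters of different magnitudes are comparable; `|y_i|` is
floored at 1 nM (1e-6 mM), below any measurable metabolite concentration,
because dividing by near-zero predictions otherwise amplifies solver
noise four orders of magnitude above signal.

The collinearity angle between two sensitivity vectors,
`∠(i,j) = arccos(b_i·b_j/‖b_i‖‖b_j‖) ∈ [0°, 180°]`, is a cheap pairwise
screen: values near 90° indicate linear independence, values near 0° or
180° flag pairs that the data at hand cannot separate. The default
critical band flags `∠ < 5°` or `∠ > 175°`. It is a screen, not a proof —
correlation is only examined pairwise — and the angle matrix records the
parameter vector at which it was evaluated, since the answer is
point-dependent.

## Estimability ranking

Candidates are ranked by the Euclidean norm of their normalized
sensitivity column after projecting out the span of the already-selected
columns (modified Gram–Schmidt, pivot-drop tolerance 1e-12 relative to
the largest selected norm; modified rather than classical purely for
numerical stability). With nothing selected this reduces to a pure norm
ranking.

The selection procedure ranks on *information-normalized* columns,
`(∂y_i/∂θ_j)·θ_j/σ_i` — the log-parameter columns of the weighted
estimation problem — so the residual norm measures exactly the marginal
information a candidate would add to the fit. Under a proportional error
model σ ≈ a·y this coincides with the classical relative (θ/y)
normalization up to the constant a, with the additive floor b keeping
near-zero records bounded; the two normalizations are the same idea, one
expressed against the measurement scale and one against the error model
actually used in the objective. Orthogonalization discounts only the *selected* set — parameters
that merely failed earlier do not discount anything. Ties break by
declaration order so runs are reproducible. The ranking criterion is a
pluggable hook (`ProcedureSettings.rank_fn`); norms-plus-Gram–Schmidt is
the shipped default.

## Weighted-least-squares estimation

Measurement uncertainty follows `σ_y = a·y + b` with `a` dimensionless
and `b` in mM, evaluated on the *experimental* values so that the weight
matrix is constant during optimization and S(θ) is a fixed quadratic form
in the residuals. Only the diagonal of the error covariance is used.

The subset fit runs `scipy.optimize.least_squares` (trust-region
reflective, jacobian column scaling, ftol = xtol = 1e-8, at most 200
iterations per parameter). Strictly positive parameters are optimized in
log space, which enforces positivity without explicit bounds and makes
steps multiplicative — the natural geometry for rate constants and
concentrations. Inside the optimizer, a trial point whose integration
fails returns a steep penalty that grows with distance from the entry
point, so the trust region backs off instead of the whole fit dying on a
single probe.

Because the weighted objective is multi-modal for saturable kinetics, a
converged fit whose weighted SSR still exceeds 2× the record count
triggers up to three deterministic restarts from seeded log-jittered
starting points (factor-3 spread), keeping the best minimizer. The
threshold is χ²-calibrated: the SSR of a correct fit concentrates near
the record count, so twice that value lies many standard deviations
beyond any plausible noise fluctuation and can only mean a wrong basin.
Well-fit calls never trigger, so the usual cost is zero.

A call *fails* — and hands the parameter vector back unchanged — on any
of: optimizer non-convergence; integration failure at the entry or the
converged point; singular FIM; or a final objective above the entry
objective. The singularity test runs twice: once at the entry point
(a rank-deficient subset, e.g. a structurally duplicated parameter, is
ill-posed before any step is taken, so the optimizer is never let loose
along the flat direction) and once at the optimum. The sensitivity
columns feeding these checks — and the reported covariance — are
computed with central differences at relative step 1e-5 under tightened
integrator tolerances (rtol 1e-9): the test compares columns at the
1e-10 reciprocal-condition level, which demands columns whose noise sits
orders of magnitude below that, and the reported σ_θ inherit the same
accuracy.

### FIM, covariance, and the conditioning metric

At the optimum, `FIM = Bᵀ V_Y⁻¹ B` over the subset's raw sensitivity
columns; `V_Θ = FIM⁻¹`; `σ_θj = √V_Θ[j,j]`; the reported relative
uncertainty is `σ_θ/θ`. Off-diagonal covariance entries (parameter
interactions) are preserved and reported.

The singular/non-singular decision uses the θ-scaled FIM — the
information matrix of the relative (log-space) parameterization the
optimizer itself works in — with reciprocal-condition threshold 1e-10.
The unscaled eigenvalue ratio conflates column-magnitude disparity with
collinearity: a parameter of large magnitude and modest relative
influence would dead-end the procedure even though nothing is actually
confounded. Genuinely collinear columns are singular under any diagonal
scaling, so the test keeps its meaning. The same scaling acts as a
preconditioner for the covariance inversion. Additionally, a subset in
which any parameter's σ_θ/θ exceeds 100 at the optimum is rejected under
the same verdict: a scalar FIM can never fail a condition-number test,
yet a single-parameter fit that has run into a zero-information plateau
(e.g. a maximum rate pushed deep into saturation) has not estimated
anything.

## The intensive selection procedure

See the README for the loop itself. Design points worth recording:

* After a **failed** inclusion the next candidate comes from the
  *existing* rank without re-ranking — no estimation succeeded, so the
  evaluation point is unchanged and re-ranking would be a no-op.
  Re-ranking happens after every success.
* `Θ(E)` is recycled into `Θ(NS)` after **every** success, not only at
  exhaustion. This is what makes the worst case exactly triangular:
  each ranking round attempts at most the current pool, and the pool
  shrinks by at least one between rounds, giving
  `nP + (nP−1) + … + 1 = nP(nP+1)/2`.
* A candidate may fail repeatedly across recycles; there is no
  per-candidate retry cap (the triangular bound caps total work). An
  optional wall-clock budget exists for large models.
* On termination, `Θ(E)` members remain at their entry-to-this-run
  values; the final vector is the one left by the last successful
  estimation.
* The procedure itself is deterministic; randomness exists only in data
  generation and the seeded optimizer restarts.

The first-failure mode used by `compare_baseline` differs *only* in the
stopping rule, so the comparison isolates the recycling strategy. Under
identical deterministic estimator behavior the two runs coincide up to
the first failure, after which the intensive incumbent can only improve;
hence intensive-final-objective ≤ first-failure-final-objective and
intensive-selected-size ≥ first-failure-size, which is what the tests
assert (the magnitude of the gap is problem-dependent).

## The E. coli central-carbon skeleton

Eighteen dynamic states — extracellular glucose plus 17 intracellular
metabolites of glycolysis and the pentose-phosphate pathway — wired to 30
named kinetic rates (PTS, PGI, G6PDH, PGM, PFK, ALDO, TIS, GAPDH, PGK,
PGluMu, ENO, PK, PDH, PEPCxylase, DAHPS, two generic synthesis drains,
MurSynth, TrpSynth, MetSynth, SerSynth, G3PDH, PGDH, Ru5P, R5PI, TKa,
TKb, TA, RPPK, G1PAT). Each intracellular balance carries −μ·C; the
glucose balance carries feed, pulse and PTS-uptake terms
`D(C_feed − C_glc) + f_pulse − (C_x/ρ_x)·r_PTS`, with all forcing
constants defaulting to an unfed batch (ρ_x defaults to 1 so the uptake
term is well-defined whenever C_x is set).

The literature's full rate expressions for this network are long,
allosteric, and tied to co-metabolite pools this skeleton does not carry,
so rate laws are *pluggable*: a registry maps rate symbols to callables,
and unregistered symbols fall back to a generic irreversible
Michaelis–Menten form with one saturation factor per consumed in-network
substrate (`rmax_<enzyme>`, `K_<enzyme>_<substrate>`; zero-order for the
two pure synthesis inflows). The multi-substrate form is load-bearing: a
single-substrate fallback keeps firing when a co-substrate (e4p, rib5p,
gap…) is exhausted and drives its balance negative. The skeleton
therefore has the right *structure* for identifiability studies at
realistic scale while making no claim to reproduce any published
parameterization; co-metabolites (atp, nadp, …) appear only as constants
inside user-supplied rate laws if at all. Five intracellular states
(pgp, 3pg, xyl5p, sed7p, g1p) are flagged unknown-IC by default, and 13
of the 18 states form the default measurable output set.

## Synthetic benchmarks

`make_chain_pathway` builds linear pathways S0 → S1 → … → Sn with seeded
log-uniform kinetics (vmax 0.5–2 mM/s, Km 0.5–5 mM; mass-action k
0.05–0.5 s⁻¹), a 10 mM substrate reservoir, partially filled
intermediates (0.2–2 mM) and an empty terminal pool. Two negative
controls can be injected: a structurally duplicated parameter
(`(vmax_1 + vmax_1_dup)·MM`, duplicate true value 2e-4, well below the
~3e-4 uncertainty the default error model leaves on the host vmax, so
that freezing the duplicate at a wrong entry value cannot bias the host
beyond its reported uncertainty) and a collinear gain pair (the last rate scaled by
`gain_a·gain_b`, whose sensitivity columns are parallel by construction).

`sample_dataset` simulates at the true parameters and adds independent
Gaussian noise with `σ = a·y_true + b`, redrawing negative values
(truncation; the redraw count is reported). Default scenario conventions:
15 log-spaced sample times from 1 to 300 s (the fast transient carries
most of the kinetic information), noise `a = 0.01, b = 1e-6`, full
observation unless masked, and starting estimates drawn log-uniformly
within a factor of 2 of truth.

What these benchmarks emulate: partially observed, heteroscedastically
noisy metabolite time courses with withheld initial conditions and known
ground truth. What they do not emulate: real rate-law misspecification
(the fitted model family always contains the truth), correlated or
asynchronous instrument noise, and the 100+-parameter scale of a full
network. Passing the recovery tests therefore demonstrates that the
selection-and-estimation machinery works as specified — not that any
particular real dataset would yield an equally clean partition.

## Problem sizes used in the checked results

The automated end-to-end checks run 20 seeded replicates of the 3-enzyme
scenario (7 candidates including the injected duplicate, 60 records) for
parameter recovery, 20 mass-action replicates for withheld-IC recovery,
and the procedure-logic properties on mock estimators at up to 10
candidates; these sizes exercise every code path of the procedure while
keeping a full suite run on one CPU in the minutes range. The recovery
thresholds (3 reported standard deviations, ≥ 90% of replicates) are
statistical: individual replicates may legitimately fail on hard draws.

## Known limitations

* Greedy one-at-a-time selection with local optimization inherits some
  dependence on starting estimates; the re-estimation/recycling design
  and the seeded restarts reduce it but cannot remove it.
* The collinearity screen is pairwise only; higher-order confounding is
  caught (if at all) by the FIM conditioning test.
* Finite-difference sensitivities trade accuracy for generality; an
  exact forward-sensitivity ODE augmentation would be the natural
  upgrade for large models.
* The error model is diagonal; correlated measurement errors are out of
  scope, as are profile-likelihood confidence regions and optimal
  experimental design.
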