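# identestim

Practical parameter identifiability and estimation for ODE kinetic models
of metabolic networks.

Dynamic models of cellular metabolism routinely carry far more kinetic
parameters than the available time-series data can determine: metabolite
measurements are sparse, only a fraction of the intracellular species are
observed, and some initial concentrations are unknown. Estimating every
parameter is then an ill-posed problem. `identestim` implements an
*intensive* subset-selection strategy that decides — one parameter at a
time, with simultaneous re-estimation — which parameters the data can
actually support, and estimates them, while every parameter that fails at
the current configuration is returned to the candidate pool after each
success so that no parameter is ever written off on the basis of stale
values.

It is intended for modellers in systems biology and chemical reaction
engineering who need to fit stiff ODE kinetic models (mM / seconds scale)
to partially observed, heteroscedastic time-course data.

## The method

Given a model `dC/dt = N·r(C, θ) − μ·C + f(t)` and records
`y_i^E` with uncertainties `σ_y,i = a·y_i + b`, parameters are estimated
by weighted least squares

    S(θ) = Σ_i (y_i^C(θ) − y_i^E)² / σ_y,i² ,

with uncertainty from the Fisher information matrix over the estimated
subset, `FIM = Bᵀ V_Y⁻¹ B`, `V_Θ = FIM⁻¹`, reported per parameter as the
normalized standard deviation `σ_θ/θ`. Here `B` is the local sensitivity
matrix `∂y_i/∂θ_j`; its θ/y-normalized columns `b_θj` are the sensitivity
vectors.

Selection maintains three disjoint sets — selected `Θ(S)`, non-selected
`Θ(NS)`, evaluated-and-failed `Θ(E)` — and loops:

1. rank `Θ(NS)` by estimability: descending Euclidean norm of each
   candidate's sensitivity vector after Gram–Schmidt orthogonalization
   against the span of the selected columns (sensitivities are recomputed
   at the *current*, re-estimated parameter vector);
2. move the top candidate into `Θ(S)` and re-estimate all of `Θ(S)`
   jointly;
3. on success, return **all** of `Θ(E)` to `Θ(NS)` and re-rank; on
   failure (optimizer non-convergence, integration failure, singular FIM,
   or no objective improvement), roll back, demote the candidate to
   `Θ(E)`, and try the next entry of the existing rank;
4. stop when `Θ(NS)` is empty.

The total number of estimation attempts is bounded by `nP(nP+1)/2`; for
three parameters the worst case is exactly 6. A classical
stop-at-first-failure variant is included for comparison
(`compare_baseline`), and a pairwise collinearity-angle screen
(`∠(i,j) = arccos(b_θi·b_θj / ‖b_θi‖‖b_θj‖)`) flags parameter pairs that
are practically indistinguishable (angles near 0° or 180°).

Unknown initial conditions are handled the way practitioners do it: start
the unmeasured state at zero, integrate one short step, take the resulting
value as an initial *estimate*, and let it join the parameter vector as an
`ic_<state>` pseudo-parameter.

Two model families ship with the package: seeded synthetic enzyme chains
(with optional structurally duplicated or collinear parameters as negative
controls) and an 18-state skeleton of *E. coli* K-12 central carbon
metabolism (glycolysis, pentose-phosphate pathway, phosphotransferase
system) with the literature mass-balance structure, 30 named kinetic rates and
pluggable rate laws.

## Worked example

```python
import identestim as ie

# a 3-enzyme Michaelis-Menten chain with known ("true") parameters,
# sampled over 0-300 s with sigma = 0.01*y + 1e-6 noise, starting the
# fit from estimates perturbed by up to a factor of 2
sc = ie.make_scenario(3, seed=0, duplicate_vmax=True)
trace = ie.run(sc.model, sc.dataset, sc.error_model,
               initial_parameters=sc.initial_guess)
print(f"selected {len(trace.selected)}/{len(trace.candidates)} in "
      f"{trace.evaluation_count} attempts; "
      f"S: {trace.initial_objective:.3g} -> {trace.final_objective:.3g}")
print(trace.final_result.report_table(sc.initial_guess))
```

prints

```
selected 6/7 in 7 attempts; S: 9.14e+04 -> 39.1
  parameter  initial_estimate  estimated_value  normalized_standard_deviation
0    vmax_1          0.511145         0.531477                       0.001294
1    vmax_3          1.266409         0.947753                       0.012622
2    vmax_2          1.382412         0.730546                       0.004887
3      km_1          0.487220         0.870295                       0.003606
4      km_2          0.618036         0.734840                       0.012036
5      km_3          0.806110         0.592018                       0.023999
```

The weighted objective falls by more than three orders of magnitude; six genuine
parameters are selected and recovered close to their generating values
(each normalized standard deviation is the reported `σ_θ/θ`), while the
deliberately injected duplicate of `vmax_1` fails with a singular FIM and
ends in `Θ(E)` — exactly the negative control the screen should catch.

The same workflow is scriptable from the shell:

```
identestim run --model model.yaml --data data.csv \
    --error-a 0.01 --error-b 1e-6 --mode intensive --out trace.json
identestim angles --model model.yaml --data data.csv
identestim rank   --model model.yaml --data data.csv
identestim simulate --model model.yaml --t-end 300 --out traj.csv
```

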