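"""Synthetic models, datasets and failure oracles.

Everything the rest of the package needs to be exercised end to end is
generated here: small enzymatic chain pathways with known ("true")
parameters, noisy partially observed datasets following the σ = a·y + b
error law, and deterministic failure oracles that stand in for the
estimator when only the selection procedure's bookkeeping is under test.

The default scenario mirrors the shape of a real metabolite time-course
study: a 300-second horizon with log-spaced sampling concentrated in the
fast transient, heteroscedastic noise, an observation mask hiding some
states, and optionally a withheld initial condition that must be
bootstrapped and estimated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .data import Dataset, ErrorModel
from .estimation import EstimationResult
from .model import KineticModel, ic_parameter, simulate
from .procedure import ProcedureSettings, ProcedureTrace, run

__all__ = [
    "FailureOracle",
    "make_worst_case_oracle",
    "make_random_oracle",
    "oracle_estimator",
    "run_with_oracle",
    "make_chain_pathway",
    "sample_dataset",
    "SyntheticScenario",
    "make_scenario",
]

#: true value of the injected duplicate parameter — deliberately small so
#: freezing it at a wrong entry value cannot bias the genuine parameters:
#: the freeze error is bounded by the value itself, which must sit well
#: below the ~3e-4 standard deviation the default error model induces on
#: the host vmax.  Collinearity detection is direction-based and does not
#: depend on the magnitude.
DUPLICATE_TRUE_VALUE = 2e-4


# ---------------------------------------------------------------------------
# failure oracles


@dataclass(frozen=True)
class FailureOracle:
    """Deterministic success/failure rule for stubbing the estimator.

    ``rule(candidate, selected, round_no, attempt, n_remaining) -> bool``
    (True = the inclusion succeeds).  Must be total and deterministic so
    procedure traces are reproducible byte for byte.
    """

    rule: Callable[[str, tuple, int, int, int], bool]
    name: str = "oracle"

    def __call__(self, candidate, selected, round_no, attempt, n_remaining) -> bool:
        return bool(self.rule(candidate, tuple(selected), round_no, attempt, n_remaining))


def make_worst_case_oracle(nP: int) -> FailureOracle:
    """Worst-case oracle: in every round of m remaining candidates, fail
    the first m−1 attempts and succeed the last.

    Drives the procedure to exactly m attempts per round and a total of
    nP + (nP−1) + … + 1 = nP(nP+1)/2 attempts.
    """
    if nP < 1:
        raise ValueError("nP must be >= 1")

    def rule(candidate, selected, round_no, attempt, n_remaining):
        return attempt == n_remaining - 1

    return FailureOracle(rule, name=f"worst-case(nP={nP})")


def make_random_oracle(seed: int, p_fail: float = 0.5) -> FailureOracle:
    """Seeded random-but-deterministic oracle for property tests.

    The verdict for a (candidate, round) query is a pure function of the
    seed, so repeated queries agree and traces are reproducible.
    """

    def rule(candidate, selected, round_no, attempt, n_remaining):
        key = f"{seed}|{candidate}|{round_no}".encode()
        draw = zlib.crc32(key) / 0xFFFFFFFF
        return draw >= p_fail

    return FailureOracle(rule, name=f"random(seed={seed}, p_fail={p_fail})")


def oracle_estimator(oracle: FailureOracle) -> Callable:
    """Adapt a :class:`FailureOracle` to the procedure's estimator hook.

    Successes report a synthetic strictly decreasing objective (test
    plumbing: keeps trace monotonicity meaningful without any model).
    """
    counter = {"successes": 0}

    def call(parameters: Mapping, subset: Sequence[str], context: dict):
        candidate = subset[-1]
        selected = tuple(subset[:-1])
        ok = oracle(
            candidate,
            selected,
            context["round"],
            context["attempt"],
            context["n_remaining"],
        )
        before = 1.0 / (counter["successes"] + 1)
        if ok:
            counter["successes"] += 1
        after = 1.0 / (counter["successes"] + 1)
        return EstimationResult(
            success=ok,
            reason=None if ok else "oracle-failure",
            subset=tuple(subset),
            estimated_values={n: parameters.get(n, 1.0) for n in subset},
            updated_parameters=dict(parameters),
            objective=after if ok else before,
            entry_objective=before,
        )

    return call


def run_with_oracle(
    oracle: FailureOracle,
    candidates: Sequence[str] | int,
    *,
    mode: str = "intensive",
) -> ProcedureTrace:
    """Run the selection procedure against an oracle, no model required.

    *candidates* may be a list of names or a count (names ``p1..pn``).
    Ranking is by declaration order — with a stubbed estimator only the
    set bookkeeping is under test.
    """
    if isinstance(candidates, int):
        candidates = [f"p{i + 1}" for i in range(candidates)]
    settings = ProcedureSettings(
        mode=mode,
        estimator=oracle_estimator(oracle),
        rank_fn=lambda params, nonselected, selected: [
            (n, float(len(nonselected) - i)) for i, n in enumerate(nonselected)
        ],
    )
    return run(None, None, None, candidates=list(candidates), settings=settings)


# ---------------------------------------------------------------------------
# synthetic kinetic pathways


def make_chain_pathway(
    n_enzymes: int = 3,
    kinetics: str = "michaelis_menten",
    seed: int | None = None,
    *,
    duplicate_vmax: bool = False,
    collinear_pair: bool = False,
) -> tuple:
    """Linear pathway S0 → S1 → … → Sn with seeded true parameters.

    Michaelis–Menten steps carry ``vmax_i`` (mM/s) and ``km_i`` (mM);
    mass-action steps a single ``k_i`` (s⁻¹).  Values are drawn
    log-uniformly from ranges typical of desk-scale enzyme kinetics
    (vmax 0.5–2 mM/s, Km 0.5–5 mM, k 0.05–0.5 s⁻¹).

    Negative controls for identifiability tests can be injected:

    * ``duplicate_vmax`` adds ``vmax_1_dup`` entering the first rate as
      ``(vmax_1 + vmax_1_dup)·S/(Km+S)`` — structurally non-identifiable
      jointly with ``vmax_1`` (identical sensitivity directions).  Its
      true value is small (:data:`DUPLICATE_TRUE_VALUE`) so freezing it
      barely perturbs the rest of the problem.
    * ``collinear_pair`` multiplies the last rate by ``gain_a·gain_b``
      (both true values 1): the two gains have sensitivity columns
      collinear by construction, a pair the angle screen must flag.

    Returns ``(model, true_parameters)``.
    """
    if n_enzymes < 2:
        raise ValueError("need at least 2 enzymes")
    if kinetics not in ("michaelis_menten", "mass_action"):
        raise ValueError(f"unknown kinetics {kinetics!r}")
    rng = np.random.default_rng(seed)
    states = [f"S{i}" for i in range(n_enzymes + 1)]

    params: dict[str, float] = {}
    rate_laws: dict[str, Callable] = {}
    stoich: dict[str, dict] = {}
    rate_specs: dict[str, dict] = {}

    for i in range(1, n_enzymes + 1):
        sub, prod, rname = states[i - 1], states[i], f"r{i}"
        stoich[rname] = {sub: -1, prod: 1}
        if kinetics == "michaelis_menten":
            vname, kname = f"vmax_{i}", f"km_{i}"
            params[vname] = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
            params[kname] = float(np.exp(rng.uniform(np.log(0.5), np.log(5.0))))
            spec = {"law": "michaelis_menten", "substrate": sub,
                    "vmax": [vname], "km": kname, "gains": []}
            if i == 1 and duplicate_vmax:
                params["vmax_1_dup"] = DUPLICATE_TRUE_VALUE
                spec["vmax"] = [vname, "vmax_1_dup"]
            if i == n_enzymes and collinear_pair:
                params["gain_a"] = 1.0
                params["gain_b"] = 1.0
                spec["gains"] = ["gain_a", "gain_b"]
            rate_laws[rname] = _mm_law(spec)
            rate_specs[rname] = spec
        else:
            kname = f"k_{i}"
            params[kname] = float(np.exp(rng.uniform(np.log(0.05), np.log(0.5))))
            spec = {"law": "mass_action", "substrate": sub, "k": kname}
            rate_laws[rname] = _ma_law(spec)
            rate_specs[rname] = spec

    # steady-state-like starting pools: full substrate reservoir, partly
    # filled intermediates, empty terminal product
    ics = {states[0]: 10.0}
    for s in states[1:-1]:
        ics[s] = float(np.exp(rng.uniform(np.log(0.2), np.log(2.0))))
    ics[states[-1]] = 0.0

    model = KineticModel(
        state_names=tuple(states),
        parameters=params,
        rate_laws=rate_laws,
        stoichiometry=stoich,
        initial_conditions=ics,
        dilution_rate=0.0,
        rate_specs=rate_specs,
    )
    return model, dict(params)


def _mm_law(spec: dict) -> Callable:
    sub, vnames, kname, gains = (
        spec["substrate"], tuple(spec["vmax"]), spec["km"], tuple(spec["gains"]),
    )
    if len(vnames) == 1 and not gains:
        vname = vnames[0]

        def law(c, p):
            s = c[sub]
            return p[vname] * s / (p[kname] + s)

        return law

    def law(c, p):
        v = 0.0
        for n in vnames:
            v += p[n]
        for g in gains:
            v *= p[g]
        s = c[sub]
        return v * s / (p[kname] + s)

    return law


def _ma_law(spec: dict) -> Callable:
    sub, kname = spec["substrate"], spec["k"]

    def law(c, p):
        return p[kname] * c[sub]

    return law


# ---------------------------------------------------------------------------
# noisy sampling


def sample_dataset(
    model: KineticModel,
    true_parameters: Mapping,
    times: Sequence[float],
    error_model: ErrorModel,
    mask: Sequence[str] | None = None,
    seed: int | None = None,
    *,
    max_resample: int = 1000,
) -> Dataset:
    """Simulate at the true parameters and add heteroscedastic noise.

    Each record is y^E = y^true + ε with ε ~ N(0, (a·y^true + b)²),
    independent across records.  Negative draws are resampled (truncation
    at zero — concentrations cannot be negative); the number of redraws is
    reported on the returned dataset as ``n_resampled``.  States not in
    *mask* (default: the model's output map) are omitted entirely.
    """
    observed = tuple(mask) if mask is not None else tuple(model.output_map)
    bad = set(observed) - set(model.state_names)
    if bad:
        raise ValueError(f"mask contains unknown states: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    traj = simulate(model, true_parameters, np.asarray(times, dtype=float))
    records = []
    n_resampled = 0
    for t in traj.index:
        for var in observed:
            y = float(traj.at[t, var])
            sig = float(error_model.sigma(y))
            draw = y + sig * rng.standard_normal()
            tries = 0
            while draw < 0:
                tries += 1
                if tries > max_resample:
                    raise RuntimeError(
                        f"could not draw a non-negative value for {var} at t={t}"
                    )
                draw = y + sig * rng.standard_normal()
            n_resampled += tries
            records.append((float(t), var, float(draw)))
    ds = Dataset.from_records(records, error_model)
    ds.n_resampled = n_resampled
    return ds


# ---------------------------------------------------------------------------
# full scenarios


@dataclass
class SyntheticScenario:
    """A generated ground-truth problem: model, data, and starting point."""

    model: KineticModel
    true_parameters: dict
    dataset: Dataset
    error_model: ErrorModel
    observation_mask: tuple
    withheld_ics: tuple
    initial_guess: dict          #: perturbed starting estimates for the procedure
    seed: int | None
    times: tuple = ()

    def candidates(self) -> list:
        return list(self.model.parameters) + self.model.ic_pseudo_parameters()


def default_times(n_points: int = 15, horizon: float = 300.0, first: float = 1.0) -> np.ndarray:
    """Log-spaced sampling over a 300 s horizon, dense in the transient.

    Fast-turnover pathways carry most of their kinetic information in the
    first seconds after a perturbation, so the grid is geometric from 1 s.
    """
    return np.geomspace(first, horizon, n_points)


def make_scenario(
    n_enzymes: int = 3,
    seed: int | None = 0,
    *,
    error_model: ErrorModel = ErrorModel(a=0.01, b=1e-6),
    times: Sequence[float] | None = None,
    kinetics: str = "michaelis_menten",
    duplicate_vmax: bool = False,
    collinear_pair: bool = False,
    mask: Sequence[str] | None = None,
    withhold_ic: str | None = None,
    guess_spread: float = 2.0,
) -> SyntheticScenario:
    """Generate a complete parameter-recovery scenario.

    The starting estimates handed to the procedure are the true values
    perturbed by seeded log-uniform factors in
    [1/guess_spread, guess_spread] — the estimator must find its way back.
    ``withhold_ic`` marks one state's initial condition unknown: the
    dataset is generated with the true value, but the procedure starts
    from the zero-start bootstrap and must recover it as an ``ic_*``
    pseudo-parameter.
    """
    ss = np.random.SeedSequence(seed)
    model_seed, noise_seed, guess_seed = [
        int(s) for s in ss.generate_state(3) >> np.uint32(1)  # keep below 2**31
    ]
    model, truth = make_chain_pathway(
        n_enzymes,
        kinetics,
        model_seed,
        duplicate_vmax=duplicate_vmax,
        collinear_pair=collinear_pair,
    )
    if times is None:
        times = default_times()
    times = tuple(float(t) for t in times)
    observed = tuple(mask) if mask is not None else tuple(model.state_names)
    dataset = sample_dataset(
        model, truth, times, error_model, mask=observed, seed=noise_seed
    )

    withheld = ()
    if withhold_ic is not None:
        if withhold_ic not in model.state_names:
            raise ValueError(f"unknown state {withhold_ic!r}")
        withheld = (withhold_ic,)
        from dataclasses import replace

        model = replace(model, unknown_ics=frozenset(withheld))
        truth = dict(truth)
        truth[ic_parameter(withhold_ic)] = model.initial_conditions[withhold_ic]

    grng = np.random.default_rng(guess_seed)
    lo = np.log(1.0 / guess_spread)
    guess = {
        name: float(value * np.exp(grng.uniform(lo, -lo)))
        for name, value in truth.items()
        if not name.startswith("ic_")
    }
    model = model.with_parameters(guess)
    return SyntheticScenario(
        model=model,
        true_parameters=truth,
        dataset=dataset,
        error_model=error_model,
        observation_mask=observed,
        withheld_ics=withheld,
        initial_guess=dict(guess),
        seed=seed,
        times=times,
    )
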