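"""One-by-one parameter selection with simultaneous re-estimation.

The procedure maintains three disjoint sets over the candidate
parameters: selected Θ^(S), non-selected Θ^(NS) and evaluated Θ^(E)
(failed at the current configuration).  Each round it re-ranks Θ^(NS) at
the *current* (re-estimated) parameter vector, tries to include the
top-ranked candidate by re-estimating all of Θ^(S) ∪ {candidate}, and:

* on success — updates the vector, returns **all** of Θ^(E) to Θ^(NS)
  (a parameter that failed before may become estimable now that the
  selected values have moved), and re-ranks;
* on failure — rolls the vector back, demotes the candidate to Θ^(E) and
  tries the next entry of the *existing* rank (nothing changed, so
  re-ranking would be a no-op).

It stops when Θ^(NS) is empty; every candidate then sits in Θ^(S) or
Θ^(E).  Total estimation attempts are bounded by nP(nP+1)/2 — each
re-ranking round attempts at most the current pool, and the pool shrinks
by at least one between rounds.  The classical alternative
("first-failure" mode) stops the whole selection at the first failed
inclusion; it is kept for baseline comparisons.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

from .data import Dataset, ErrorModel
from .estimation import EstimationResult, EstimationSettings, estimate_subset, objective
from .model import IntegrationFailure, KineticModel, bootstrap_unknown_ics
from .ranking import RankingState, rank_parameters
from .sensitivity import compute_sensitivities

__all__ = [
    "ProcedureSettings",
    "IterationRecord",
    "ProcedureTrace",
    "BaselineComparison",
    "run",
    "compare_baseline",
]

MODE_INTENSIVE = "intensive"
MODE_FIRST_FAILURE = "first-failure"


@dataclass(frozen=True)
class ProcedureSettings:
    """Configuration of one selection run.

    ``estimator`` and ``rank_fn`` are injectable, primarily so the
    procedure's set bookkeeping can be exercised against deterministic
    failure oracles without any ODE work.  ``estimator`` receives
    ``(parameters, subset, context)`` and must return an
    :class:`~identestim.estimation.EstimationResult`; ``context`` carries
    ``round`` (1-based re-ranking round), ``attempt`` (0-based within the
    round) and ``n_remaining`` (pool size at round start).  ``rank_fn``
    receives ``(parameters, nonselected, selected)`` and returns
    ``[(name, norm), ...]``.
    """

    mode: str = MODE_INTENSIVE
    estimation: EstimationSettings = field(default_factory=EstimationSettings)
    sensitivity_scheme: str = "forward"
    normalized_ranking: bool = True
    estimator: Callable | None = None
    rank_fn: Callable | None = None
    check_invariants: bool = True
    wall_budget_s: float | None = None  #: optional wall-clock cutoff for real models

    def __post_init__(self):
        if self.mode not in (MODE_INTENSIVE, MODE_FIRST_FAILURE):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class IterationRecord:
    """One estimation attempt."""

    iteration: int            #: global attempt counter (1-based)
    round: int                #: re-ranking round (1-based)
    candidate: str
    rank_position: int        #: position of the candidate in the round's rank
    residual_norm: float
    outcome: str              #: "success" | "failure"
    reason: str | None
    objective_before: float
    objective_after: float
    selected: tuple
    nonselected: tuple
    evaluated: tuple


@dataclass
class ProcedureTrace:
    """Full audit trail of a selection run."""

    mode: str
    candidates: tuple
    iterations: list = field(default_factory=list)
    evaluation_count: int = 0
    initial_objective: float = float("nan")
    final_objective: float = float("nan")
    final_state: RankingState | None = None
    final_result: EstimationResult | None = None
    final_parameters: dict = field(default_factory=dict)
    stopped_early: str | None = None  #: wall-budget note, if tripped

    @property
    def selected(self) -> list:
        return list(self.final_state.selected) if self.final_state else []

    @property
    def evaluated(self) -> list:
        return list(self.final_state.evaluated) if self.final_state else []

    def worst_case_bound(self) -> int:
        n = len(self.candidates)
        return n * (n + 1) // 2

    def to_json(self) -> str:
        payload = {
            "mode": self.mode,
            "candidates": list(self.candidates),
            "evaluation_count": self.evaluation_count,
            "initial_objective": self.initial_objective,
            "final_objective": self.final_objective,
            "selected": self.selected,
            "evaluated": self.evaluated,
            "final_parameters": self.final_parameters,
            "stopped_early": self.stopped_early,
            "iterations": [asdict(r) for r in self.iterations],
        }
        return json.dumps(payload, indent=2)

    def log_lines(self) -> list:
        """Human-readable one-line-per-attempt log."""
        lines = []
        for r in self.iterations:
            lines.append(
                f"iter {r.iteration:3d} round {r.round:2d} "
                f"candidate {r.candidate:<24s} norm {r.residual_norm:10.4g} "
                f"{r.outcome:<7s} S(θ) {r.objective_after:12.6g}"
                + (f" [{r.reason}]" if r.reason else "")
            )
        return lines


def _default_estimator(model, dataset, error_model, settings: ProcedureSettings):
    def call(parameters: Mapping, subset: Sequence[str], context: dict):
        return estimate_subset(
            model, parameters, subset, dataset, error_model, settings.estimation
        )

    return call


def _default_rank_fn(model, dataset, error_model, settings: ProcedureSettings, candidates):
    def call(parameters: Mapping, nonselected: Sequence[str], selected: Sequence[str]):
        # sensitivities recomputed at the CURRENT vector: after every
        # successful re-estimation the ranking sees the updated values,
        # which is what weakens the dependence on initial estimates
        S = compute_sensitivities(
            model,
            parameters,
            dataset,
            scheme=settings.sensitivity_scheme,
            parameter_subset=list(candidates),
            on_column_failure="zero",
            rtol=settings.estimation.rtol,
            atol=settings.estimation.atol,
        )
        sigmas = dataset.sigmas(error_model) if settings.normalized_ranking else None
        return rank_parameters(
            S,
            selected,
            nonselected,
            normalized=settings.normalized_ranking,
            sigmas=sigmas,
        )

    return call


def run(
    model: KineticModel | None,
    dataset: Dataset | None,
    error_model: ErrorModel | None,
    candidates: Sequence[str] | None = None,
    settings: ProcedureSettings | None = None,
    *,
    initial_parameters: Mapping | None = None,
) -> ProcedureTrace:
    """Run the selection procedure to completion.

    Candidates default to all kinetic parameters plus one ``ic_<state>``
    pseudo-parameter per unknown initial condition, the latter seeded by
    :func:`~identestim.model.bootstrap_unknown_ics`.  *initial_parameters*
    optionally overrides entries of the starting vector (e.g. externally
    supplied initial estimates).

    Raises
    ------
    IntegrationFailure
        If the model cannot be simulated at the initial vector (nothing
        is selected in that case; fix the starting point first).
    """
    settings = settings or ProcedureSettings()
    mock_mode = settings.estimator is not None

    if model is not None:
        vector = dict(model.parameters)
        if model.unknown_ics:
            vector.update(bootstrap_unknown_ics(model, dataset=dataset))
        if initial_parameters:
            vector.update(initial_parameters)
        if candidates is None:
            candidates = list(model.parameters) + model.ic_pseudo_parameters()
    else:
        if not mock_mode or settings.rank_fn is None:
            raise ValueError("model-free runs need both estimator and rank_fn")
        vector = dict(initial_parameters or {})
        if candidates is None:
            raise ValueError("model-free runs need an explicit candidate list")
    candidates = list(candidates)

    estimator = settings.estimator or _default_estimator(
        model, dataset, error_model, settings
    )
    rank_fn = settings.rank_fn or _default_rank_fn(
        model, dataset, error_model, settings, candidates
    )

    if not mock_mode:
        dataset.validate_against(model)
        # fail fast and loudly if the starting point is unsimulable
        s0 = objective(
            model, vector, dataset, error_model, settings=settings.estimation
        )
    else:
        s0 = float("nan")

    state = RankingState.initial(candidates)
    trace = ProcedureTrace(
        mode=settings.mode, candidates=tuple(candidates), initial_objective=s0
    )
    incumbent = s0
    t_start = _time.monotonic()
    round_no = 0
    stop_all = False

    while state.nonselected and not stop_all:
        round_no += 1
        rank = rank_fn(dict(vector), list(state.nonselected), list(state.selected))
        ranked_names = [n for n, _ in rank]
        if sorted(ranked_names) != sorted(state.nonselected):
            raise RuntimeError("rank does not cover exactly the non-selected set")
        state.rank = list(rank)
        n_remaining = len(rank)
        for attempt, (name, norm) in enumerate(rank):
            if (
                settings.wall_budget_s is not None
                and _time.monotonic() - t_start > settings.wall_budget_s
            ):
                trace.stopped_early = "wall-budget"
                stop_all = True
                break
            context = {
                "round": round_no,
                "attempt": attempt,
                "n_remaining": n_remaining,
            }
            subset = list(state.selected) + [name]
            result = estimator(dict(vector), subset, context)
            trace.evaluation_count += 1
            state.nonselected.remove(name)
            if result.success:
                vector = dict(result.updated_parameters)
                state.selected.append(name)
                if settings.mode == MODE_INTENSIVE:
                    state.recycle_evaluated()
                incumbent = result.objective
                trace.final_result = result
            else:
                state.evaluated.append(name)
            trace.iterations.append(
                IterationRecord(
                    iteration=trace.evaluation_count,
                    round=round_no,
                    candidate=name,
                    rank_position=attempt + 1,
                    residual_norm=float(norm),
                    outcome="success" if result.success else "failure",
                    reason=result.reason,
                    objective_before=result.entry_objective,
                    objective_after=result.objective,
                    selected=tuple(state.selected),
                    nonselected=tuple(state.nonselected),
                    evaluated=tuple(state.evaluated),
                )
            )
            if settings.check_invariants:
                state.check_partition()
            if result.success:
                break  # re-rank at the updated vector
            if settings.mode == MODE_FIRST_FAILURE:
                stop_all = True
                break
            # failure in intensive mode: fall through to the next entry of
            # the existing rank — the evaluation point has not moved

    trace.final_state = state
    trace.final_objective = incumbent
    trace.final_parameters = dict(vector)
    return trace


@dataclass
class BaselineComparison:
    """Intensive run vs the classical first-failure-stops variant."""

    intensive: ProcedureTrace
    first_failure: ProcedureTrace

    @property
    def intensive_selected_size(self) -> int:
        return len(self.intensive.selected)

    @property
    def first_failure_selected_size(self) -> int:
        return len(self.first_failure.selected)

    @property
    def objective_ratio(self) -> float:
        """first-failure objective / intensive objective (≥ 1 expected)."""
        if self.intensive.final_objective == 0:
            return float("inf") if self.first_failure.final_objective > 0 else 1.0
        return self.first_failure.final_objective / self.intensive.final_objective

    def summary(self) -> dict:
        return {
            "intensive_selected": self.intensive_selected_size,
            "first_failure_selected": self.first_failure_selected_size,
            "intensive_objective": self.intensive.final_objective,
            "first_failure_objective": self.first_failure.final_objective,
            "objective_ratio": self.objective_ratio,
        }


def compare_baseline(
    trace: ProcedureTrace,
    model: KineticModel | None,
    dataset: Dataset | None,
    error_model: ErrorModel | None,
    settings: ProcedureSettings | None = None,
    *,
    initial_parameters: Mapping | None = None,
) -> BaselineComparison:
    """Rerun *trace*'s problem in first-failure mode and compare.

    Identical failure criteria and settings are used in both modes; only
    the stopping rule differs.  The expected ordering — the intensive
    final objective is no worse and its selected set no smaller — is the
    caller's to assert.
    """
    if trace.mode != MODE_INTENSIVE:
        raise ValueError("baseline comparison expects an intensive-mode trace")
    settings = settings or ProcedureSettings()
    ff_settings = ProcedureSettings(
        mode=MODE_FIRST_FAILURE,
        estimation=settings.estimation,
        sensitivity_scheme=settings.sensitivity_scheme,
        normalized_ranking=settings.normalized_ranking,
        estimator=settings.estimator,
        rank_fn=settings.rank_fn,
        check_invariants=settings.check_invariants,
        wall_budget_s=settings.wall_budget_s,
    )
    ff = run(
        model,
        dataset,
        error_model,
        candidates=list(trace.candidates),
        settings=ff_settings,
        initial_parameters=initial_parameters,
    )
    return BaselineComparison(intensive=trace, first_failure=ff)
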