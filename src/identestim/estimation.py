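"""Weighted-least-squares estimation of a parameter subset.

The objective is the maximum-likelihood weighted least squares

    S(θ) = Σ_i (y_i^C − y_i^E)² / σ_{y,i}²,

with diagonal measurement covariance and σ_y = a·y^E + b evaluated on the
*experimental* values, so the weights are a fixed quadratic form during
optimization.  Only the designated subset moves; every other parameter is
frozen at its current value.  At the optimum the Fisher information
matrix FIM = Bᵀ V_Y⁻¹ B over the subset's raw sensitivity columns gives
the covariance V_Θ = FIM⁻¹ and the reported relative uncertainties
σ_θ/θ.

Any of four conditions makes the call a *failure* — optimizer
non-convergence, integration failure during an objective evaluation,
singular FIM at the optimum, or a final objective above the entry
objective — and on failure the parameter vector is handed back unchanged,
so the caller's state stays well defined.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data import Dataset, ErrorModel
from .model import IntegrationFailure, KineticModel
from .sensitivity import DEFAULT_REL_STEP, _predict, compute_sensitivities

__all__ = [
    "ErrorModel",
    "EstimationSettings",
    "EstimationResult",
    "SingularFIMError",
    "objective",
    "compute_fim",
    "estimate_subset",
]

#: reciprocal-condition threshold below which the FIM is declared singular
FIM_RCOND = 1e-10

FAIL_NONCONVERGENCE = "optimizer-nonconvergence"
FAIL_SINGULAR_FIM = "singular-FIM"
FAIL_INTEGRATION = "integration-failure"
FAIL_NONIMPROVEMENT = "objective-nonimprovement"


class SingularFIMError(np.linalg.LinAlgError):
    """FIM reciprocal condition number below threshold; no inversion attempted."""


@dataclass(frozen=True)
class EstimationSettings:
    """Optimizer and diagnostic knobs for one subset estimation."""

    ftol: float = 1e-8
    xtol: float = 1e-8
    max_iter: int = 200            #: cap on optimizer iterations
    log_transform: bool = True     #: estimate strictly positive parameters in log space
    fim_rcond: float = FIM_RCOND
    fd_rel_step: float = DEFAULT_REL_STEP  #: step for post-fit FIM sensitivities
    rtol: float = 1e-6
    atol: float = 1e-9
    # local LM can park in a poor basin; when the converged weighted SSR is
    # far above its χ² expectation (≈ number of records), retry from seeded
    # jittered starts and keep the best minimizer.  Well-fit calls never
    # trigger, so the usual cost is zero.
    restarts: int = 3              #: extra starts when the misfit trigger fires
    restart_trigger: float = 2.0   #: fire when S > trigger · n_records (χ² says ≈1)
    restart_spread: float = 3.0    #: log-uniform jitter factor on the start
    restart_seed: int = 0          #: deterministic restart stream
    # a parameter whose reported σ_θ/θ exceeds this cap carries essentially
    # no information at its optimum (e.g. a rate driven deep into
    # saturation); the subset is then not jointly estimable.  The rcond
    # test cannot see this for single-parameter subsets (scalar FIM), so
    # it is checked explicitly.
    nstd_cap: float = 100.0
    # integrator tolerances for the FIM-check sensitivities (entry and
    # optimum).  Tighter than the fitting tolerances: the singularity test
    # compares columns at the 1e-10 reciprocal-condition level, and the
    # reported σ_θ inherit any solver noise in these columns.
    fim_rtol: float = 1e-9
    fim_atol: float = 1e-12
    fim_scheme: str = "central"    #: FD scheme for the FIM-check sensitivities
    fim_fd_rel_step: float = 1e-5  #: their step: coarse enough to sit above noise


@dataclass
class EstimationResult:
    """Outcome of one weighted-least-squares subset estimation."""

    success: bool
    reason: str | None
    subset: tuple
    estimated_values: dict
    updated_parameters: dict       #: full vector (entry vector on failure)
    objective: float               #: final S(θ) on success, entry value otherwise
    entry_objective: float
    fim: np.ndarray | None = None
    covariance: np.ndarray | None = None
    std: dict = field(default_factory=dict)
    normalized_std: dict = field(default_factory=dict)
    nfev: int = 0

    def to_json(self) -> str:
        payload = {
            "success": self.success,
            "reason": self.reason,
            "subset": list(self.subset),
            "estimated_values": self.estimated_values,
            "objective": self.objective,
            "entry_objective": self.entry_objective,
            "normalized_std": self.normalized_std,
            "fim": None if self.fim is None else self.fim.tolist(),
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "nfev": self.nfev,
        }
        return json.dumps(payload, indent=2)

    def report_table(self, initial_estimates: Mapping | None = None) -> pd.DataFrame:
        """Per-parameter report: initial estimate, estimated value, σ_θ/θ."""
        rows = []
        for name in self.subset:
            rows.append(
                {
                    "parameter": name,
                    "initial_estimate": None
                    if initial_estimates is None
                    else initial_estimates.get(name),
                    "estimated_value": self.estimated_values.get(name),
                    "normalized_standard_deviation": self.normalized_std.get(name),
                }
            )
        return pd.DataFrame(rows)


def _weighted_residuals(
    model: KineticModel,
    parameters: Mapping,
    dataset: Dataset,
    sigmas: np.ndarray,
    settings: EstimationSettings,
) -> np.ndarray:
    y_c = _predict(model, parameters, dataset, rtol=settings.rtol, atol=settings.atol)
    resid = (y_c - dataset.values) / sigmas
    if not np.all(np.isfinite(resid)):
        raise IntegrationFailure("non-finite-residual", "prediction produced NaN/inf")
    return resid


def objective(
    model: KineticModel,
    parameters: Mapping,
    dataset: Dataset,
    error_model: ErrorModel,
    overrides: Mapping | None = None,
    *,
    settings: EstimationSettings | None = None,
) -> float:
    """S(θ) = Σ (y^C − y^E)²/σ², with σ from the error model on the data.

    *overrides* patches individual entries of the full vector (used to
    evaluate trial subset values without mutating the caller's vector).
    """
    settings = settings or EstimationSettings()
    params = dict(model.parameters)
    params.update(parameters)
    if overrides:
        params.update(overrides)
    sig = dataset.sigmas(error_model)
    r = _weighted_residuals(model, params, dataset, sig, settings)
    return float(r @ r)


def compute_fim(
    B_subset: np.ndarray,
    sigmas: np.ndarray,
    theta: Sequence[float],
    *,
    rcond_threshold: float = FIM_RCOND,
):
    """FIM, covariance and uncertainties from raw subset sensitivities.

    FIM = Bᵀ V_Y⁻¹ B with V_Y = diag(σ²).  When the reciprocal condition
    number of the FIM is above *rcond_threshold* it is inverted to the
    covariance V_Θ; σ_θj = sqrt(V_Θ[j, j]) and the normalized standard
    deviation is σ_θj/|θ_j|.

    Returns ``(fim, covariance, std, normalized_std)``.

    Raises
    ------
    SingularFIMError
        If the FIM is numerically singular (no inversion is attempted).
    """
    B = np.asarray(B_subset, dtype=float)
    sig = np.asarray(sigmas, dtype=float)
    theta = np.asarray(theta, dtype=float)
    W = B / sig[:, None]
    fim = W.T @ W
    fim = 0.5 * (fim + fim.T)  # symmetrize roundoff
    # The singularity test runs on the θ-scaled FIM — the information
    # matrix of the relative (log-space) parameterization the optimizer
    # itself uses.  Without the scaling, a parameter of large magnitude
    # and modest relative influence collapses the eigenvalue ratio purely
    # through column-norm disparity, which is conditioning, not
    # non-identifiability.  Genuinely collinear columns are singular in
    # any diagonal scaling.  The scaling also acts as a preconditioner for
    # the covariance inversion.
    scale = np.where(np.abs(theta) > 0, np.abs(theta), 1.0)
    fim_s = fim * np.outer(scale, scale)
    if not np.all(np.isfinite(fim_s)):
        raise SingularFIMError("FIM contains non-finite entries")
    try:
        eigs = np.linalg.eigvalsh(fim_s)
    except np.linalg.LinAlgError as exc:
        raise SingularFIMError(f"FIM eigendecomposition failed: {exc}") from exc
    emax = eigs[-1]
    if emax <= 0 or eigs[0] <= rcond_threshold * emax:
        raise SingularFIMError(
            f"scaled-FIM reciprocal condition "
            f"{0 if emax <= 0 else eigs[0] / emax:.3e} "
            f"below threshold {rcond_threshold:g}"
        )
    cov = np.linalg.inv(fim_s) * np.outer(scale, scale)
    std = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore"):
        nstd = np.where(theta != 0, std / np.abs(theta), np.inf)
    return fim, cov, std, nstd


def estimate_subset(
    model: KineticModel,
    parameters: Mapping,
    subset: Sequence[str],
    dataset: Dataset,
    error_model: ErrorModel,
    settings: EstimationSettings | None = None,
) -> EstimationResult:
    """Estimate *subset* by weighted least squares, others frozen.

    Initial values come from the current full vector, which carries any
    previous re-estimates.  Strictly positive subset entries are optimized
    in log space when ``settings.log_transform`` (keeps concentrations and
    rate constants positive without explicit bounds); non-positive entries
    stay in natural space.

    On success the returned ``updated_parameters`` carries the new values;
    on any failure it is exactly the entry vector (rollback), with
    ``reason`` one of optimizer-nonconvergence, integration-failure,
    singular-FIM, objective-nonimprovement.
    """
    settings = settings or EstimationSettings()
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    entry = dict(model.parameters)
    entry.update(parameters)
    missing = [n for n in subset if n not in entry]
    if missing:
        raise KeyError(f"subset parameters absent from the vector: {missing}")

    sig = dataset.sigmas(error_model)

    def failure(reason, s_entry, nfev=0):
        return EstimationResult(
            success=False,
            reason=reason,
            subset=subset,
            estimated_values={n: entry[n] for n in subset},
            updated_parameters=dict(entry),
            objective=s_entry,
            entry_objective=s_entry,
            nfev=nfev,
        )

    try:
        r0 = _weighted_residuals(model, entry, dataset, sig, settings)
    except IntegrationFailure:
        return failure(FAIL_INTEGRATION, float("nan"))
    s_entry = float(r0 @ r0)

    logged = (
        [entry[n] > 0 for n in subset]
        if settings.log_transform
        else [False] * len(subset)
    )

    def encode(values):
        return np.array(
            [np.log(v) if lg else v for v, lg in zip(values, logged)]
        )

    def decode(x):
        # clip keeps exp finite; absurd magnitudes still fail downstream
        return [
            float(np.exp(min(max(xi, -700.0), 700.0))) if lg else float(xi)
            for xi, lg in zip(x, logged)
        ]

    x0 = encode([entry[n] for n in subset])
    x0_arr = np.asarray(x0, dtype=float)

    # a rank-deficient FIM at the entry point means the weighted
    # least-squares subproblem is ill-posed before any step is taken
    # (e.g. structurally duplicated parameters): fail fast rather than let
    # the optimizer wander along the flat direction
    try:
        S_entry = compute_sensitivities(
            model,
            entry,
            dataset,
            parameter_subset=subset,
            scheme=settings.fim_scheme,
            rel_step=settings.fim_fd_rel_step,
            rtol=settings.fim_rtol,
            atol=settings.fim_atol,
        )
        compute_fim(
            S_entry.raw,
            sig,
            [entry[n] for n in subset],
            rcond_threshold=settings.fim_rcond,
        )
    except IntegrationFailure:
        return failure(FAIL_INTEGRATION, s_entry)
    except SingularFIMError:
        return failure(FAIL_SINGULAR_FIM, s_entry)

    # inside the optimizer an unintegrable trial point returns a steep
    # penalty (pointing back toward the entry) instead of aborting: the
    # trust region backs off and the fit continues.  Failure verdicts are
    # made at the entry point and at the converged point, where the four
    # failure modes keep their meaning.
    penalty_base = 1e4 * max(1.0, np.sqrt(s_entry / len(dataset)))

    def fun(x):
        trial = dict(entry)
        trial.update(zip(subset, decode(x)))
        try:
            return _weighted_residuals(model, trial, dataset, sig, settings)
        except IntegrationFailure:
            dist = float(np.linalg.norm(np.asarray(x) - x0_arr))
            return penalty_base * (1.0 + dist) * np.ones(len(dataset))

    def solve_from(x_start):
        # trust-region reflective with jacobian column scaling: robust to
        # the poorly scaled, occasionally rank-deficient subproblems this
        # procedure generates
        return least_squares(
            fun,
            x_start,
            method="trf",
            x_scale="jac",
            ftol=settings.ftol,
            xtol=settings.xtol,
            max_nfev=settings.max_iter * (len(subset) + 1),
        )

    try:
        res = solve_from(x0)
    except IntegrationFailure:
        return failure(FAIL_INTEGRATION, s_entry)
    nfev_total = res.nfev

    if (
        res.status > 0
        and settings.restarts > 0
        and float(res.fun @ res.fun) > settings.restart_trigger * len(dataset)
    ):
        key = zlib.crc32("|".join(subset).encode()) ^ settings.restart_seed
        rng = np.random.default_rng(key & 0x7FFFFFFF)
        spread = np.log(settings.restart_spread)
        for _ in range(settings.restarts):
            jitter = rng.uniform(-spread, spread, size=len(x0))
            # jitter multiplicatively in log space, additively otherwise
            x_try = np.where(logged, x0 + jitter, np.asarray(x0) * np.exp(jitter))
            try:
                alt = solve_from(x_try)
            except IntegrationFailure:
                continue
            nfev_total += alt.nfev
            if alt.status > 0 and float(alt.fun @ alt.fun) < float(res.fun @ res.fun):
                res = alt
            if float(res.fun @ res.fun) <= settings.restart_trigger * len(dataset):
                break

    if res.status <= 0:
        return failure(FAIL_NONCONVERGENCE, s_entry, nfev_total)
    res_nfev = nfev_total

    values = decode(res.x)
    s_final = float(res.fun @ res.fun)
    if s_final > s_entry * (1 + 1e-10) + 1e-12:
        return failure(FAIL_NONIMPROVEMENT, s_entry, res_nfev)

    updated = dict(entry)
    updated.update(zip(subset, values))

    try:
        S = compute_sensitivities(
            model,
            updated,
            dataset,
            parameter_subset=subset,
            scheme=settings.fim_scheme,
            rel_step=settings.fim_fd_rel_step,
            rtol=settings.fim_rtol,
            atol=settings.fim_atol,
        )
    except IntegrationFailure:
        return failure(FAIL_INTEGRATION, s_entry, res_nfev)
    try:
        fim, cov, std, nstd = compute_fim(
            S.raw, sig, values, rcond_threshold=settings.fim_rcond
        )
    except SingularFIMError:
        return failure(FAIL_SINGULAR_FIM, s_entry, res_nfev)
    if np.max(nstd) > settings.nstd_cap:
        # undetermined at the optimum: same scientific condition as a
        # singular FIM, reported under the same verdict
        return failure(FAIL_SINGULAR_FIM, s_entry, res_nfev)

    return EstimationResult(
        success=True,
        reason=None,
        subset=subset,
        estimated_values=dict(zip(subset, values)),
        updated_parameters=updated,
        objective=s_final,
        entry_objective=s_entry,
        fim=fim,
        covariance=cov,
        std=dict(zip(subset, std)),
        normalized_std=dict(zip(subset, nstd)),
        nfev=res_nfev,
    )
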