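"""Local sensitivity matrix and collinearity-angle screening.

The raw sensitivity matrix B stacks ∂y_i/∂θ_j over all observed
(time, variable) records (rows) by parameters (columns).  Its normalized
form B_N rescales entry-wise by θ_j/y_i so parameters and outputs of
different magnitudes are comparable; each column b_θj is the sensitivity
vector of parameter θ_j.  The angle between two such vectors measures
their linear dependence: pairs near 0° or 180° are practically
indistinguishable from the data at hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import Dataset
from .model import IntegrationFailure, KineticModel, simulate

__all__ = [
    "SensitivityMatrix",
    "compute_sensitivities",
    "collinearity_angles",
    "angles_from_columns",
    "flag_critical_pairs",
]

#: relative finite-difference step, and the parameter-magnitude floor in
#: the step rule h = rel_step·max(|θ|, floor).  The floor sits at the
#: problem's natural mM scale: a parameter that has collapsed toward zero
#: still gets a step large enough for its column to be signal, not solver
#: noise.
DEFAULT_REL_STEP = 1e-6
THETA_FLOOR = 0.1
#: |y| floor (mM) used when normalizing rows.  Set at 1 nM: far below any
#: measurable metabolite concentration but far above integration noise,
#: so near-zero predictions neither blow up the relative scaling nor let
#: solver noise masquerade as sensitivity.
EPS_Y = 1e-6


@dataclass(frozen=True)
class SensitivityMatrix:
    """Raw and normalized sensitivities at a recorded evaluation point.

    Rows correspond one-to-one (and in order) with the dataset records;
    columns with ``parameter_names``.
    """

    raw: np.ndarray
    normalized: np.ndarray
    parameter_names: tuple
    records: pd.DataFrame
    evaluation_point: dict
    predictions: np.ndarray

    def __post_init__(self):
        if self.raw.shape != self.normalized.shape:
            raise ValueError("raw and normalized shapes differ")
        if self.raw.shape[1] != len(self.parameter_names):
            raise ValueError("column count does not match parameter names")
        if self.raw.shape[0] != len(self.records):
            raise ValueError("row count does not match dataset records")

    @property
    def shape(self):
        return self.raw.shape

    def column_index(self, name: str) -> int:
        try:
            return self.parameter_names.index(name)
        except ValueError:
            raise KeyError(f"no sensitivity column for parameter {name!r}") from None

    def column(self, name: str, normalized: bool = True) -> np.ndarray:
        """Sensitivity vector b_θ for one parameter."""
        j = self.column_index(name)
        return (self.normalized if normalized else self.raw)[:, j]

    def columns(self, names: Sequence[str], normalized: bool = True) -> np.ndarray:
        idx = [self.column_index(n) for n in names]
        return (self.normalized if normalized else self.raw)[:, idx]


def _predict(model: KineticModel, parameters: Mapping, dataset: Dataset,
             **sim_kwargs) -> np.ndarray:
    """Model predictions aligned with the dataset's records."""
    times = dataset.unique_times()
    traj = simulate(model, parameters, times, **sim_kwargs)
    rows = traj.loc[dataset.times]
    return np.array(
        [rows.iloc[i][v] for i, v in enumerate(dataset.variables)], dtype=float
    )


def compute_sensitivities(
    model: KineticModel,
    parameters: Mapping,
    dataset: Dataset,
    *,
    scheme: str = "forward",
    rel_step: float = DEFAULT_REL_STEP,
    theta_floor: float = THETA_FLOOR,
    eps_y: float = EPS_Y,
    parameter_subset: Sequence[str] | None = None,
    on_column_failure: str = "raise",
    **sim_kwargs,
) -> SensitivityMatrix:
    """Finite-difference sensitivities of the observed outputs.

    Perturbs one parameter at a time by ``rel_step·max(|θ|, theta_floor)``
    (one- or two-sided per *scheme*) and differences the model predictions
    at every dataset record.  Initial-condition pseudo-parameters
    (``ic_<state>`` entries of *parameters*) are perturbed exactly like
    kinetic parameters.

    Normalization multiplies entry (i, j) by θ_j / y_i, with |y_i| floored
    at *eps_y* so records where the prediction sits at zero do not blow up
    the ranking.

    ``on_column_failure`` decides what an integration failure at a
    *perturbed* point means: ``"raise"`` propagates the typed failure,
    ``"zero"`` records a zero column — the parameter is unevaluable at
    this point and will rank least estimable.  A failure at the
    unperturbed evaluation point always raises.

    Raises
    ------
    IntegrationFailure
        If the model cannot be simulated at the evaluation point, or (with
        ``on_column_failure="raise"``) at any perturbed point.
    """
    if scheme not in ("forward", "central"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if on_column_failure not in ("raise", "zero"):
        raise ValueError(f"unknown on_column_failure {on_column_failure!r}")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    params = dict(model.parameters)
    params.update(parameters)
    names = tuple(parameter_subset) if parameter_subset is not None else tuple(params)
    missing = [n for n in names if n not in params]
    if missing:
        raise KeyError(f"parameters not in vector: {missing}")

    y0 = _predict(model, params, dataset, **sim_kwargs)
    raw = np.empty((len(dataset), len(names)))
    for j, name in enumerate(names):
        theta = params[name]
        h = rel_step * max(abs(theta), theta_floor)
        try:
            hi = dict(params)
            hi[name] = theta + h
            y_hi = _predict(model, hi, dataset, **sim_kwargs)
            if scheme == "central":
                lo = dict(params)
                lo[name] = theta - h
                y_lo = _predict(model, lo, dataset, **sim_kwargs)
                raw[:, j] = (y_hi - y_lo) / (2.0 * h)
            else:
                raw[:, j] = (y_hi - y0) / h
        except IntegrationFailure:
            if on_column_failure == "raise":
                raise
            raw[:, j] = 0.0

    theta_vec = np.array([params[n] for n in names])
    y_safe = np.maximum(np.abs(y0), eps_y)
    normalized = raw * theta_vec[None, :] / y_safe[:, None]
    return SensitivityMatrix(
        raw=raw,
        normalized=normalized,
        parameter_names=names,
        records=dataset.records.copy(),
        evaluation_point={n: params[n] for n in names},
        predictions=y0,
    )


def angles_from_columns(B: np.ndarray) -> np.ndarray:
    """Pairwise angles (degrees, in [0, 180]) between the columns of *B*.

    Zero-norm columns give NaN rows/columns (degenerate: the angle is
    undefined); the diagonal is exactly 0 for non-degenerate columns.
    """
    B = np.asarray(B, dtype=float)
    norms = np.linalg.norm(B, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = (B.T @ B) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    np.fill_diagonal(ang, 0.0)
    degenerate = norms == 0.0
    ang[degenerate, :] = np.nan
    ang[:, degenerate] = np.nan
    return ang


def collinearity_angles(
    S: SensitivityMatrix, *, normalized: bool = True
) -> pd.DataFrame:
    """Symmetric matrix of collinearity angles ∠(i, j) over all parameter
    pairs, ∠ = arccos(b_i·b_j / (‖b_i‖‖b_j‖)) in degrees.

    Values near 90° indicate linearly independent sensitivity vectors;
    values near 0° or 180° flag pairs whose effects on the observed
    outputs are (anti)parallel and hence not separable in a pair.
    Degenerate (zero) columns yield NaN.
    """
    if S.shape[1] < 2:
        raise ValueError("need at least two parameter columns")
    B = S.normalized if normalized else S.raw
    ang = angles_from_columns(B)
    names = list(S.parameter_names)
    return pd.DataFrame(ang, index=names, columns=names)


def flag_critical_pairs(
    angles: pd.DataFrame, *, low: float = 5.0, high: float = 175.0
) -> pd.DataFrame:
    """Parameter pairs with critical collinearity: ∠ < *low* or ∠ > *high*.

    Returns a table with columns (parameter_i, parameter_j, angle_deg),
    one row per unordered pair, sorted by distance from 90°.  Degenerate
    (NaN) pairs are listed separately with angle NaN.
    """
    names = list(angles.index)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = angles.iat[i, j]
            if np.isnan(a) or a < low or a > high:
                rows.append((names[i], names[j], a))
    out = pd.DataFrame(rows, columns=["parameter_i", "parameter_j", "angle_deg"])
    if len(out):
        out = out.sort_values(
            "angle_deg", key=lambda s: np.where(np.isnan(s), np.inf, np.minimum(s, 180 - s))
        ).reset_index(drop=True)
    return out
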