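"""Estimability ranking by sensitivity norms with Gram-Schmidt discounting.

With nothing yet selected, the most estimable parameter is the one whose
sensitivity vector has the largest Euclidean norm.  Once parameters have
been selected, each remaining candidate column is orthogonalized against
the span of the selected columns (modified Gram-Schmidt) and ranked by
the norm of the residual, so influence that is linearly dependent on the
already-selected set is discounted.  Orthogonalization is against the
selected set only — parameters that merely failed earlier do not discount
anything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sensitivity import SensitivityMatrix

__all__ = ["RankingState", "rank_parameters", "residual_norms"]

#: relative pivot-drop tolerance for near-dependent selected columns
PIVOT_TOL = 1e-12


@dataclass
class RankingState:
    """The three disjoint parameter sets maintained by the selection
    procedure, plus the current rank over the non-selected set.

    ``selected`` is ordered (inclusion order); ``nonselected`` and
    ``evaluated`` are kept as ordered lists for deterministic iteration
    but behave as sets.
    """

    candidates: tuple
    selected: list = field(default_factory=list)
    nonselected: list = field(default_factory=list)
    evaluated: list = field(default_factory=list)
    rank: list = field(default_factory=list)  # [(name, residual_norm)]

    @classmethod
    def initial(cls, candidates: Sequence[str]) -> "RankingState":
        """All candidates start non-selected."""
        cand = tuple(candidates)
        if len(set(cand)) != len(cand):
            raise ValueError("duplicate candidate names")
        return cls(candidates=cand, nonselected=list(cand))

    def check_partition(self) -> None:
        """Assert Θ^(S) ∪ Θ^(NS) ∪ Θ^(E) partitions the candidate set."""
        union = self.selected + self.nonselected + self.evaluated
        if len(union) != len(set(union)) or set(union) != set(self.candidates):
            raise AssertionError(
                "selected/nonselected/evaluated do not partition the candidates: "
                f"S={self.selected} NS={self.nonselected} E={self.evaluated}"
            )

    def recycle_evaluated(self) -> None:
        """Return every evaluated parameter to the non-selected pool."""
        self.nonselected.extend(self.evaluated)
        self.evaluated.clear()


def _orthonormal_basis(B: np.ndarray, pivot_tol: float) -> np.ndarray:
    """Orthonormal basis of the column span of *B* via modified
    Gram-Schmidt, dropping near-dependent pivots."""
    if B.size == 0:
        return np.empty((B.shape[0], 0))
    scale = np.linalg.norm(B, axis=0).max()
    if scale == 0.0:
        return np.empty((B.shape[0], 0))
    basis = []
    dropped = 0
    for j in range(B.shape[1]):
        v = B[:, j].astype(float).copy()
        for q in basis:
            v -= (q @ v) * q
        nrm = np.linalg.norm(v)
        if nrm <= pivot_tol * scale:
            dropped += 1
            continue
        basis.append(v / nrm)
    if dropped:
        warnings.warn(
            f"{dropped} selected column(s) linearly dependent on the others; "
            "skipped during orthogonalization",
            stacklevel=3,
        )
    return np.column_stack(basis) if basis else np.empty((B.shape[0], 0))


def residual_norms(
    B_candidates: np.ndarray,
    B_selected: np.ndarray,
    *,
    pivot_tol: float = PIVOT_TOL,
) -> np.ndarray:
    """Norms of candidate columns after projecting out the selected span."""
    Q = _orthonormal_basis(B_selected, pivot_tol)
    resid = B_candidates - Q @ (Q.T @ B_candidates) if Q.shape[1] else B_candidates
    return np.linalg.norm(resid, axis=0)


def rank_parameters(
    S: SensitivityMatrix,
    selected: Sequence[str] = (),
    candidates: Sequence[str] | None = None,
    *,
    normalized: bool = True,
    sigmas=None,
    pivot_tol: float = PIVOT_TOL,
) -> list:
    """Rank candidates from most to least estimable.

    Each candidate's sensitivity column is orthogonalized against the span
    of the selected columns and candidates are ordered by descending
    residual norm.  Ties (and the empty-selected case, which reduces to a
    pure norm ranking) break by declaration order, keeping runs
    deterministic.

    With *sigmas* (per-record measurement standard deviations) the ranking
    operates on information-normalized columns ``(∂y_i/∂θ_j)·θ_j/σ_i`` —
    the log-parameter columns of the weighted estimation problem, so the
    rank measures exactly the marginal information each candidate adds.
    Under a proportional error model σ ≈ a·y this coincides with the
    relative (θ/y) normalization up to the constant a, with the additive
    floor b keeping near-zero records bounded.  Without *sigmas* the
    ranking uses the normalized (or raw) matrix as stored.

    Returns ``[(parameter, residual_norm), ...]`` in rank order.
    """
    if candidates is None:
        candidates = [n for n in S.parameter_names if n not in set(selected)]
    else:
        candidates = list(candidates)
    overlap = set(candidates) & set(selected)
    if overlap:
        raise ValueError(f"candidates overlap the selected set: {sorted(overlap)}")
    if sigmas is not None:
        sig = np.asarray(sigmas, dtype=float)
        if sig.shape != (S.raw.shape[0],) or np.any(sig <= 0):
            raise ValueError("sigmas must be positive, one per record")
        theta = np.array([S.evaluation_point[n] for n in S.parameter_names])
        W = S.raw * theta[None, :] / sig[:, None]
        idx = {n: j for j, n in enumerate(S.parameter_names)}
        B_sel = W[:, [idx[n] for n in selected]]
        B_cand = W[:, [idx[n] for n in candidates]]
    else:
        B_sel = S.columns(list(selected), normalized=normalized)
        B_cand = S.columns(candidates, normalized=normalized)
    norms = residual_norms(B_cand, B_sel, pivot_tol=pivot_tol)
    # stable sort on -norm preserves declaration order among ties
    order = np.argsort(-norms, kind="stable")
    return [(candidates[i], float(norms[i])) for i in order]
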