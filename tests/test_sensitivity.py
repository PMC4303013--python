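"""Sensitivity matrices and collinearity angles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from identestim import (
    Dataset,
    KineticModel,
    compute_sensitivities,
    collinearity_angles,
    flag_critical_pairs,
)
from identestim.sensitivity import SensitivityMatrix, angles_from_columns


def _matrix_from_columns(B):
    """Wrap bare columns in a SensitivityMatrix (records are synthetic)."""
    import pandas as pd

    n, p = B.shape
    records = pd.DataFrame(
        {"time": np.arange(n, dtype=float), "variable": "y", "value": 0.0}
    )
    names = tuple(f"p{j}" for j in range(p))
    return SensitivityMatrix(
        raw=B,
        normalized=B,
        parameter_names=names,
        records=records,
        evaluation_point=dict.fromkeys(names, 1.0),
        predictions=np.zeros(n),
    )


class TestComputeSensitivities:
    def test_linear_model_exact_columns(self, linear_growth_model):
        """y = θ·t: raw column is t, normalized column is identically 1."""
        ds = Dataset.from_records([(1.0, "Y", 3.0), (2.0, "Y", 6.0)])
        S = compute_sensitivities(linear_growth_model, {}, ds)
        assert np.allclose(S.column("rate_k", normalized=False), [1.0, 2.0], rtol=1e-5)
        assert np.allclose(S.column("rate_k"), [1.0, 1.0], rtol=1e-5)

    def test_inactive_parameter_gives_zero_column(self, linear_growth_model):
        model = linear_growth_model.with_parameters({"unused": 5.0})
        ds = Dataset.from_records([(1.0, "Y", 3.0), (2.0, "Y", 6.0)])
        S = compute_sensitivities(model, {}, ds)
        assert np.allclose(S.column("unused"), 0.0)

    def test_central_differences_match_forward_sensitivity_oracle(self, mm_chain):
        """FD sensitivities agree with an independently integrated
        forward-sensitivity (variational) system on the enzyme chain."""
        from scipy.integrate import solve_ivp

        model, truth = mm_chain
        times = [2.0, 10.0, 40.0]
        ds = Dataset.from_records(
            [(t, s, 1.0) for t in times for s in model.state_names]
        )
        S = compute_sensitivities(
            model, truth, ds, scheme="central", rel_step=1e-6,
            rtol=1e-10, atol=1e-12,
        )

        # oracle: hand-derived Michaelis-Menten partials, augmented ODE
        names = [f"S{i}" for i in range(4)]
        pnames = list(S.parameter_names)
        v = [truth[f"vmax_{i}"] for i in (1, 2, 3)]
        k = [truth[f"km_{i}"] for i in (1, 2, 3)]

        def rates(c):
            return [v[i] * c[i] / (k[i] + c[i]) for i in range(3)]

        def drate_dc(c, i):  # ∂r_i/∂S_{i}
            return v[i] * k[i] / (k[i] + c[i]) ** 2

        def rhs(t, z):
            c, sens = z[:4], z[4:].reshape(4, 6)
            r = rates(c)
            dc = np.array([-r[0], r[0] - r[1], r[1] - r[2], r[2]])
            # jacobian wrt states: each rate depends on its substrate only
            J = np.zeros((4, 4))
            for i in range(3):
                g = drate_dc(c, i)
                J[i, i] -= g
                J[i + 1, i] += g
            # ∂f/∂θ columns in pnames order (vmax_i, km_i pairs)
            F = np.zeros((4, 6))
            for i in range(3):
                dv = c[i] / (k[i] + c[i])            # ∂r_i/∂vmax_i
                dk = -v[i] * c[i] / (k[i] + c[i]) ** 2  # ∂r_i/∂km_i
                for dval, pname in ((dv, f"vmax_{i+1}"), (dk, f"km_{i+1}")):
                    j = pnames.index(pname)
                    F[i, j] -= dval
                    F[i + 1, j] += dval
            dsens = J @ sens + F
            return np.concatenate([dc, dsens.ravel()])

        z0 = np.concatenate(
            [[model.initial_conditions[s] for s in names], np.zeros(24)]
        )
        sol = solve_ivp(rhs, (0, times[-1]), z0, t_eval=times,
                        rtol=1e-10, atol=1e-12, method="LSODA")
        # reshape oracle to match the dataset's (time, variable) record order
        expected = np.empty_like(S.raw)
        for row, (t, var) in enumerate(
            zip(S.records["time"], S.records["variable"])
        ):
            ti = times.index(t)
            si = names.index(var)
            expected[row] = sol.y[4:, ti].reshape(4, 6)[si]
        scale = np.abs(expected).max()
        assert np.allclose(S.raw, expected, atol=1e-4 * scale)

    def test_central_difference_halving_converges_quadratically(self, mm_chain):
        model, truth = mm_chain
        ds = Dataset.from_records([(5.0, "S1", 1.0), (20.0, "S2", 1.0)])
        kw = dict(scheme="central", rtol=1e-12, atol=1e-14)
        S_h = compute_sensitivities(model, truth, ds, rel_step=1e-3, **kw)
        S_h2 = compute_sensitivities(model, truth, ds, rel_step=5e-4, **kw)
        S_ref = compute_sensitivities(model, truth, ds, rel_step=1e-5, **kw)
        err_h = np.abs(S_h.raw - S_ref.raw).max()
        err_h2 = np.abs(S_h2.raw - S_ref.raw).max()
        # halving the step should cut the truncation error by about 4
        assert err_h2 < err_h / 2.5


class TestCollinearityAngles:
    def test_orthogonal_vectors_90_degrees(self):
        ang = angles_from_columns(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert ang[0, 1] == pytest.approx(90.0)

    def test_antiparallel_vectors_180_degrees(self):
        B = np.array([[1.0, -2.0], [1.0, -2.0]])
        ang = angles_from_columns(B)
        assert ang[0, 1] == pytest.approx(180.0)

    def test_symmetry_range_and_zero_diagonal(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(12, 6))
        ang = angles_from_columns(B)
        assert np.allclose(ang, ang.T)
        assert np.all((ang >= 0) & (ang <= 180))
        assert np.allclose(np.diag(ang), 0.0)

    @given(scale=st.floats(0.1, 1e6), flip=st.booleans())
    @settings(max_examples=50, deadline=None)
    def test_scaling_a_column_preserves_or_reflects_angles(self, scale, flip):
        rng = np.random.default_rng(11)
        B = rng.normal(size=(9, 3))
        before = angles_from_columns(B)[0, 1]
        B2 = B.copy()
        B2[:, 0] *= -scale if flip else scale
        after = angles_from_columns(B2)[0, 1]
        expected = 180.0 - before if flip else before
        assert after == pytest.approx(expected, abs=1e-8)

    def test_random_high_dimensional_vectors_concentrate_near_90(self):
        """In high dimension random sensitivity vectors are nearly
        orthogonal, matching the screen's typical empirical histogram."""
        rng = np.random.default_rng(123)
        B = rng.normal(size=(50, 20))
        ang = angles_from_columns(B)
        off = ang[np.triu_indices(20, k=1)]
        # direct dot-product oracle per pair
        for i, j in zip(*np.triu_indices(20, k=1)):
            cos = B[:, i] @ B[:, j] / (
                np.linalg.norm(B[:, i]) * np.linalg.norm(B[:, j])
            )
            assert np.degrees(np.arccos(np.clip(cos, -1, 1))) == pytest.approx(
                ang[i, j], abs=1e-10
            )
        assert np.mean(np.abs(off - 90.0) < 20.0) > 0.9

    def test_zero_column_reported_degenerate(self):
        B = np.array([[1.0, 0.0], [2.0, 0.0]])
        ang = angles_from_columns(B)
        assert np.isnan(ang[0, 1])

    def test_flagging_critical_pairs(self):
        B = np.column_stack(
            [
                [1.0, 0.0, 0.0],
                [1.0, 0.01, 0.0],   # ~0.6 degrees from the first
                [0.0, 1.0, 0.0],
                [-1.0, 0.0, 1e-4],  # ~180 degrees from the first
            ]
        )
        S = _matrix_from_columns(B)
        ang = collinearity_angles(S)
        flagged = flag_critical_pairs(ang, low=5.0, high=175.0)
        pairs = {
            frozenset((r.parameter_i, r.parameter_j)) for r in flagged.itertuples()
        }
        assert frozenset(("p0", "p1")) in pairs
        assert frozenset(("p0", "p3")) in pairs
        assert frozenset(("p0", "p2")) not in pairs
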