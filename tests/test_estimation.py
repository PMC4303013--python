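"""Weighted least squares, FIM diagnostics, failure semantics."""

import numpy as np
import pytest

from identestim import (
    Dataset,
    ErrorModel,
    KineticModel,
    SingularFIMError,
    compute_fim,
    estimate_subset,
    objective,
)
from identestim.estimation import EstimationSettings
from identestim.model import ic_parameter


def make_affine_model(duplicate=False):
    """y(t) = ic + (θ1 [+ θ3])·t — analytically transparent test model."""
    params = {"theta1": 2.0}
    if duplicate:
        params["theta3"] = 0.5

        def law(c, p):
            return p["theta1"] + p["theta3"]

    else:

        def law(c, p):
            return p["theta1"]

    return KineticModel(
        state_names=("Y",),
        parameters=params,
        rate_laws={"r": law},
        stoichiometry={"r": {"Y": 1}},
        initial_conditions={"Y": 1.0},
        unknown_ics=frozenset({"Y"}),
    )


def affine_dataset(slope=2.0, intercept=1.0, times=(1.0, 2.0, 4.0, 8.0)):
    return Dataset.from_records(
        [(t, "Y", intercept + slope * t) for t in times]
    )


class TestObjective:
    def test_perfect_fit_is_zero(self):
        model = make_affine_model()
        ds = affine_dataset()
        em = ErrorModel(a=0.1, b=1e-5)
        s = objective(model, {"theta1": 2.0, ic_parameter("Y"): 1.0}, ds, em)
        assert s == pytest.approx(0.0, abs=1e-8)

    def test_single_record_hand_arithmetic(self):
        """y^E = 2, y^C = 3, a = 0.1, b = 1e-5: σ = 0.20001, S = (1/σ)²."""
        model = make_affine_model()
        # ic = 1, θ1 = 1, t = 1 → y^C = 2... choose θ1 = 2 → y^C = 3
        ds = Dataset.from_records([(1.0, "Y", 2.0)])
        em = ErrorModel(a=0.1, b=1e-5)
        s = objective(model, {"theta1": 2.0, ic_parameter("Y"): 1.0}, ds, em)
        assert s == pytest.approx((1.0 / 0.20001) ** 2, rel=1e-6)
        assert s == pytest.approx(24.9975, rel=1e-4)

    def test_doubling_error_coefficients_quarters_objective(self):
        model = make_affine_model()
        ds = affine_dataset(slope=2.5)
        p = {"theta1": 2.0, ic_parameter("Y"): 1.0}
        s1 = objective(model, p, ds, ErrorModel(a=0.1, b=1e-5))
        s2 = objective(model, p, ds, ErrorModel(a=0.2, b=2e-5))
        assert s2 == pytest.approx(s1 / 4.0, rel=1e-9)


class TestComputeFim:
    def test_scalar_closed_form(self):
        s, sigma, theta = 3.0, 0.5, 2.0
        fim, cov, std, nstd = compute_fim([[s]], [sigma], [theta])
        assert fim[0, 0] == pytest.approx(s**2 / sigma**2)
        assert std[0] == pytest.approx(sigma / abs(s))
        assert nstd[0] == pytest.approx(sigma / abs(s) / theta)

    def test_orthogonal_columns_give_diagonal_fim(self):
        B = np.array([[1.0, 0.0], [0.0, 2.0], [0.0, 0.0]])
        fim, cov, std, _ = compute_fim(B, np.full(3, 0.5), [1.0, 1.0])
        assert fim[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert cov[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_fim_times_covariance_is_identity(self):
        rng = np.random.default_rng(2)
        B = rng.normal(size=(12, 4))
        theta = rng.uniform(0.5, 2.0, size=4)
        fim, cov, _, _ = compute_fim(B, np.full(12, 0.3), theta)
        assert np.allclose(fim @ cov, np.eye(4), atol=1e-8)

    def test_collinear_columns_raise_singular(self):
        B = np.column_stack([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        with pytest.raises(SingularFIMError):
            compute_fim(B, np.full(3, 0.1), [1.0, 1.0])

    def test_fim_symmetry_and_psd(self):
        rng = np.random.default_rng(8)
        B = rng.normal(size=(30, 5))
        fim, _, _, _ = compute_fim(B, np.full(30, 0.2), np.ones(5))
        assert np.linalg.norm(fim - fim.T) <= 1e-10 * np.linalg.norm(fim)
        assert np.all(np.linalg.eigvalsh(fim) >= -1e-10)


class TestEstimateSubset:
    EM = ErrorModel(a=0.05, b=1e-4)

    def test_exact_affine_recovery(self):
        model = make_affine_model()
        ds = affine_dataset(slope=2.0, intercept=1.0)
        start = {"theta1": 0.7, ic_parameter("Y"): 0.3}
        res = estimate_subset(
            model, start, ["theta1", ic_parameter("Y")], ds, self.EM
        )
        assert res.success
        assert res.estimated_values["theta1"] == pytest.approx(2.0, abs=1e-6)
        assert res.estimated_values[ic_parameter("Y")] == pytest.approx(1.0, abs=1e-6)
        assert res.objective == pytest.approx(0.0, abs=1e-8)
        assert res.objective <= res.entry_objective

    def test_structural_duplicate_fails_singular_fim(self):
        model = make_affine_model(duplicate=True)
        ds = affine_dataset(slope=2.5)
        res = estimate_subset(
            model,
            {"theta1": 2.0, "theta3": 0.5, ic_parameter("Y"): 1.0},
            ["theta1", "theta3"],
            ds,
            self.EM,
        )
        assert not res.success
        assert res.reason == "singular-FIM"

    def test_failure_rolls_back_the_vector(self):
        model = make_affine_model(duplicate=True)
        ds = affine_dataset(slope=2.5)
        start = {"theta1": 1.7, "theta3": 0.4, ic_parameter("Y"): 0.9}
        res = estimate_subset(model, start, ["theta1", "theta3"], ds, self.EM)
        assert not res.success
        assert res.updated_parameters == start

    def test_non_subset_parameters_untouched(self):
        model = make_affine_model()
        ds = affine_dataset()
        start = {"theta1": 1.2, ic_parameter("Y"): 0.8}
        res = estimate_subset(model, start, ["theta1"], ds, self.EM)
        assert res.success
        assert res.updated_parameters[ic_parameter("Y")] == 0.8

    def test_error_model_scale_does_not_break_estimation(self, mm_chain):
        """Two different (a, b) settings both complete and both improve
        their own objectives (the selected values may differ)."""
        from identestim import simulate

        model, truth = mm_chain
        times = np.geomspace(1, 100, 10)
        traj = simulate(model, truth, times)
        records = [(float(t), "S3", float(traj.at[t, "S3"])) for t in times]
        start = {k: v * 1.3 for k, v in truth.items()}
        for em in (ErrorModel(1e-1, 1e-5), ErrorModel(1e-2, 1e-6)):
            ds = Dataset.from_records(records, em)
            res = estimate_subset(model, start, ["vmax_3"], ds, em)
            assert res.success
            assert res.objective <= res.entry_objective

    def test_report_table_layout(self):
        model = make_affine_model()
        ds = affine_dataset()
        start = {"theta1": 1.5, ic_parameter("Y"): 0.9}
        res = estimate_subset(model, start, ["theta1"], ds, self.EM)
        table = res.report_table(initial_estimates=start)
        assert list(table.columns) == [
            "parameter",
            "initial_estimate",
            "estimated_value",
            "normalized_standard_deviation",
        ]
        assert table.loc[0, "parameter"] == "theta1"
        assert table.loc[0, "initial_estimate"] == 1.5
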