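"""Rate laws, parameter validation, QSS mark curves and effective Hill fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episwitch.model import (
    THETA_KEYS,
    HillFit,
    ModelParams,
    QSSCurves,
    StateVars,
    default_x_grid,
    effective_hill,
    mark_root_sets,
    qss_marks,
    rates_marks,
    rates_tf,
    response_curve,
)


def make_params(th=None, **kw):
    theta = {k: 1.0 for k in THETA_KEYS}
    if th:
        theta.update(th)
    defaults = dict(rho=1.0, C1=2.0, C2=0.5, C4=1.0, Lambda_A=1.0, Lambda_I=1.0,
                    rho_A=1.0, rho_I=1.0, Omega_T=100, Omega_S=10)
    defaults.update(kw)
    return ModelParams(theta=theta, **defaults)


class TestValidation:
    def test_theta_must_have_exactly_16_keys(self):
        theta = {k: 1.0 for k in THETA_KEYS[:-1]}
        with pytest.raises(ValueError, match="lambda_I"):
            ModelParams(theta=theta)
        theta = {k: 1.0 for k in THETA_KEYS}
        theta["bogus"] = 1.0
        with pytest.raises(ValueError, match="bogus"):
            ModelParams(theta=theta)

    def test_negative_theta_rejected(self):
        theta = {k: 1.0 for k in THETA_KEYS}
        theta["K6"] = -0.1
        with pytest.raises(ValueError, match="K6"):
            ModelParams(theta=theta)

    def test_slow_fast_assumption_enforced(self):
        with pytest.raises(ValueError, match="eps2"):
            make_params(Omega_T=10, Omega_S=10)

    def test_state_bounds(self):
        p = make_params()
        with pytest.raises(ValueError):
            StateVars(x=-1.0, q_A=0.5, q_I=0.5).validate(p)
        with pytest.raises(ValueError):
            StateVars(x=1.0, q_A=1.5, q_I=0.5).validate(p)

    def test_with_theta_rejects_unknown_component(self):
        with pytest.raises(ValueError, match="unknown"):
            make_params().with_theta(K99=1.0)


class TestTFRates:
    def test_zero_tf_limit(self):
        p = make_params()
        B, D = rates_tf(StateVars(x=0.0, q_A=0.5, q_I=0.5), p)
        assert B == p.rho
        assert D == 0.0

    def test_hand_evaluated_example(self):
        # rho=1, C1=2, C2=0.5, C4=1, lambda_x=1, x=qA=qI=1:
        # h = 1/2, B = 1 + 3/2 = 2.5, D = 0.5 + 0.5 = 1.0
        p = make_params()
        B, D = rates_tf(StateVars(x=1.0, q_A=1.0, q_I=1.0), p)
        assert B == pytest.approx(2.5, abs=1e-12)
        assert D == pytest.approx(1.0, abs=1e-12)

    def test_saturation_limit(self):
        p = make_params(C4=0.0)
        B, _ = rates_tf(StateVars(x=1e8, q_A=1.0, q_I=1e-8), p)
        assert B == pytest.approx(p.rho * (1 + p.C1), rel=1e-6)

    def test_shared_fraction_zero_at_origin(self):
        # 0/0 point (x=0, q_I=0) defined as 0: basal rates only
        p = make_params()
        B, D = rates_tf(StateVars(x=0.0, q_A=0.0, q_I=0.0), p)
        assert (B, D) == (p.rho, 0.0)


class TestMarkRates:
    def test_removal_vanishes_without_marks(self):
        p = make_params()
        _, DA, _, DI = rates_marks(StateVars(x=2.0, q_A=0.0, q_I=0.0), p)
        assert DA == 0.0 and DI == 0.0

    def test_hand_evaluated_addition_rate(self):
        # Lambda_A=1, rho_A=1, A1=A3=B2=K2=1, q_A=0: B_A = 1*1*1/(1+1) = 0.5
        p = make_params()
        BA, _, _, _ = rates_marks(StateVars(x=3.0, q_A=0.0, q_I=0.5), p)
        assert BA == pytest.approx(0.5, abs=1e-12)

    def test_addition_vanishes_at_capacity(self):
        p = make_params()
        BA, _, BI, _ = rates_marks(StateVars(x=1.0, q_A=p.rho_A, q_I=p.rho_I), p)
        assert BA == 0.0 and BI == 0.0

    def test_vanishing_denominator_raises_with_diagnostic(self):
        p = make_params(th={"A1": 0.0, "B2": 0.0, "K2": 0.0})
        with pytest.raises(ZeroDivisionError, match="B2"):
            rates_marks(StateVars(x=0.0, q_A=0.5, q_I=0.5), p)


@st.composite
def random_state_params(draw):
    theta = {k: draw(st.floats(0.01, 10.0)) for k in THETA_KEYS}
    p = ModelParams(theta=theta,
                    rho=draw(st.floats(0.01, 10.0)),
                    C1=draw(st.floats(0.0, 20.0)),
                    C2=draw(st.floats(0.01, 10.0)),
                    C4=draw(st.floats(0.0, 10.0)),
                    Omega_T=100, Omega_S=10)
    s = StateVars(x=draw(st.floats(0.0, 50.0)),
                  q_A=draw(st.floats(0.0, 1.0)),
                  q_I=draw(st.floats(0.0, 1.0)))
    return p, s


@given(random_state_params())
@settings(max_examples=200, deadline=None, derandomize=True)
def test_all_rates_nonnegative_and_finite(ps):
    p, s = ps
    B, D = rates_tf(s, p)
    BA, DA, BI, DI = rates_marks(s, p)
    for r in (B, D, BA, DA, BI, DI):
        assert np.isfinite(r) and r >= 0.0


class TestQSS:
    def test_demethylation_off_gives_full_occupancy(self):
        p = make_params(th={"K6": 0.0})
        q = qss_marks(p, np.geomspace(0.01, 5, 50))
        assert np.allclose(q.qA_star, p.rho_A)

    def test_matches_dense_grid_oracle(self, bistable_params):
        p = bistable_params
        grid = default_x_grid(p, n=30)
        q = qss_marks(p, grid)
        from episwitch.model import _rates_A_arrays, _rates_I_arrays
        for i in (0, 10, 20, 29):
            qs = np.linspace(0, p.rho_A, 10_000)
            BA, DA = _rates_A_arrays(grid[i], qs, p)
            best = qs[np.argmin(np.abs(BA - DA))]
            assert abs(best - q.qA_star[i]) < 2e-4
            qs = np.linspace(0, p.rho_I, 10_000)
            BI, DI = _rates_I_arrays(grid[i], qs, p)
            best = qs[np.argmin(np.abs(BI - DI))]
            assert abs(best - q.qI_star[i]) < 2e-4

    def test_residual_tolerance_enforced(self, bistable_params):
        q = qss_marks(bistable_params, default_x_grid(bistable_params, n=100),
                      tol=1e-8)
        from episwitch.model import _rates_A_arrays
        BA, DA = _rates_A_arrays(q.x_grid, q.qA_star, bistable_params)
        assert np.max(np.abs(BA - DA)) < 1e-8

    def test_bistable_fixture_has_x_like_pattern(self, bistable_params):
        """Activating mark rises, repressive falls, with a single crossover."""
        p = bistable_params
        q = qss_marks(p, default_x_grid(p, n=200))
        assert q.crossover_x is not None
        lo = q.x_grid < q.crossover_x
        hi = ~lo
        assert q.qA_star[lo].mean() < q.qI_star[lo].mean()
        assert q.qA_star[hi].mean() > q.qI_star[hi].mean()
        # trend over the relevant window
        w = (q.x_grid > 0.05) & (q.x_grid < 2.0)
        assert q.qA_star[w][-1] > q.qA_star[w][0]
        assert q.qI_star[w][-1] < q.qI_star[w][0]


class TestResponseCurve:
    def test_bounds_and_basal_value(self, bistable_params):
        p = bistable_params
        q = qss_marks(p, default_x_grid(p, n=100))
        R = response_curve(p, q)
        assert np.all(R >= p.rho - 1e-12)
        assert np.all(R <= p.rho * (1 + p.C1) + 1e-12)

    def test_monotone_for_fixture(self, bistable_params):
        p = bistable_params
        q = qss_marks(p, default_x_grid(p, n=200))
        R = response_curve(p, q)
        assert np.all(np.diff(R) > -1e-9)


class TestEffectiveHill:
    def test_x_independent_marks_give_monomeric_hill(self):
        # K6 = 0 pins q_A* at rho_A; K8 = 0 removes x from the q_I equation:
        # both mark curves are then x-free and the response is monomeric Hill
        p = make_params(th={"K6": 0.0, "K8": 0.0})
        q = qss_marks(p, np.geomspace(1e-3, 50, 300))
        fit = effective_hill(p, q)
        assert fit.n_eff == pytest.approx(1.0, abs=1e-3)

    def test_linear_activating_mark_gives_order_two(self):
        p = make_params()
        x = np.geomspace(1e-3, 10, 400)
        q = QSSCurves(x_grid=x, qA_star=0.05 * x, qI_star=np.full_like(x, 0.5),
                      rootsA_count=np.ones_like(x, int),
                      rootsI_count=np.ones_like(x, int))
        fit = effective_hill(p, q)
        assert fit.n_eff == pytest.approx(2.0, abs=1e-3)

    def test_bistable_fixture_is_ultrasensitive(self, bistable_params):
        p = bistable_params
        q = qss_marks(p, default_x_grid(p, n=400))
        fit = effective_hill(p, q)
        assert fit.n_eff > 1.0

    def test_degenerate_response_raises(self):
        p = make_params()
        x = np.geomspace(0.01, 10, 100)
        q = QSSCurves(x_grid=x, qA_star=np.zeros_like(x), qI_star=np.ones_like(x),
                      rootsA_count=np.ones_like(x, int),
                      rootsI_count=np.ones_like(x, int))
        with pytest.raises(ValueError, match="n_eff"):
            effective_hill(p, q)
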