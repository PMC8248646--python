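"""Action, effective potential, stationary density and classification."""

import numpy as np
import pytest
from scipy.integrate import trapezoid
from scipy.stats import poisson

from episwitch.landscape import (
    action_S,
    compute_landscape,
    find_critical_points,
    phi_mode_visibility,
    potential_U,
    sprime_at,
    stationary_pdf,
    wkb_mark_pdf,
)
from episwitch.model import (
    ModelParams,
    _rates_tf_arrays,
    default_x_grid,
    mark_root_sets,
    qss_marks,
)


class TestActionDecoupled:
    """C1 = C4 = 0, C2 = 1: S(x) = x - x*log(x) in closed form."""

    def test_closed_form(self, decoupled_params):
        p = decoupled_params
        grid = np.geomspace(1e-3, 8, 500)
        q = qss_marks(p, grid)
        S = action_S(p, q)
        expected = grid - grid * np.log(grid)
        assert np.max(np.abs(S - expected)) < 2e-3

    def test_maximum_at_unit_concentration(self, decoupled_params):
        grid = np.geomspace(1e-3, 8, 800)
        q = qss_marks(decoupled_params, grid)
        S = action_S(decoupled_params, q)
        assert grid[np.argmax(S)] == pytest.approx(1.0, rel=5e-3)
        assert np.max(S) == pytest.approx(1.0, abs=2e-3)

    def test_single_sprime_root_at_inverse_degradation(self, decoupled_params):
        L = compute_landscape(decoupled_params, x_grid=np.geomspace(1e-3, 8, 600))
        assert len(L.roots_Sprime) == 1
        assert L.roots_Sprime[0] == pytest.approx(1.0, abs=1e-3)

    def test_poisson_stationary_law(self, decoupled_params):
        """Birth-death limit: counts are Poisson with mean Omega_T/C2."""
        p = decoupled_params  # Omega_T = 50, C2 = 1
        L = compute_landscape(p, Omega_T=50, x_grid=np.geomspace(1e-3, 8, 800))
        ns = np.arange(0, 120)
        phi_n = np.interp(ns / 50.0, L.x_grid, L.phi_x, left=0, right=0)
        phi_n /= phi_n.sum()
        tv = 0.5 * np.abs(phi_n - poisson.pmf(ns, 50.0)).sum()
        assert tv < 0.02


class TestPotential:
    def test_u_converges_to_minus_s(self, bistable_params):
        p = bistable_params
        grid = default_x_grid(p, n=300)
        q = qss_marks(p, grid)
        S = action_S(p, q)
        interior = (grid > 0.05) & (grid < 2.0)
        for Omega in (100, 1000, 10000):
            U = potential_U(p, q, Omega)
            gap = np.max(np.abs((U + S))[interior])
            assert gap < 50.0 / Omega

    def test_minima_displacement_shrinks_with_system_size(self, bistable_params):
        p = bistable_params
        grid = default_x_grid(p, n=800)
        mins = {}
        for Omega in (200, 400, 800):
            L = compute_landscape(p, Omega_T=Omega, x_grid=grid)
            mins[Omega] = L.modes[-1]
        root = compute_landscape(p, Omega_T=10**7, x_grid=grid).roots_Sprime[-1]
        d200 = abs(mins[200] - root)
        d800 = abs(mins[800] - root)
        assert d800 < d200

    def test_sign_of_sprime_matches_drift(self, bistable_params):
        p = bistable_params
        grid = default_x_grid(p, n=200)
        q = qss_marks(p, grid)
        B, D = _rates_tf_arrays(grid, q.qA_star, q.qI_star, p)
        assert np.all(np.sign(np.log(B / D)) == np.sign(B - D))


class TestStationaryPdf:
    def test_normalisation(self, landscape_by_class):
        for L in landscape_by_class.values():
            assert trapezoid(L.phi_x, L.x_grid) == pytest.approx(1.0, abs=1e-6)

    def test_modes_coincide_with_minima_of_u(self, landscape_by_class):
        for L in landscape_by_class.values():
            for m in L.modes:
                i = np.argmin(np.abs(L.x_grid - m))
                lo, hi = max(i - 3, 0), min(i + 4, len(L.x_grid))
                assert L.U[lo:hi].min() <= L.U.min() + 0.5 * np.ptp(L.U)

    def test_flat_potential_raises_on_zero_density(self):
        with pytest.raises(ValueError):
            stationary_pdf(np.full(10, np.inf), 100, np.linspace(0.1, 1, 10))


class TestWKBMarkPdf:
    def test_mode_at_qss_root(self, bistable_params):
        p = bistable_params
        x = 0.5
        qA_roots, _ = mark_root_sets(p, x)
        grid, dens = wkb_mark_pdf(p, x, "A", Omega_S=100)
        assert abs(grid[np.argmax(dens)] - qA_roots[0]) < 2 * (grid[1] - grid[0]) + 1e-3

    def test_normalisation(self, bistable_params):
        grid, dens = wkb_mark_pdf(bistable_params, 0.5, "I", Omega_S=100)
        assert trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_matches_frozen_x_gillespie(self, bistable_params):
        """Conditional mark density vs an SSA run with the TF frozen."""
        from episwitch.model import StateVars
        from episwitch.ssa import SSAConfig, gillespie_run
        p = bistable_params
        x = 0.5
        OS = 100
        qA_roots, qI_roots = mark_root_sets(p, x)
        cfg = SSAConfig(t_max=4000.0, seed=42, burn_in=200.0, record_stride=0.05,
                        Omega_T=1000, Omega_S=OS)
        init = StateVars(x=x, q_A=float(qA_roots[0]), q_I=float(qI_roots[0]))
        traj = gillespie_run(p, cfg, init=init, freeze_x=True)
        keep = traj.times >= cfg.burn_in
        emp = np.bincount(traj.n_A[keep], minlength=OS + 1) / keep.sum()
        grid, dens = wkb_mark_pdf(p, x, "A", Omega_S=OS, n_grid=4000)
        wkb = np.interp(np.arange(OS + 1) / OS, grid, dens, left=0, right=0)
        wkb /= wkb.sum()
        tv = 0.5 * np.abs(emp - wkb).sum()
        assert tv < 0.05


class TestCriticalPoints:
    def test_constructed_cubic_roots_recovered(self):
        roots = np.array([0.1, 1.0, 3.0])
        x = np.geomspace(0.01, 10, 2000)
        f = (x - 0.1) * (x - 1.0) * (x - 3.0)   # derivative of a double-well
        found, tags = find_critical_points(f, x)
        assert np.allclose(found, roots, atol=1e-6)
        assert tags == ["min", "max", "min"]

    def test_too_many_roots_flagged_as_artefact(self):
        x = np.linspace(0.1, 10, 500)
        f = np.sin(5 * x)
        with pytest.raises(RuntimeError, match="artefact"):
            find_critical_points(f, x)


class TestClassification:
    def test_reference_fixtures_reclassify_to_their_own_label(self, landscape_by_class):
        for label, L in landscape_by_class.items():
            assert L.class_label == label

    def test_bistable_has_three_roots_of_both(self, landscape_by_class):
        L = landscape_by_class["BISTABLE"]
        assert len(L.roots_Sprime) == 3 and len(L.roots_Uprime) == 3

    def test_noise_induced_root_counts(self, landscape_by_class):
        L = landscape_by_class["NOISE_INDUCED"]
        assert len(L.roots_Sprime) == 1 and len(L.roots_Uprime) == 3

    def test_barriers_strictly_positive_for_bimodal_classes(self, landscape_by_class):
        for label in ("BISTABLE", "NOISE_INDUCED"):
            L = landscape_by_class[label]
            assert L.dU0 > 0 and L.dU1 > 0

    def test_label_invariant_under_grid_refinement(self, params_by_class):
        for label, p in params_by_class.items():
            L2 = compute_landscape(p, x_grid=default_x_grid(p, n=800))
            assert L2.class_label == label

    def test_sprime_roots_are_meanfield_equilibria(self, bistable_params):
        """Refined zeros of S' satisfy |B_x - D_x| < 1e-8 at QSS marks."""
        from episwitch.landscape import refine_sprime_roots
        p = bistable_params
        L = compute_landscape(p)
        roots = refine_sprime_roots(p, L.roots_Sprime)
        for r in roots:
            qA, qI = mark_root_sets(p, r)
            B, D = _rates_tf_arrays(r, qA[0], qI[0], p)
            assert abs(B - D) < 1e-8

    def test_k11_increase_drives_saddle_node(self, bistable_params):
        """Raising the H3K27me3-demethylase K_M removes bistability."""
        p = bistable_params
        assert compute_landscape(p).class_label == "BISTABLE"
        p2 = p.with_theta(K11=p.theta["K11"] * 6.0)
        L2 = compute_landscape(p2)
        assert len(L2.roots_Sprime) == 1

    def test_noise_induced_visibility_reported(self, landscape_by_class):
        assert phi_mode_visibility(landscape_by_class["NOISE_INDUCED"]) > 0.02
        assert phi_mode_visibility(landscape_by_class["HIGH_GE"]) == 0.0
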