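"""Discretization checks: steady states, ODE limits, conservation, bounds."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import gbmsim
from gbmsim.model_core import ModelParameters
from gbmsim.solver import (
    SimulationState,
    Simulator,
    SolverConfig,
    gaussian_initial_condition,
    initial_nutrient,
)
from conftest import centered_box, isotropic_cell_field


def _sim(mesh, params, config, res=4):
    D, T = isotropic_cell_field(mesh, res, params.D_n)
    return Simulator(mesh, D, T, params, config)


@pytest.fixture(scope="module")
def tiny_mesh():
    return centered_box(4.0, 2)


class TestGaussianInitialCondition:
    def test_center_vertex_amplitude(self, small_mesh):
        phi0 = gaussian_initial_condition(small_mesh, (0, 0, 0), 2.0, 0.4279)
        center = np.argmin(np.linalg.norm(small_mesh.vertices, axis=1))
        assert phi0[center] == pytest.approx(0.4279)
        assert phi0.max() == pytest.approx(0.4279)

    def test_half_width(self, small_mesh):
        sigma = 1.25
        phi0 = gaussian_initial_condition(small_mesh, (0, 0, 0), sigma, 0.4)
        r_half = sigma * np.sqrt(2 * np.log(2))
        # evaluate analytically at a vertex at that distance along x
        v = np.argmin(np.linalg.norm(small_mesh.vertices - [r_half, 0, 0], axis=1))
        d = np.linalg.norm(small_mesh.vertices[v])
        assert phi0[v] == pytest.approx(0.4 * np.exp(-d**2 / (2 * sigma**2)))

    def test_default_amplitude_slightly_above_equilibrium(self):
        assert 1.1 * 0.389 == pytest.approx(0.4279)

    def test_low_amplitude_warns(self, small_mesh, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="gbmsim"):
            gaussian_initial_condition(small_mesh, (0, 0, 0), 2.0, 0.2, phi_e=0.389)
        assert any("phi_e" in rec.message for rec in caplog.records)


class TestInitialNutrient:
    def test_zero_phase_gives_exact_physiological_level(self, small_mesh, params):
        D, _ = isotropic_cell_field(small_mesh, 4, params.D_n)
        n = initial_nutrient(np.zeros(small_mesh.n_vertices), D, params, small_mesh)
        assert np.allclose(n, params.n_s, rtol=1e-10)

    def test_uniform_closed_form_no_flux(self, small_mesh):
        # steady reaction balance: n = S_n n_s / (S_n + delta_n phi)
        p = ModelParameters(S_n=1e4, delta_n=1e3, n_s=0.07)
        D, _ = isotropic_cell_field(small_mesh, 4, p.D_n)
        n = initial_nutrient(0.5 * np.ones(small_mesh.n_vertices), D, p,
                             small_mesh, bc="no-flux")
        assert np.allclose(n, 1e4 * 0.07 / (1e4 + 1e3 * 0.5), rtol=1e-10)
        assert n.max() == pytest.approx(0.06667, abs=5e-6)

    def test_minimum_at_tumor_core(self, params):
        mesh = centered_box(20.0, 8)
        D, _ = isotropic_cell_field(mesh, 8, params.D_n)
        phi0 = gaussian_initial_condition(mesh, (0, 0, 0), 2.0, 0.4279)
        n = initial_nutrient(phi0, D, params, mesh)
        argmin = mesh.vertices[np.argmin(n)]
        assert np.linalg.norm(argmin) <= 20.0 / 8 * np.sqrt(3) + 1e-9
        assert n.min() >= 0.0 and n.max() <= params.n_s * (1 + 1e-9)


class TestTrivialFixedPoint:
    def test_zero_phase_is_stationary(self, small_mesh, params):
        sim = _sim(small_mesh, params, SolverConfig(dt=0.1, t_end=0.3))
        traj = sim.run(np.zeros(small_mesh.n_vertices))
        assert np.allclose(traj[-1].phi, 0.0, atol=1e-12)
        assert np.allclose(traj[-1].n, params.n_s, rtol=1e-10)


class TestODELimit:
    """Uniform fields on the no-flux harness reduce to a 2-ODE system."""

    @staticmethod
    def _rhs(p):
        def rhs(t, y):
            phi, n = y
            return [p.nu_c * phi * (n / p.n_s - p.delta_c) * (1 - phi),
                    p.S_n * (p.n_s - n) - p.delta_n * phi * n]
        return rhs

    def test_single_step_third_order_local_error(self, tiny_mesh):
        p = ModelParameters(nu_c=1.0, S_n=1e4, delta_n=8640.0, k_n=0.0)
        phi0, n0 = 0.2, 0.05
        errs = []
        for dt in (4e-6, 2e-6):
            sim = _sim(tiny_mesh, p, SolverConfig(bc="no-flux", dt=dt, t_end=dt), res=2)
            st = SimulationState(phi0 * np.ones(tiny_mesh.n_vertices),
                                 np.zeros(tiny_mesh.n_vertices),
                                 n0 * np.ones(tiny_mesh.n_vertices), 0.0)
            st.sigma = sim.project_sigma(st.phi)
            out = sim.step(st)
            ref = solve_ivp(self._rhs(p), (0, dt), [phi0, n0], method="Radau",
                            rtol=1e-13, atol=1e-16)
            errs.append(abs(out.phi[0] - ref.y[0, -1]) + abs(out.n[0] - ref.y[1, -1]))
        order = np.log2(errs[0] / errs[1])
        assert order >= 2.5

    def test_global_second_order_under_dt_halving(self, tiny_mesh):
        p = ModelParameters(nu_c=1.0, S_n=1e4, delta_n=8640.0, k_n=0.0)
        phi0 = 0.2
        n0 = p.S_n * p.n_s / (p.S_n + p.delta_n * phi0)
        errs = []
        for dt in (0.05, 0.025, 0.0125):
            sim = _sim(tiny_mesh, p, SolverConfig(bc="no-flux", dt=dt, t_end=0.5), res=2)
            traj = sim.run(phi0 * np.ones(tiny_mesh.n_vertices))
            ref = solve_ivp(self._rhs(p), (0, 0.5), [phi0, n0], method="Radau",
                            rtol=1e-12, atol=1e-14)
            errs.append(abs(traj[-1].phi[0] - ref.y[0, -1])
                        + abs(traj[-1].n[0] - ref.y[1, -1]))
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(len(errs) - 1)]
        assert min(orders) >= 1.8


class TestConservation:
    def test_mass_conserved_without_sources(self, params):
        # nu = 0, k_n = 0, no-flux: the phase equation is in divergence form
        mesh = centered_box(20.0, 8)
        p = params.replace(nu_c=0.0, k_n=0.0)
        sim = _sim(mesh, p, SolverConfig(bc="no-flux", dt=0.05, t_end=0.5,
                                         output_every=100), res=8)
        phi0 = gaussian_initial_condition(mesh, (0, 0, 0), 2.0, 0.4279)
        traj = sim.run(phi0)
        weights = sim.space.Mc @ np.ones(mesh.n_vertices)
        m0 = weights @ traj[0].phi
        m1 = weights @ traj[-1].phi
        assert abs(m1 - m0) / m0 <= 1e-6

    def test_mass_grows_with_proliferation(self, params):
        mesh = centered_box(20.0, 6)
        p = params.replace(k_n=0.0, delta_n=0.0)  # n stays at n_s > delta_c n_s
        sim = _sim(mesh, p, SolverConfig(bc="no-flux", dt=0.05, t_end=0.25,
                                         output_every=100), res=6)
        phi0 = gaussian_initial_condition(mesh, (0, 0, 0), 2.0, 0.4279)
        traj = sim.run(phi0)
        weights = sim.space.Mc @ np.ones(mesh.n_vertices)
        assert weights @ traj[-1].phi > weights @ traj[0].phi
        assert traj[-1].phi.max() < 1.0


class TestNutrientBounds:
    def test_bounds_along_production_run(self, params):
        mesh = centered_box(20.0, 8)
        sim = _sim(mesh, params, SolverConfig(dt=0.1, t_end=0.6, output_every=1),
                   res=8)
        phi0 = gaussian_initial_condition(mesh, (0, 0, 0), 2.0, 0.4279)
        for st in sim.run(phi0):
            assert st.n.min() >= 0.0
            assert st.n.max() <= params.n_s * (1 + 1e-6)

    def test_nutrient_pinned_without_uptake(self, params):
        # delta_n = 0 with large S_n: n/n_s stays at 1 everywhere
        mesh = centered_box(20.0, 6)
        p = params.replace(delta_n=0.0)
        sim = _sim(mesh, p, SolverConfig(dt=0.1, t_end=0.3), res=6)
        phi0 = gaussian_initial_condition(mesh, (0, 0, 0), 2.0, 0.4279)
        traj = sim.run(phi0)
        assert np.all(traj[-1].n / p.n_s >= 1 - 1e-3)


class TestRunDriver:
    def test_t_end_zero_returns_initial(self, small_mesh, params):
        sim = _sim(small_mesh, params, SolverConfig(t_end=0.0))
        phi0 = gaussian_initial_condition(small_mesh, (0, 0, 0), 2.0, 0.4279)
        traj = sim.run(phi0)
        assert len(traj) == 1
        assert np.array_equal(traj[0].phi, phi0)

    def test_output_every_controls_snapshots(self, small_mesh, params):
        phi0 = gaussian_initial_condition(small_mesh, (0, 0, 0), 2.0, 0.4279)
        n1 = len(_sim(small_mesh, params,
                      SolverConfig(dt=0.1, t_end=0.8, output_every=2)).run(phi0))
        n2 = len(_sim(small_mesh, params,
                      SolverConfig(dt=0.1, t_end=0.8, output_every=4)).run(phi0))
        assert abs((n1 - 2) - 2 * (n2 - 2)) <= 1

    def test_deterministic(self, small_mesh, params):
        phi0 = gaussian_initial_condition(small_mesh, (0, 0, 0), 2.0, 0.4279)
        cfg = SolverConfig(dt=0.1, t_end=0.3)
        a = _sim(small_mesh, params, cfg).run(phi0)
        b = _sim(small_mesh, params, cfg).run(phi0)
        assert np.array_equal(a[-1].phi, b[-1].phi)
        assert np.array_equal(a[-1].n, b[-1].n)


class TestSpatialSymmetry:
    def test_axis_permutation_symmetry_isotropic(self, params):
        # Kuhn tessellation + isotropic tensors: solution invariant under
        # coordinate permutation; check phi at mirrored vertex pairs
        mesh = centered_box(20.0, 6)
        sim = _sim(mesh, params, SolverConfig(dt=0.1, t_end=0.5), res=6)
        phi0 = gaussian_initial_condition(mesh, (0, 0, 0), 2.0, 0.4279)
        phi = sim.run(phi0)[-1].phi
        order = np.lexsort(mesh.vertices.T[::-1])
        perm_order = np.lexsort(mesh.vertices[:, [1, 0, 2]].T[::-1])
        assert np.allclose(phi[order], phi[perm_order], atol=1e-8)


class TestAnisotropyResponse:
    def test_axis_aligned_tensor_elongates_along_x(self, params):
        from gbmsim.tensor_fields import (preferential_directions,
                                          sample_to_mesh,
                                          synthetic_axis_aligned)
        from gbmsim.metrics import semi_axes
        mesh = centered_box(30.0, 10)
        field = synthetic_axis_aligned((10,) * 3, params.D_n, axis="x",
                                       spacing=(3.0,) * 3, origin=(-13.5,) * 3)
        D = sample_to_mesh(field, mesh)
        T = preferential_directions(D)
        sim = Simulator(mesh, D, T, params.replace(k_n=200.0, nu_c=1.0),
                        SolverConfig(dt=0.1, t_end=2.0))
        phi0 = gaussian_initial_condition(mesh, (0, 0, 0), 2.0, 0.4279)
        phi = sim.run(phi0)[-1].phi
        dx, dy, dz = semi_axes(mesh, phi, 0.05)
        assert dx > dy and dx > dz


class TestSolverConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"dt": 0.0}, {"newton_tol": -1.0}, {"eps_t": 0.0}, {"eps_t": 1.0},
        {"bc": "periodic"},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)
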