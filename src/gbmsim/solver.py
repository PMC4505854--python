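"""Discretization and time stepping of the coupled tumor/nutrient system.

The tumor phase obeys a fourth-order Cahn–Hilliard-type equation; it is
solved in the standard mixed second-order form with the excess pressure
Sigma as an auxiliary unknown:

    d(phi)/dt - div( phi K(phi) grad Sigma ) - nu phi (n/n_s - delta)(1 - phi)
              + div( k_n phi T grad n ) = 0
    Sigma = f(phi) - eps^2 Laplacian(phi)

coupled to the nutrient reaction–diffusion equation

    dn/dt = div( D grad n ) + S_n (n_s - n) - delta_n phi n.

Space: linear (P1) tetrahedral finite elements, assembled here with
numpy/scipy.sparse.  Time: each step solves the nutrient equation first —
implicitly with TR-BDF2, an L-stable second-order scheme chosen because the
reaction terms are very stiff (S_n dt >> 1) and trapezoidal stepping alone
would oscillate the nutrient past its physiological bound; the uptake
coefficient is extrapolated to the new time level so the phase nonlinearity
stays out of this linear solve, with a predictor-corrector pass on the
first step.  Then the mixed (phi, Sigma) phase system is advanced by
Crank–Nicolson and solved with Newton iteration and an analytic Jacobian.

Boundary conditions (production): phi = 0 essential, the no-flux condition
on grad(phi) is the natural condition of the Sigma equation, and n = n_s
essential.  A pure-natural ("no-flux") harness variant exists for
conservation and ODE-limit tests.

Mass matrices are lumped (vertex quadrature) throughout.  For the nutrient
equation this preserves discrete monotonicity; for the phase equation it
suppresses the node-to-node oscillations that consistent-mass P1 transport
exhibits at the advancing chemotactic front — with consistent mass the
phase field accumulates undershoot of order 1e-2 at coarse resolution,
with lumping it stays non-negative to solver tolerance.  Lumping keeps
second-order spatial accuracy for P1 elements and conserves the same
discrete mass functional (the row sums of the consistent matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Mesh
from .model_core import (
    ModelParameters,
    bulk_pressure_derivative,
    bulk_pressure_derivative_prime,
)
from .tensor_fields import TensorField, sample_to_mesh

__all__ = [
    "SimulationState",
    "SolverConfig",
    "Simulator",
    "NewtonError",
    "gaussian_initial_condition",
    "initial_nutrient",
    "step",
    "run",
]

logger = logging.getLogger("gbmsim")


class NewtonError(RuntimeError):
    """Newton iteration failed to converge."""


@dataclass
class SimulationState:
    """Fields (phi, Sigma, n) on the mesh vertices at one time point.

    ``phi_prev``/``dt_prev`` carry the previous phase field for the
    second-order extrapolation of the nutrient uptake coefficient; they are
    None at the initial time.
    """

    phi: np.ndarray
    sigma: np.ndarray
    n: np.ndarray
    t: float
    phi_prev: np.ndarray | None = None
    dt_prev: float | None = None

    PHI_TOL = 1.0e-3
    N_TOL = 1.0e-6

    def check_invariants(self, params: ModelParameters, *, strict: bool = False) -> list[str]:
        """Check the physical-range invariants; returns violation messages."""
        problems = []
        if self.phi.min() < -self.PHI_TOL or self.phi.max() > 1.0 + self.PHI_TOL:
            problems.append(f"phi out of [-1e-3, 1+1e-3]: range "
                            f"[{self.phi.min():.3e}, {self.phi.max():.3e}] at t={self.t:g}")
        if self.n.min() < 0.0 or self.n.max() > params.n_s * (1.0 + self.N_TOL):
            problems.append(f"n out of [0, n_s(1+1e-6)]: range "
                            f"[{self.n.min():.6e}, {self.n.max():.6e}] at t={self.t:g}")
        for msg in problems:
            logger.warning("state invariant violated: %s", msg)
        if strict and problems:
            raise ValueError("; ".join(problems))
        return problems

    def copy(self) -> "SimulationState":
        return SimulationState(self.phi.copy(), self.sigma.copy(), self.n.copy(),
                               self.t,
                               None if self.phi_prev is None else self.phi_prev.copy(),
                               self.dt_prev)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of a run.

    dt : time step (day); halved automatically (up to 3 times) on Newton
        failure.
    t_end : final time (day).
    newton_tol : relative residual tolerance of the (phi, Sigma) Newton solve.
    newton_max_iter : Newton iteration cap per attempt.
    clip_eta : width of the saturation guard — flux and pressure
        coefficients are evaluated on phi clipped to [0, 1 - clip_eta].
    output_every : snapshot interval in steps.
    eps_t : tumor threshold for the shape metrics.
    seed : integer seed for any stochastic phantom input.
    staggered : if False, every step runs an extra nutrient/phase corrector
        pass (Picard sweep) instead of only the first.
    bc : "dirichlet" for the production conditions (phi = 0, n = n_s on the
        boundary) or "no-flux" for the pure-natural test harness.
    """

    dt: float = 0.05
    t_end: float = 6.0
    newton_tol: float = 1.0e-8
    newton_max_iter: int = 20
    clip_eta: float = 1.0e-6
    output_every: int = 10
    eps_t: float = 0.05
    seed: int = 0
    staggered: bool = True
    bc: str = "dirichlet"

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError(f"dt must be positive, got {self.dt!r}")
        if self.t_end < 0.0:
            raise ValueError(f"t_end must be non-negative, got {self.t_end!r}")
        if self.newton_tol <= 0.0:
            raise ValueError(f"newton_tol must be positive, got {self.newton_tol!r}")
        if not 0.0 < self.eps_t < 1.0:
            raise ValueError(f"eps_t must lie in (0, 1), got {self.eps_t!r}")
        if self.bc not in ("dirichlet", "no-flux"):
            raise ValueError(f"bc must be 'dirichlet' or 'no-flux', got {self.bc!r}")

    def replace(self, **changes) -> "SolverConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# P1 assembly helpers
# ---------------------------------------------------------------------------

class _P1Space:
    """Geometry caches for P1 assembly on a tetrahedral mesh."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        cells = mesh.cells
        verts = mesh.vertices[cells]                     # (M, 4, 3)
        edges = verts[:, 1:] - verts[:, :1]              # (M, 3, 3)
        det = np.linalg.det(edges)
        if np.any(det <= 0.0):
            raise ValueError("mesh contains non-positively-oriented cells")
        self.vols = det / 6.0
        inv = np.linalg.inv(edges)                       # rows of inv give grad(lambda_i)
        grads = np.empty((len(cells), 4, 3))
        grads[:, 1:, :] = np.transpose(inv, (0, 2, 1))
        grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
        self.grads = grads
        self.rows = np.repeat(cells, 4, axis=1).reshape(-1)
        self.cols = np.tile(cells, (1, 4)).reshape(-1)
        # Plain stiffness local matrices: vol * g_i . g_j
        self.S_geom = np.einsum("m,mik,mjk->mij", self.vols, grads, grads)
        n = mesh.n_vertices
        # Consistent mass: vol * (1 + delta_ij) / 20
        mc_loc = (np.ones((4, 4)) + np.eye(4)) / 20.0
        self.Mc = self.assemble(self.vols[:, None, None] * mc_loc)
        self.m_lumped = np.zeros(n)
        np.add.at(self.m_lumped, cells.reshape(-1),
                  np.repeat(self.vols / 4.0, 4))
        self.ML = sp.diags(self.m_lumped).tocsr()
        self.K = self.assemble(self.S_geom)
        self.n_dof = n

    def assemble(self, local_vals: np.ndarray) -> sp.csr_matrix:
        """Sum (M, 4, 4) local matrices into a global CSR matrix."""
        n = self.mesh.n_vertices
        return sp.coo_matrix((local_vals.reshape(-1), (self.rows, self.cols)),
                             shape=(n, n)).tocsr()

    def tensor_stiffness_local(self, tensors: np.ndarray) -> np.ndarray:
        """(M, 4, 4) local stiffness values for a per-cell 3x3 tensor."""
        return np.einsum("m,mik,mkl,mjl->mij", self.vols, self.grads,
                         tensors, self.grads)


def _as_cell_field(field: TensorField, mesh: Mesh) -> TensorField:
    if field.on_grid:
        return sample_to_mesh(field, mesh)
    if field.location_shape != (mesh.n_cells,):
        raise ValueError("tensor field is defined on "
                         f"{field.location_shape} locations but the mesh has "
                         f"{mesh.n_cells} cells")
    return field


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def gaussian_initial_condition(mesh: Mesh, center, sigma_mm: float,
                               amplitude: float, phi_e: float | None = None) -> np.ndarray:
    """Gaussian initial tumor profile on the mesh vertices.

    phi0(x) = amplitude * exp(-|x - center|^2 / (2 sigma_mm^2)) — the smooth
    initial distribution of a diffuse glioblastoma seed, with its maximum
    (slightly above the equilibrium fraction phi_e) at the tumor center.
    """
    if sigma_mm <= 0.0:
        raise ValueError(f"sigma_mm must be positive, got {sigma_mm!r}")
    if not 0.0 < amplitude < 1.0:
        raise ValueError(f"amplitude must lie in (0, 1), got {amplitude!r}")
    if phi_e is not None and amplitude <= phi_e:
        logger.warning("gaussian_initial_condition: amplitude %g <= phi_e %g "
                       "(the seed should slightly exceed the equilibrium "
                       "fraction); honoring it anyway", amplitude, phi_e)
    center = np.asarray(center, dtype=float).reshape(3)
    r2 = np.sum((mesh.vertices - center[None, :]) ** 2, axis=1)
    return amplitude * np.exp(-r2 / (2.0 * sigma_mm**2))


class Simulator:
    """Cached discretization of one (mesh, D, T, parameters) problem."""

    def __init__(self, mesh: Mesh, D: TensorField, T: TensorField,
                 params: ModelParameters, config: SolverConfig):
        self.mesh = mesh
        self.params = params
        self.config = config
        self.space = _P1Space(mesh)
        self.D = _as_cell_field(D, mesh)
        self.T = _as_cell_field(T, mesh)
        self.K_D = self.space.assemble(
            self.space.tensor_stiffness_local(self.D.as_matrices()))
        self.S_T = self.space.tensor_stiffness_local(self.T.as_matrices())
        self.boundary = (mesh.boundary_vertices() if config.bc == "dirichlet"
                         else np.empty(0, dtype=np.int64))
        self._jac_lu = None
        self._jac_fp = None
        self._jac_dt = None
        self.newton_iterations: list[int] = []
        self.newton_factorizations = 0
        self.dt_halvings = 0
        self.clip_events = 0

    # -- small helpers ------------------------------------------------------

    def _clip(self, phi: np.ndarray) -> np.ndarray:
        """Saturation guard; clip events are counted for run diagnostics."""
        n_out = int(np.count_nonzero((phi < 0.0)
                                     | (phi > 1.0 - self.config.clip_eta)))
        if n_out:
            self.clip_events += n_out
            logger.debug("saturation guard clipped %d nodal value(s)", n_out)
        return np.clip(phi, 0.0, 1.0 - self.config.clip_eta)

    def _clip_active(self, phi: np.ndarray) -> np.ndarray:
        return ((phi >= 0.0) & (phi <= 1.0 - self.config.clip_eta)).astype(float)

    def _cell_mean(self, nodal: np.ndarray) -> np.ndarray:
        return nodal[self.mesh.cells].mean(axis=1)

    def _mobility_coeff(self, phi: np.ndarray) -> np.ndarray:
        """Cell-wise flux coefficient w = phi (1-phi)^2 / M at the cell mean."""
        pm = self._cell_mean(self._clip(phi))
        return pm * (1.0 - pm) ** 2 / self.params.M

    def _mobility_coeff_prime(self, phi: np.ndarray) -> np.ndarray:
        pm = self._cell_mean(self._clip(phi))
        return (1.0 - pm) * (1.0 - 3.0 * pm) / self.params.M

    def _reaction(self, phi_c: np.ndarray, n: np.ndarray) -> np.ndarray:
        p = self.params
        return p.nu_c * phi_c * (n / p.n_s - p.delta_c) * (1.0 - phi_c)

    def _reaction_dphi(self, phi_c: np.ndarray, n: np.ndarray) -> np.ndarray:
        p = self.params
        return p.nu_c * (n / p.n_s - p.delta_c) * (1.0 - 2.0 * phi_c)

    # -- nutrient solves ----------------------------------------------------

    def _nutrient_operator(self, phi_coeff: np.ndarray) -> sp.csr_matrix:
        p = self.params
        ml = self.space.m_lumped
        return (self.K_D + sp.diags(p.S_n * ml + p.delta_n * ml * phi_coeff)).tocsr()

    def _solve_spd(self, A: sp.csr_matrix, b: np.ndarray,
                   dirichlet_value: float | None, x0: np.ndarray | None = None,
                   what: str = "nutrient") -> np.ndarray:
        """Solve an SPD nutrient system by preconditioned CG.

        Dirichlet rows are eliminated symmetrically (rows and columns zeroed,
        knowns moved to the right-hand side) so conjugate gradients applies;
        the reaction terms keep the operator strongly diagonally dominant, so
        a Jacobi preconditioner converges in a handful of iterations.
        """
        n = A.shape[0]
        if dirichlet_value is not None and len(self.boundary):
            g = np.zeros(n)
            g[self.boundary] = dirichlet_value
            keep = np.ones(n)
            keep[self.boundary] = 0.0
            P = sp.diags(keep)
            b = keep * (b - A @ g) + g
            A = (P @ A @ P + sp.diags(1.0 - keep)).tocsr()
        diag = A.diagonal()
        precond = spla.LinearOperator((n, n), matvec=lambda x: x / diag)
        scale = max(float(np.linalg.norm(b)), 1e-300)
        x, info = spla.cg(A, b, x0=x0, M=precond, rtol=1e-13, atol=1e-13 * scale,
                          maxiter=2000)
        if info != 0:
            x = spla.spsolve(A.tocsc(), b)
        res = float(np.linalg.norm(A @ x - b))
        if not np.all(np.isfinite(x)) or res > 1e-8 * scale:
            raise RuntimeError(f"{what} solve failed (residual {res:.3e})")
        return x

    def steady_nutrient(self, phi0: np.ndarray) -> np.ndarray:
        """Steady nutrient balance for the initial condition.

        Solves 0 = div(D grad n) + S_n (n_s - n) - delta_n phi0 n with
        n = n_s on the boundary (production) or pure natural conditions
        (harness).  For phi0 = 0 the exact solution n = n_s is recovered.
        """
        p = self.params
        A = self._nutrient_operator(self._clip(phi0))
        b = p.S_n * p.n_s * self.space.m_lumped
        bc = p.n_s if self.config.bc == "dirichlet" else None
        return self._solve_spd(A, b, bc, x0=np.full(self.space.n_dof, p.n_s),
                               what="steady nutrient")

    #: TR-BDF2 split point (the standard 2 - sqrt(2) choice).
    _TRBDF2_GAMMA = 2.0 - np.sqrt(2.0)

    def nutrient_step(self, n0: np.ndarray, phi_old: np.ndarray,
                      phi_mid_coeff: np.ndarray, phi_new_coeff: np.ndarray,
                      dt: float) -> np.ndarray:
        """One TR-BDF2 step of the nutrient equation.

        The uptake coefficients at the intermediate (t + gamma dt) and new
        time levels are supplied by the caller (extrapolated, or corrected
        from a computed phase field); the phase system never enters these
        two linear solves.
        """
        p = self.params
        ml = self.space.m_lumped
        ML = sp.diags(ml)
        gamma = self._TRBDF2_GAMMA
        source = p.S_n * p.n_s * ml
        bc = p.n_s if self.config.bc == "dirichlet" else None

        A_old = self._nutrient_operator(self._clip(phi_old))
        A_mid = self._nutrient_operator(np.clip(phi_mid_coeff, 0.0, 1.0))
        A_new = self._nutrient_operator(np.clip(phi_new_coeff, 0.0, 1.0))

        # Trapezoidal stage over [t, t + gamma dt].
        lhs = (ML / (gamma * dt) + 0.5 * A_mid).tocsr()
        rhs = (ML / (gamma * dt)) @ n0 - 0.5 * (A_old @ n0) + source
        n_mid = self._solve_spd(lhs, rhs, bc, x0=n0)

        # BDF2 stage at t + dt.
        c1 = 1.0 / (gamma * (2.0 - gamma))
        c2 = (1.0 - gamma) ** 2 / (gamma * (2.0 - gamma))
        beta = (1.0 - gamma) / (2.0 - gamma)
        lhs = (ML + beta * dt * A_new).tocsr()
        rhs = ml * (c1 * n_mid - c2 * n0) + beta * dt * source
        n1 = self._solve_spd(lhs, rhs, bc, x0=n_mid)
        if not np.all(np.isfinite(n1)):
            raise RuntimeError("nutrient TR-BDF2 solve produced non-finite values")
        return n1

    # -- phase system -------------------------------------------------------

    def project_sigma(self, phi: np.ndarray) -> np.ndarray:
        """Lumped L2 projection of Sigma = f(phi) - eps^2 Lap(phi)."""
        phi_c = self._clip(phi)
        f = bulk_pressure_derivative(phi_c, self.params)
        return f + self.params.eps**2 * (self.space.K @ phi) / self.space.m_lumped

    def _flux_operator(self, phi: np.ndarray) -> sp.csr_matrix:
        return self.space.assemble(
            self._mobility_coeff(phi)[:, None, None] * self.space.S_geom)

    def _chemo_operator(self, phi: np.ndarray) -> sp.csr_matrix:
        coeff = self.params.k_n * self._cell_mean(self._clip(phi))
        return self.space.assemble(coeff[:, None, None] * self.S_T)

    def _explicit_rhs(self, phi: np.ndarray, sigma: np.ndarray,
                      n: np.ndarray) -> np.ndarray:
        """F(phi, Sigma, n): the spatial terms of the phase equation."""
        phi_c = self._clip(phi)
        return (self._flux_operator(phi) @ sigma
                - self.space.m_lumped * self._reaction(phi_c, n)
                - self._chemo_operator(phi) @ n)

    def newton_solve(self, phi0: np.ndarray, sigma0: np.ndarray,
                     n0: np.ndarray, n1: np.ndarray,
                     dt: float) -> tuple[np.ndarray, np.ndarray, int]:
        """Crank–Nicolson step of the mixed (phi, Sigma) system by Newton.

        The Jacobian is analytic (including the derivatives of the
        degenerate mobility, the bulk pressure law and the saturation
        guard).  Because the lumped Sigma-equation mass block is diagonal,
        the Sigma increment is eliminated exactly and only the N x N Schur
        complement in phi is factorized.  The factorization is kept across
        iterations and across time steps and refreshed lazily — only when
        the residual stops contracting fast enough (or the step size
        changed).  Accuracy is unaffected: the stopping test is on the true
        residual of the full system.
        """
        cfg = self.config
        space = self.space
        eps2 = self.params.eps**2
        N = space.n_dof
        F_old = self._explicit_rhs(phi0, sigma0, n0)
        phi, sigma = phi0.copy(), sigma0.copy()
        if len(self.boundary):
            phi[self.boundary] = 0.0

        if self._jac_dt is not None and self._jac_dt != dt:
            self._jac_lu = None
        scale = None
        res_prev = None
        fresh = False
        for it in range(cfg.newton_max_iter + 1):
            phi_c = self._clip(phi)
            A_w = self._flux_operator(phi)
            A_c = self._chemo_operator(phi)
            f_val = bulk_pressure_derivative(phi_c, self.params)
            ml = space.m_lumped
            R_phi = (ml * (phi - phi0) / dt
                     + 0.5 * (A_w @ sigma
                              - ml * self._reaction(phi_c, n1)
                              - A_c @ n1)
                     + 0.5 * F_old)
            R_sig = ml * (sigma - f_val) - eps2 * space.K @ phi
            if len(self.boundary):
                R_phi[self.boundary] = phi[self.boundary]
            res = float(np.sqrt(np.dot(R_phi, R_phi) + np.dot(R_sig, R_sig)))
            if scale is None:
                scale = max(res, 1e-300)
            if res <= cfg.newton_tol * scale or res < 1e-14:
                self.newton_iterations.append(it)
                return phi, sigma, it
            if it == cfg.newton_max_iter:
                break

            stalled = (res_prev is not None and res > 0.3 * res_prev
                       and not fresh)
            res_prev = res
            if self._jac_lu is None or stalled:
                dclip = self._clip_active(phi)
                cells = self.mesh.cells
                # d(A_w Sigma)/d(phi_k): cell-local rank-one updates.
                Sg_sig = np.einsum("mij,mj->mi", space.S_geom, sigma[cells])
                c_w = (self._mobility_coeff_prime(phi)[:, None]
                       * dclip[cells] / 4.0)
                dflux = Sg_sig[:, :, None] * c_w[:, None, :]
                St_n = np.einsum("mij,mj->mi", self.S_T, n1[cells])
                c_c = self.params.k_n * dclip[cells] / 4.0
                dchemo = St_n[:, :, None] * c_c[:, None, :]
                J_pp = (space.ML / dt
                        + 0.5 * space.assemble(dflux - dchemo)
                        - 0.5 * sp.diags(
                            ml * self._reaction_dphi(phi_c, n1) * dclip))
                fp = bulk_pressure_derivative_prime(phi_c, self.params) * dclip
                # Schur complement in phi after exact elimination of
                # d(Sigma) = (R_sig - J_sp d(phi)) / ml:
                schur = (J_pp + 0.5 * A_w @ sp.diags(fp)
                         + 0.5 * eps2 * A_w @ sp.diags(1.0 / ml) @ space.K)
                if len(self.boundary):
                    keep = np.ones(N)
                    keep[self.boundary] = 0.0
                    schur = sp.diags(keep) @ schur + sp.coo_matrix(
                        (np.ones(len(self.boundary)),
                         (self.boundary, self.boundary)), shape=(N, N))
                schur = schur.tocsc()
                # Incomplete LU as a (near-exact) preconditioner: for this
                # operator an exact factorization suffers severe fill while
                # ILU + GMRES converges in a handful of iterations.
                ilu = spla.spilu(schur, drop_tol=1e-5, fill_factor=10)
                self._jac_lu = (schur, spla.LinearOperator(schur.shape, ilu.solve))
                self._jac_fp = fp
                self._jac_dt = dt
                self.newton_factorizations += 1
                fresh = True
            else:
                fresh = False

            rhs = R_phi - 0.5 * A_w @ (R_sig / ml)
            if len(self.boundary):
                rhs[self.boundary] = R_phi[self.boundary]
            jac_mat, jac_pre = self._jac_lu
            rhs_norm = max(float(np.linalg.norm(rhs)), 1e-300)
            dphi, info = spla.gmres(jac_mat, rhs, M=jac_pre, rtol=1e-10,
                                    atol=1e-12 * rhs_norm, restart=50,
                                    maxiter=400)
            if info != 0:
                raise NewtonError(f"inner linear solve failed (GMRES info "
                                  f"{info}) at Newton iteration {it}")
            fp = self._jac_fp
            dsigma = (R_sig + ml * fp * dphi + eps2 * space.K @ dphi) / ml
            phi -= dphi
            sigma -= dsigma

        raise NewtonError(f"Newton did not converge in {cfg.newton_max_iter} "
                          f"iterations (last residual {res:.3e}, "
                          f"relative {res / scale:.3e})")

    # -- time stepping ------------------------------------------------------

    def initial_state(self, phi0: np.ndarray) -> SimulationState:
        phi0 = np.asarray(phi0, dtype=float)
        n0 = self.steady_nutrient(phi0)
        sigma0 = self.project_sigma(phi0)
        return SimulationState(phi0.copy(), sigma0, n0, 0.0)

    def step(self, state: SimulationState, dt: float | None = None,
             _depth: int = 0) -> SimulationState:
        """Advance one time step, halving dt (up to 3 times) on Newton failure."""
        cfg = self.config
        dt = cfg.dt if dt is None else dt

        gamma = self._TRBDF2_GAMMA
        first_step = state.phi_prev is None
        if first_step:
            phi_mid = phi_new = state.phi
        else:
            slope = (state.phi - state.phi_prev) / state.dt_prev
            phi_mid = state.phi + gamma * dt * slope
            phi_new = state.phi + dt * slope

        try:
            n1 = self.nutrient_step(state.n, state.phi, phi_mid, phi_new, dt)
            phi1, sigma1, _ = self.newton_solve(state.phi, state.sigma,
                                                state.n, n1, dt)
            if first_step or not cfg.staggered:
                # Corrector pass: redo the nutrient solve with the computed
                # phase field, then the phase solve with the corrected
                # nutrient (restores second-order coupling on step one).
                phi_mid = state.phi + gamma * (phi1 - state.phi)
                n1 = self.nutrient_step(state.n, state.phi, phi_mid, phi1, dt)
                phi1, sigma1, _ = self.newton_solve(state.phi, state.sigma,
                                                    state.n, n1, dt)
        except NewtonError:
            self._jac_lu = None
            if _depth >= 3:
                raise
            self.dt_halvings += 1
            logger.warning("Newton failure at t=%g; halving dt to %g",
                           state.t, dt / 2.0)
            half = self.step(state, dt / 2.0, _depth + 1)
            return self.step(half, dt / 2.0, _depth + 1)

        if phi1.min() < -1e-2 or phi1.max() > 1.0 + 1e-2:
            raise RuntimeError(
                f"phase field escaped [-1e-2, 1+1e-2] (range "
                f"[{phi1.min():.3e}, {phi1.max():.3e}]) at t={state.t + dt:g}; "
                "reduce dt")
        new = SimulationState(phi1, sigma1, n1, state.t + dt,
                              phi_prev=state.phi, dt_prev=dt)
        new.check_invariants(self.params)
        return new

    def run(self, phi0: np.ndarray) -> list[SimulationState]:
        """Integrate to t_end; snapshots every ``output_every`` steps + final."""
        cfg = self.config
        state = self.initial_state(phi0)
        trajectory = [state.copy()]
        if cfg.t_end <= 0.0:
            return trajectory
        n_steps = int(np.ceil(cfg.t_end / cfg.dt - 1e-12))
        for k in range(n_steps):
            dt = min(cfg.dt, cfg.t_end - state.t)
            state = self.step(state, dt)
            if (k + 1) % cfg.output_every == 0 and k != n_steps - 1:
                trajectory.append(state.copy())
        trajectory.append(state.copy())
        return trajectory


# ---------------------------------------------------------------------------
# Module-level operation wrappers
# ---------------------------------------------------------------------------

def initial_nutrient(phi0: np.ndarray, D: TensorField, params: ModelParameters,
                     mesh: Mesh, bc: str = "dirichlet") -> np.ndarray:
    """Steady-state nutrient field consistent with the initial tumor profile."""
    sim = Simulator(mesh, D, _identity_T(mesh), params,
                    SolverConfig(bc=bc, t_end=0.0))
    return sim.steady_nutrient(np.asarray(phi0, dtype=float))


def step(state: SimulationState, config: SolverConfig, params: ModelParameters,
         D: TensorField, T: TensorField, mesh: Mesh) -> SimulationState:
    """Advance a state by one time step (convenience wrapper; for long runs
    construct a :class:`Simulator` once and reuse it)."""
    return Simulator(mesh, D, T, params, config).step(state)


def run(mesh: Mesh, D: TensorField, T: TensorField, params: ModelParameters,
        config: SolverConfig, phi0: np.ndarray) -> list[SimulationState]:
    """Integrate the coupled system from phi0 to t_end; returns snapshots."""
    return Simulator(mesh, D, T, params, config).run(np.asarray(phi0, dtype=float))


def _identity_T(mesh: Mesh) -> TensorField:
    comps = np.zeros((mesh.n_cells, 6))
    comps[:, :3] = 1.0
    return TensorField(comps=comps, units="dimensionless")
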