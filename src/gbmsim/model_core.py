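"""Constitutive laws of the binary-mixture glioblastoma model.

The tumor and its environment are treated as a saturated two-phase mixture:
a cellular phase with volume fraction ``phi`` and a liquid/host phase with
fraction ``1 - phi``.  This module collects the pointwise constitutive
relations of that model — the bulk interaction pressure ``f(phi)``, the
degenerate Darcy motility ``K(phi)``, the nutrient-limited net proliferation
rate, and the fiber-aligned (Keller–Segel type) chemotactic flux — together
with the two parameter derivations used to close the parameter set (the
oxygen uptake rate from diffusivity and penetration length, and the
diffuse-interface coefficient from the interstitial fluid pressure scale and
the cell size).

Everything here is a pure function of scalars/arrays; no mesh or
discretization enters.  Units throughout: mm, day, mM, Pa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "bulk_pressure_derivative",
    "motility",
    "net_proliferation",
    "chemotactic_flux",
    "derive_uptake_rate",
    "derive_interface_coefficient",
    "clip_phase",
    "PHI_CLIP_MAX",
]

logger = logging.getLogger("gbmsim")

#: Saturation guard: f(phi) and K(phi) are evaluated on phi clipped to
#: [0, 1 - PHI_CLIP_EPS] so numerical overshoot never produces infinities.
PHI_CLIP_EPS = 1.0e-6
PHI_CLIP_MAX = 1.0 - PHI_CLIP_EPS


@dataclass(frozen=True)
class ModelParameters:
    """Biological and physical constants of the mixture model.

    Defaults follow the values used in the simulations (proliferation rate
    and hypoxic-death threshold from the sensitivity runs) rather than the
    literature ranges, which are wider; see the package methods note.

    Attributes
    ----------
    nu_c : float
        Cancer-cell proliferation rate (1/day).
    delta_c : float
        Dimensionless hypoxic-death threshold: net proliferation changes
        sign where ``n / n_s`` crosses this value.
    n_s : float
        Physiological oxygen concentration (mM).
    k_n : float
        Chemotactic coefficient (mm² mM⁻¹ day⁻¹).
    M : float
        Interphase friction (mm⁻² Pa day); the Darcy motility is its inverse
        scaled by ``(1 - phi)²``.
    eps : float
        Diffuse-interface coefficient; ``eps² Δphi`` carries pressure units
        (Pa^½ mm under this package's convention, see
        :func:`derive_interface_coefficient`).
    E : float
        Young's modulus of brain matter (Pa).
    phi_e : float
        Equilibrium cell volume fraction: cell-cell forces vanish there,
        attraction below, repulsion above.
    S_n : float
        Blood–tissue oxygen transfer rate (1/day).
    delta_n : float
        Oxygen consumption rate by tumor cells (1/day).
    D_n : float
        Scalar oxygen diffusivity for isotropic runs (mm²/day).
    chi : float
        Interstitial fluid pressure scale (Pa).
    l_n : float
        Oxygen penetration length (mm).
    """

    nu_c: float = 0.25
    delta_c: float = 0.3
    n_s: float = 0.07
    k_n: float = 100.0
    M: float = 5000.0
    eps: float = 0.02
    E: float = 694.0
    phi_e: float = 0.389
    S_n: float = 1.0e4
    delta_n: float = 1000.0
    D_n: float = 86.4
    chi: float = 900.0
    l_n: float = 0.1

    def __post_init__(self) -> None:
        positive = ("n_s", "M", "eps", "E", "S_n", "D_n", "chi", "l_n")
        for name in positive:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"parameter {name} must be strictly positive, "
                                 f"got {value!r}")
        # nu_c, delta_n and k_n may be exactly zero: switching off
        # proliferation, uptake or chemotaxis is a legitimate limit case
        # (used by the conservation and nutrient-pinning diagnostics).
        for name in ("nu_c", "delta_n", "k_n"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0.0:
                raise ValueError(f"parameter {name} must be non-negative, "
                                 f"got {value!r}")
        if not 0.0 < self.phi_e < 1.0:
            raise ValueError(f"phi_e must lie in (0, 1), got {self.phi_e!r}")
        if not 0.0 <= self.delta_c <= 1.0:
            raise ValueError(f"delta_c must lie in [0, 1], got {self.delta_c!r}")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# Module-level clip counter so solver diagnostics can report how often the
# saturation guard fired during a run.
_clip_events = {"count": 0}


def clip_phase(phi: np.ndarray | float, *, count: bool = True):
    """Clip a volume fraction to the admissible range [0, 1 - 1e-6].

    Numerical overshoot near saturation must not produce infinities in
    ``f(phi)`` (which diverges at phi = 1); undershoot below zero must not
    flip the sign of the degenerate coefficients.  Clipping events are
    counted and logged at debug level.
    """
    arr = np.asarray(phi, dtype=float)
    out_of_range = (arr < 0.0) | (arr > PHI_CLIP_MAX)
    n_bad = int(np.count_nonzero(out_of_range))
    if n_bad and count:
        _clip_events["count"] += n_bad
        logger.debug("clip_phase: clipped %d value(s) into [0, %g]",
                     n_bad, PHI_CLIP_MAX)
    clipped = np.clip(arr, 0.0, PHI_CLIP_MAX)
    if np.isscalar(phi) or np.ndim(phi) == 0:
        return float(clipped)
    return clipped


def clip_event_count() -> int:
    """Total number of saturation-guard clips since import (diagnostic)."""
    return _clip_events["count"]


def bulk_pressure_derivative(phi, params: ModelParameters):
    """Bulk interaction pressure f(phi) = E phi² (phi − phi_e) / (1 − phi), in Pa.

    This is the derivative of the bulk free energy with respect to the cell
    fraction: negative (adhesion) for 0 < phi < phi_e, zero at phi ∈
    {0, phi_e}, positive (repulsion) above phi_e, and diverging as the
    mixture approaches cell saturation phi → 1.

    Raises
    ------
    ValueError
        If any phi lies outside [0, 1) — the law is singular at 1 and a
        negative volume fraction is non-physical.
    """
    arr = np.asarray(phi, dtype=float)
    if np.any(arr < 0.0) or np.any(arr >= 1.0):
        raise ValueError("bulk_pressure_derivative requires 0 <= phi < 1")
    out = params.E * arr**2 * (arr - params.phi_e) / (1.0 - arr)
    if np.isscalar(phi) or np.ndim(phi) == 0:
        return float(out)
    return out


def bulk_pressure_derivative_prime(phi, params: ModelParameters):
    """d f / d phi, needed for the Newton linearization of the Σ equation."""
    arr = np.asarray(phi, dtype=float)
    if np.any(arr < 0.0) or np.any(arr >= 1.0):
        raise ValueError("bulk_pressure_derivative_prime requires 0 <= phi < 1")
    one_m = 1.0 - arr
    bracket = 2.0 * (arr - params.phi_e) * one_m + arr * one_m + arr * (arr - params.phi_e)
    out = params.E * arr * bracket / one_m**2
    if np.isscalar(phi) or np.ndim(phi) == 0:
        return float(out)
    return out


def motility(phi, params: ModelParameters):
    """Darcy motility K(phi) = (1 − phi)² / M (mm² Pa⁻¹ day⁻¹).

    Inverse of the interphase friction, degenerating to zero at cell
    saturation (phi = 1), where relative motion of the phases stops.
    """
    if params.M <= 0.0:
        raise ValueError(f"friction parameter M must be positive, got {params.M!r}")
    arr = np.asarray(phi, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("motility requires 0 <= phi <= 1")
    out = (1.0 - arr) ** 2 / params.M
    if np.isscalar(phi) or np.ndim(phi) == 0:
        return float(out)
    return out


def net_proliferation(phi, n, params: ModelParameters):
    """Net proliferation rate ν_c phi (n/n_s − δ_c)(1 − phi), in 1/day.

    Oxygen-limited logistic growth: positive where the normalized nutrient
    exceeds the hypoxic threshold δ_c, negative (apoptosis) below it; the
    (1 − phi) factor models contact inhibition near saturation.
    """
    phi_arr = np.asarray(phi, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(phi_arr < 0.0) or np.any(phi_arr > 1.0):
        raise ValueError("net_proliferation requires 0 <= phi <= 1")
    if np.any(n_arr < 0.0):
        raise ValueError("net_proliferation requires n >= 0")
    out = params.nu_c * phi_arr * (n_arr / params.n_s - params.delta_c) * (1.0 - phi_arr)
    if np.ndim(phi_arr) == 0 and np.ndim(n_arr) == 0:
        return float(out)
    return out


def net_proliferation_dphi(phi, n, params: ModelParameters):
    """Derivative of the net proliferation rate with respect to phi."""
    phi_arr = np.asarray(phi, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    out = params.nu_c * (n_arr / params.n_s - params.delta_c) * (1.0 - 2.0 * phi_arr)
    if np.ndim(phi_arr) == 0 and np.ndim(n_arr) == 0:
        return float(out)
    return out


def chemotactic_flux(phi, grad_n, T, k_n, *, sym_tol: float = 1.0e-10):
    """Cell-phase chemotactic advective flux J = k_n · phi · T · ∇n.

    Directed motion up the nutrient gradient, biased along the local fiber
    direction by the dimensionless preferential-direction tensor ``T``
    (symmetric, PSD).  The tumor-phase balance receives ``−∇·J``.

    Parameters
    ----------
    phi : float
        Local cell volume fraction.
    grad_n : (3,) array
        Nutrient gradient (mM/mm).
    T : (3, 3) array
        Symmetric tensor of preferential directions.
    k_n : float
        Chemotactic coefficient (mm² mM⁻¹ day⁻¹).
    """
    T = np.asarray(T, dtype=float)
    if T.shape != (3, 3):
        raise ValueError(f"T must be a 3x3 tensor, got shape {T.shape}")
    if not np.allclose(T, T.T, atol=sym_tol, rtol=0.0):
        raise ValueError("preferential-direction tensor must be symmetric")
    eigvals = np.linalg.eigvalsh(T)
    if eigvals.min() < -sym_tol:
        raise ValueError("preferential-direction tensor must be positive "
                         f"semi-definite (min eigenvalue {eigvals.min():g})")
    grad = np.asarray(grad_n, dtype=float)
    return k_n * float(phi) * (T @ grad)


def derive_uptake_rate(D_n: float, l_n: float) -> float:
    """Oxygen uptake rate δ_n = D_n / l_n² (1/day).

    Derived from the oxygen diffusivity and the penetration length — the
    distance an oxygen molecule covers before being taken up by a tumor
    cell.  D_n = 86.4–156.5 mm²/day with l_n = 0.1 mm gives the admissible
    range 8640–15650 day⁻¹.
    """
    if not (np.isfinite(D_n) and D_n > 0.0):
        raise ValueError(f"D_n must be strictly positive, got {D_n!r}")
    if not (np.isfinite(l_n) and l_n > 0.0):
        raise ValueError(f"l_n must be strictly positive, got {l_n!r}")
    return D_n / l_n**2


def derive_interface_coefficient(chi: float, cell_size: float) -> float:
    """Interface coefficient ε = √χ · cell_size (Pa^½ mm).

    One dimensionally consistent reconstruction of the diffuse-interface
    coefficient from the interstitial fluid pressure scale χ and the
    cell-cell interaction distance (of the order of the cell size): with
    this convention ``ε² Δphi`` carries pressure units, matching ``f(phi)``
    in the excess-pressure law Σ = f(phi) − ε² Δphi.
    """
    if not (np.isfinite(chi) and chi > 0.0):
        raise ValueError(f"chi must be strictly positive, got {chi!r}")
    if not (np.isfinite(cell_size) and cell_size > 0.0):
        raise ValueError(f"cell_size must be strictly positive, got {cell_size!r}")
    return float(np.sqrt(chi) * cell_size)
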