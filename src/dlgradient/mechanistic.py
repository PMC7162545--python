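"""Compartmental Dl/Cact/Toll dynamics over nuclear cycle 14.

The half-embryo DV circumference is discretized into ``n_compartments``
(default 51) well-mixed nucleus + cytoplasm compartments with centres
x_h = (h-1)/(n-1) on [0, 1] (0 = ventral midline, 1 = dorsal midline).
Two cytoplasmic species are tracked per compartment: free Dorsal ``u`` and
the Dl/Cact complex ``w``.  Their nondimensional dynamics are

    du_h/dT = a1*lambda_d  * Lap(u)_h + a2*beta(x_h)*w_h/(kappa + w_h) - a3*gamma*u_h
    dw_h/dT = a4*lambda_dc * Lap(w)_h - a5*beta(x_h)*w_h/(kappa + w_h) + a6*gamma*u_h

where Lap is the discrete Laplacian with no-flux ends,
beta(x) = beta_o * exp(-(x/phi_toll)^2) is the ventrally-peaked Toll-mediated
dissociation rate (Michaelis-Menten in w with saturation constant kappa), and
gamma is the re-association of free Dl with Cactus.  The a_i are order-one
weighting factors from the nondimensionalization (default 1).  With
a2 = a5 and a3 = a6 total Dl (u + w summed over compartments) is conserved.

Dosage perturbations double or halve the initial Dl/Cact load: the initial
condition is u = 0, w = dosage everywhere.  Nuclear concentrations follow
the cytoplasm through an import/export pseudo-equilibrium, C_nuc = K_eq *
C_cyt, so the nuclear free-Dl gradient is a positive multiple of ``u`` and
threshold-crossing positions do not depend on K_eq.

The length-scale ratio compares effective diffusivities of complexed versus
free Dl:

    rho = lambda_dc * (V_nuc*K_eq_dc + V_cyt) / (lambda_d * (V_nuc*K_eq_d + V_cyt))

rho > 1 means Cact facilitates Dl transport ("shuttling").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MechanisticParams",
    "GeometryParams",
    "SimulationOutput",
    "SimulationError",
    "toll_profile",
    "rhs",
    "simulate",
    "length_scale_ratio",
    "nuclear_gradient",
]


class InvalidParameterError(ValueError):
    pass


class SimulationError(RuntimeError):
    """Solver failure; carries the offending parameter set."""

    def __init__(self, message: str, params: "MechanisticParams"):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class MechanisticParams:
    """Rate and transport constants of the compartment model.

    lambda_d, lambda_dc : intercompartmental exchange rates of free Dl and
        Dl/Cact complex (the model's lambda_u, lambda_w)
    beta_o : maximal Toll-mediated dissociation rate
    gamma : re-association rate of free Dl with Cactus
    kappa : Michaelis-Menten saturation constant (order-1 concentration units)
    phi_toll : Gaussian width of the active-Toll region (DV coordinate)
    a : six order-one weighting factors from the nondimensionalization
    dosage : initial Dl/Cact multiplier (0.5 / 1 / 2 for 1x / 2x / 4x)
    t_end : simulated duration, ~minutes (nuclear cycle 14 interphase)
    """

    lambda_d: float = 1.0
    lambda_dc: float = 1.0
    beta_o: float = 1.0
    gamma: float = 1.0
    kappa: float = 1.0
    phi_toll: float = 0.15
    a: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    n_compartments: int = 51
    dosage: float = 1.0
    t_end: float = 60.0

    def __post_init__(self) -> None:
        for name in ("lambda_d", "lambda_dc", "beta_o", "gamma"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.kappa <= 0:
            raise InvalidParameterError("kappa must be > 0")
        if self.phi_toll <= 0:
            raise InvalidParameterError("phi_toll must be > 0")
        if self.n_compartments < 3:
            raise InvalidParameterError("n_compartments must be >= 3")
        if self.dosage <= 0:
            raise InvalidParameterError("dosage must be > 0")
        if len(self.a) != 6:
            raise InvalidParameterError("a must have six entries")

    def with_dosage(self, dosage: float) -> "MechanisticParams":
        return replace(self, dosage=dosage)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_compartments)


@dataclass(frozen=True)
class GeometryParams:
    """Nondimensional nuclear/cytoplasmic volumes and import equilibria."""

    v_nuc: float = 1.0
    v_cyt: float = 1.0
    keq_d: float = 1.0
    keq_dc: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v_nuc", "v_cyt", "keq_d", "keq_dc"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")


@dataclass
class SimulationOutput:
    """Time-resolved compartment concentrations and derived summaries."""

    times: np.ndarray
    u: np.ndarray  # [time, compartment] free cytoplasmic Dl
    w: np.ndarray  # [time, compartment] Dl/Cact complex
    x: np.ndarray
    params: MechanisticParams = field(repr=False, default=None)

    @property
    def final_free_dl(self) -> np.ndarray:
        return self.u[-1]

    @property
    def amplitude(self) -> float:
        return float(self.final_free_dl.max())

    def total_mass(self) -> np.ndarray:
        """Sum of u + w over compartments at each stored time."""
        return (self.u + self.w).sum(axis=1)


def toll_profile(beta_o: float, phi_toll: float, x) -> np.ndarray | float:
    """Ventrally restricted Toll activity beta(x) = beta_o*exp(-(x/phi)^2)."""
    if phi_toll <= 0:
        raise InvalidParameterError(f"phi_toll must be > 0, got {phi_toll}")
    out = beta_o * np.exp(-((np.asarray(x, dtype=float) / phi_toll) ** 2))
    return float(out) if np.ndim(x) == 0 else out


def _laplacian(v: np.ndarray) -> np.ndarray:
    """Flux-form discrete Laplacian with no-flux (reflecting) ends.

    Boundary fluxes are zero, so the row sum telescopes to exactly zero and
    the plain compartment sum is conserved by pure transport.
    """
    flux = np.diff(v)
    out = np.empty_like(v)
    out[0] = flux[0]
    out[-1] = -flux[-1]
    out[1:-1] = flux[1:] - flux[:-1]
    return out


def rhs(state: np.ndarray, params: MechanisticParams, beta: np.ndarray | None = None):
    """Time derivatives (du, dw) for stacked state vectors (u, w)."""
    n = params.n_compartments
    u = state[:n]
    w = state[n:]
    if np.any(np.isnan(u)) or np.any(np.isnan(w)):
        raise SimulationError("NaN encountered in state vector", params)
    if beta is None:
        beta = toll_profile(params.beta_o, params.phi_toll, params.x)
    a1, a2, a3, a4, a5, a6 = params.a
    toll = beta * w / (params.kappa + w)
    du = a1 * params.lambda_d * _laplacian(u) + a2 * toll - a3 * params.gamma * u
    dw = a4 * params.lambda_dc * _laplacian(w) - a5 * toll + a6 * params.gamma * u
    return du, dw


def simulate(params: MechanisticParams, n_times: int = 61) -> SimulationOutput:
    """Integrate the compartment model over nc14.

    Initial condition: all Dl complexed with Cact, uniformly distributed
    (u = 0, w = dosage).  Uses LSODA (stiff-capable) with a banded Jacobian
    on an interleaved state layout; rtol 1e-6, atol 1e-9, outputs on
    ``n_times`` (>= 61) uniform time points.

    Raises :class:`SimulationError` on solver failure so screen callers can
    record rather than crash.
    """
    n = params.n_compartments
    x = params.x
    beta = toll_profile(params.beta_o, params.phi_toll, x)
    a1, a2, a3, a4, a5, a6 = params.a
    ld = a1 * params.lambda_d
    ldc = a4 * params.lambda_dc
    kappa, gamma = params.kappa, params.gamma

    def f(t, y):
        # interleaved layout (u0, w0, u1, w1, ...) keeps the Jacobian banded
        u = y[0::2]
        w = y[1::2]
        toll = beta * w / (kappa + w)
        du = ld * _laplacian(u) + a2 * toll - a3 * gamma * u
        dw = ldc * _laplacian(w) - a5 * toll + a6 * gamma * u
        out = np.empty(2 * n)
        out[0::2] = du
        out[1::2] = dw
        return out

    y0 = np.empty(2 * n)
    y0[0::2] = 0.0
    y0[1::2] = params.dosage
    t_eval = np.linspace(0.0, params.t_end, max(n_times, 61))
    sol = solve_ivp(
        f,
        (0.0, params.t_end),
        y0,
        method="LSODA",
        lband=2,
        uband=2,
        rtol=1e-6,
        atol=1e-9,
        t_eval=t_eval,
    )
    if not sol.success:
        raise SimulationError(f"solver failed: {sol.message}", params)
    y = sol.y.T
    return SimulationOutput(
        times=sol.t, u=y[:, 0::2].copy(), w=y[:, 1::2].copy(), x=x, params=params
    )


def length_scale_ratio(params: MechanisticParams, geom: GeometryParams) -> float:
    """Effective-diffusivity ratio rho of Dl/Cact complex to free Dl."""
    if params.lambda_d == 0:
        raise InvalidParameterError("rho undefined for lambda_d = 0")
    num = params.lambda_dc * (geom.v_nuc * geom.keq_dc + geom.v_cyt)
    den = params.lambda_d * (geom.v_nuc * geom.keq_d + geom.v_cyt)
    return float(num / den)


def nuclear_gradient(output: SimulationOutput, geom: GeometryParams) -> np.ndarray:
    """Nuclear free-Dl per compartment at t_end via pseudo-equilibrium.

    C_nuc = K_eq,d * C_cyt; a positive scaling of u, so border positions are
    invariant to the choice of K_eq,d.
    """
    return geom.keq_d * output.final_free_dl
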