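"""Drug concentration fields from blood-vessel sources.

Implements the standard linear reaction-diffusion model for a drug released
by vessels and absorbed everywhere at a first-order clearance rate ``gamma``:

``du/dt = D * laplacian(u) - gamma * u + source``

Closed forms for a point source of strength ``k``:

* 1D steady state: ``u(x) = k / sqrt(4 D gamma) * exp(-|x| sqrt(gamma/D))``
* 2D steady state: ``u(r) = k / (2 pi D) * K0(sqrt(gamma/D) * r)`` — the
  modified-Bessel kernel, regularized inside a finite vessel radius where it
  would diverge.
* 1D transient (quadrature oracle):
  ``u(x,t) = (k/pi) * Int_0^inf cos(x y) (1 - exp(-t (D y^2 + gamma))) / (D y^2 + gamma) dy``

plus an explicit finite-difference solver with clamped (Dirichlet) vessel
sites and a zero-concentration outer boundary, and the empirical exponential
penetration model ``u = k * 2**(-d / L)`` with characteristic penetration
length ``L`` (the distance at which the concentration halves).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import yaml
from scipy import integrate, special

__all__ = [
    "PkParams",
    "DrugField",
    "VesselLayout",
    "steady_state_1d",
    "steady_state_2d",
    "transient_1d_oracle",
    "transient_2d_oracle",
    "solve_pde",
    "exp_decay_field",
    "superpose_sources",
    "write_field",
    "read_field",
]


@dataclass(frozen=True)
class PkParams:
    """Pharmacokinetic parameters of the reaction-diffusion model.

    ``D`` is the diffusivity (length^2/time), ``gamma`` the first-order
    absorption/clearance rate (1/time), ``k`` the point-source strength, and
    ``vessel_radius`` the regularization radius inside which the 2D kernel is
    held constant.
    """

    D: float = 1.0
    gamma: float = 1.0
    k: float = 1.0
    vessel_radius: float = 0.5

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.vessel_radius <= 0:
            raise ValueError("vessel_radius must be > 0")


@dataclass
class DrugField:
    """Scalar drug concentration on a lattice (values >= 0, finite)."""

    values: np.ndarray
    spacing: float = 1.0
    unit: str = "ug/mL"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("drug field contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("drug field contains negative values")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class VesselLayout:
    """Vessel positions (lattice coordinates) with per-vessel source values."""

    positions: List[Tuple[int, int]]
    strengths: Optional[List[float]] = None  # boundary conc (PDE) or k (kernels)

    def __post_init__(self) -> None:
        self.positions = [tuple(int(v) for v in p) for p in self.positions]
        if not self.positions:
            raise ValueError("vessel layout must contain at least one vessel")
        if self.strengths is None:
            self.strengths = [1.0] * len(self.positions)
        if len(self.strengths) != len(self.positions):
            raise ValueError("one strength per vessel required")
        if any(s < 0 for s in self.strengths):
            raise ValueError("vessel strengths must be >= 0")

    def validate_in_grid(self, shape: Tuple[int, int]) -> None:
        for p in self.positions:
            if not all(0 <= c < s for c, s in zip(p, shape)):
                raise ValueError(f"vessel at {p} outside grid of shape {shape}")


def steady_state_1d(params: PkParams, x) -> np.ndarray:
    """1D steady-state concentration of a point source at the origin."""
    if params.gamma == 0:
        raise ValueError("gamma = 0 has no 1D steady state (unbounded accumulation)")
    x = np.asarray(x, dtype=float)
    amp = params.k / np.sqrt(4.0 * params.D * params.gamma)
    out = amp * np.exp(-np.abs(x) * np.sqrt(params.gamma / params.D))
    return out if out.ndim else float(out)


def steady_state_2d(params: PkParams, r) -> np.ndarray:
    """2D steady-state kernel ``k/(2 pi D) K0(a r)``, capped inside the vessel.

    The Bessel kernel diverges at ``r = 0``; concentrations at
    ``r < vessel_radius`` are held at the value on the vessel boundary.
    """
    if params.gamma == 0:
        raise ValueError("gamma = 0 has no 2D steady state")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance must be >= 0")
    a = np.sqrt(params.gamma / params.D)
    r_eff = np.maximum(r, params.vessel_radius)
    out = params.k / (2.0 * np.pi * params.D) * special.k0(a * r_eff)
    return out if out.ndim else float(out)


def transient_1d_oracle(params: PkParams, x: float, t: float, quadrature_tol: float = 1e-10) -> float:
    """Transient 1D point-source solution, evaluated by adaptive quadrature.

    Exact at ``t = 0`` (zero everywhere) and converges to
    :func:`steady_state_1d` as ``t`` grows. Uses the oscillatory-weight
    QUADPACK rule for the semi-infinite cosine transform.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0.0:
        return 0.0
    D, gamma, k = params.D, params.gamma, params.k

    def f(y: float) -> float:
        q = D * y * y + gamma
        return (k / np.pi) * (1.0 - np.exp(-t * q)) / q

    if x == 0.0:
        val, err = integrate.quad(f, 0.0, np.inf, epsabs=quadrature_tol, epsrel=quadrature_tol)
    else:
        val, err = integrate.quad(
            f, 0.0, np.inf, weight="cos", wvar=abs(float(x)), epsabs=quadrature_tol, limlst=200
        )
    if not np.isfinite(val):
        raise RuntimeError(f"transient quadrature failed: value={val}, err={err}")
    return float(val)


def transient_2d_oracle(params: PkParams, r: float, t: float, quadrature_tol: float = 1e-10) -> float:
    """Transient 2D radial solution via the Hankel-transform integral.

    ``u(r,t) = (1/2pi) Int_0^inf k rho J0(r rho) (1 - exp(-t(D rho^2+gamma)))/(D rho^2+gamma) drho``.
    Provided as a validation oracle only; converges to :func:`steady_state_2d`
    (without the vessel cap) at large ``t``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0.0:
        return 0.0
    D, gamma, k = params.D, params.gamma, params.k

    def f(rho: float) -> float:
        q = D * rho * rho + gamma
        return k * rho * special.j0(r * rho) * (1.0 - np.exp(-t * q)) / (2.0 * np.pi * q)

    # split at the J0 oscillation scale; truncate the (absolutely convergent,
    # oscillatory) tail at a finite bound where the integrand is negligible
    upper = max(50.0 / max(r, 1e-6), 20.0 / np.sqrt(D * t + 1e-12))
    val, err = integrate.quad(f, 0.0, upper, epsabs=quadrature_tol, epsrel=1e-10, limit=500)
    tail, _ = integrate.quad(f, upper, 20.0 * upper, epsabs=quadrature_tol, limit=500)
    return float(val + tail)


def _laplacian_interior(u: np.ndarray, dx: float) -> np.ndarray:
    return (
        u[:-2, 1:-1] + u[2:, 1:-1] + u[1:-1, :-2] + u[1:-1, 2:] - 4.0 * u[1:-1, 1:-1]
    ) / (dx * dx)


def solve_pde(
    layout: VesselLayout,
    params: PkParams,
    grid_shape: Tuple[int, int],
    dt: Optional[float] = None,
    n_steps: Optional[int] = None,
    steady_tol: Optional[float] = 1e-9,
    dx: float = 1.0,
    u0: Optional[np.ndarray] = None,
    max_steps: int = 2_000_000,
) -> DrugField:
    """Explicit (FTCS) reaction-diffusion solve with clamped vessel sites.

    Vessel sites are Dirichlet-clamped to their per-vessel strength every
    step ("constant supply"); the outer boundary is held at zero. With
    ``n_steps`` the solver runs a fixed number of steps; otherwise it runs to
    steady state (max per-step change < ``steady_tol``).
    """
    layout.validate_in_grid(grid_shape)
    if dt is None:
        # positivity bound includes the decay term: dt <= 1/(4 D/dx^2 + gamma)
        dt = 0.9 / (4.0 * params.D / (dx * dx) + params.gamma)
    if params.D * dt / (dx * dx) > 0.25 + 1e-12:
        raise ValueError(
            f"explicit scheme unstable: D*dt/dx^2 = {params.D * dt / (dx * dx):.3g} > 0.25"
        )
    u = np.zeros(grid_shape, dtype=float) if u0 is None else np.array(u0, dtype=float)
    pos = tuple(np.array(p) for p in zip(*layout.positions))
    strengths = np.asarray(layout.strengths, dtype=float)
    u[pos] = strengths
    total = n_steps if n_steps is not None else max_steps
    for _ in range(total):
        lap = _laplacian_interior(u, dx)
        new = u.copy()
        new[1:-1, 1:-1] = u[1:-1, 1:-1] + dt * (params.D * lap - params.gamma * u[1:-1, 1:-1])
        new[0, :] = new[-1, :] = new[:, 0] = new[:, -1] = 0.0
        new[pos] = strengths
        delta = np.max(np.abs(new - u))
        u = new
        if n_steps is None and delta < steady_tol:
            break
    else:
        if n_steps is None:
            warnings.warn(f"solve_pde did not reach steady_tol={steady_tol} in {max_steps} steps")
    return DrugField(values=np.maximum(u, 0.0), spacing=dx)


def pde_step(
    u: np.ndarray,
    layout: VesselLayout,
    params: PkParams,
    dt: float,
    dx: float = 1.0,
    n_substeps: int = 1,
) -> np.ndarray:
    """Advance an existing field by one (possibly sub-stepped) FTCS update.

    Used by the agent-based simulator to co-integrate the drug field with the
    population; mutates and returns ``u``.
    """
    sub_dt = dt / n_substeps
    if params.D * sub_dt / (dx * dx) > 0.25 + 1e-12:
        raise ValueError("explicit scheme unstable; increase n_substeps")
    pos = tuple(np.array(p) for p in zip(*layout.positions))
    strengths = np.asarray(layout.strengths, dtype=float)
    u[pos] = strengths
    for _ in range(n_substeps):
        lap = _laplacian_interior(u, dx)
        u[1:-1, 1:-1] += sub_dt * (params.D * lap - params.gamma * u[1:-1, 1:-1])
        u[0, :] = u[-1, :] = u[:, 0] = u[:, -1] = 0.0
        u[pos] = strengths
    np.maximum(u, 0.0, out=u)
    return u


def _distance_maps(layout: VesselLayout, grid_shape: Tuple[int, int]) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(grid_shape[0]), np.arange(grid_shape[1]), indexing="ij")
    return np.stack(
        [np.hypot(ii - p[0], jj - p[1]) for p in layout.positions]
    )  # (n_vessels, *shape)


def exp_decay_field(
    layout: VesselLayout,
    k: float,
    L: float,
    grid_shape: Tuple[int, int],
    mode: str = "nearest",
    spacing: float = 1.0,
) -> DrugField:
    """Empirical perivascular exponential-decay field ``u = k * 2**(-d/L)``.

    ``L`` is the characteristic penetration length: the distance (in lattice
    units) at which concentration falls to half the vessel boundary value
    ``k``. ``d`` is the Euclidean distance to the nearest vessel
    (``mode="nearest"``, the default, since the model is an empirical
    single-vessel fit); ``mode="sum"`` superposes per-vessel exponentials.
    """
    if L <= 0:
        raise ValueError("characteristic length L must be > 0")
    layout.validate_in_grid(grid_shape)
    dists = _distance_maps(layout, grid_shape)
    if mode == "nearest":
        values = k * np.exp(-dists.min(axis=0) * np.log(2.0) / L)
    elif mode == "sum":
        values = (k * np.exp(-dists * np.log(2.0) / L)).sum(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DrugField(values=values, spacing=spacing)


def superpose_sources(
    layout: VesselLayout,
    params: PkParams,
    grid_shape: Tuple[int, int],
    spacing: float = 1.0,
) -> DrugField:
    """Multi-vessel 2D steady state: sum of the regularized K0 kernel over sources.

    Equivalent to convolving the discretized kernel with the point-source
    indicator map (the model is linear, so superposition is exact). Per-vessel
    layout strengths act as relative multipliers of ``params.k``.
    """
    layout.validate_in_grid(grid_shape)
    dists = _distance_maps(layout, grid_shape) * spacing
    values = np.zeros(grid_shape, dtype=float)
    for d, s in zip(dists, layout.strengths):
        p = PkParams(
            D=params.D, gamma=params.gamma, k=s * params.k, vessel_radius=params.vessel_radius
        )
        values += steady_state_2d(p, d)
    return DrugField(values=values, spacing=spacing)


def write_field(fieldobj: DrugField, grid_path, meta_path=None) -> None:
    """Row-major float CSV grid plus optional YAML sidecar (shape, spacing, unit)."""
    np.savetxt(grid_path, fieldobj.values, delimiter=",")
    if meta_path is not None:
        meta = {
            "shape": list(fieldobj.values.shape),
            "spacing": float(fieldobj.spacing),
            "unit": fieldobj.unit,
        }
        with open(meta_path, "w") as fh:
            yaml.safe_dump(meta, fh)


def read_field(grid_path, meta_path=None) -> DrugField:
    values = np.loadtxt(grid_path, delimiter=",", ndmin=2)
    spacing, unit = 1.0, "ug/mL"
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
        spacing = float(meta.get("spacing", 1.0))
        unit = meta.get("unit", unit)
    return DrugField(values=values, spacing=spacing, unit=unit)
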