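"""Constrained bending-energy minimization of the coupled membrane system.

The outer membrane and the inner boundary membrane are treated as parallel
non-stretchable Helfrich surfaces with vanishing spontaneous curvature.
Because the two membranes share (to leading order in d·J) the curvature of
the mid-surface, the system energy is

    F = F_out + F_in = 2 · (κ/2) ∮ J² dA = κ ∮ J² dA,

i.e. twice the Willmore-type functional of the mid-surface.  Optimal shapes
minimize F at fixed mid-surface area A and fixed area difference
ΔA = d·M, with M = ∮J dA.  The enclosed volume is left unconstrained:
water and solutes exchange freely across mitochondrial membranes, so only
the membrane areas are conserved quantities on the modelled timescale.

The profile is restricted to closed, up-down mirror-symmetric shapes and
parametrized by the tilt angle on the half-profile,

    psi(t) = (π/2)·t + Σ_k a_k sin(kπt),   t = s / h ∈ [0, 1],

where h is the half arclength.  The Fourier coefficients a_k and h are the
unknowns; boundary conditions psi(0)=0 (pole) and psi(1)=π/2 (equator) are
built into the basis, so every iterate closes smoothly at the poles.
Minimization uses SLSQP with equality constraints on A and M; shapes along
a family are obtained by continuation in ΔA/A starting from a slightly
perturbed sphere.

Energies are reported in units of the bending modulus κ; for any closed
shape F ≥ 16π·κ, with equality only for the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq, minimize

from .errors import (
    BranchError,
    DegenerateShapeError,
    InvalidParameterError,
    SolverError,
    UnreachableTargetError,
)
from .geometry import (
    AxisymmetricShape,
    geometry_report,
    make_spheroid,
    willmore_energy,
)

WILLMORE_BOUND = 16.0 * np.pi  # ∮J²dA of a sphere; lower bound for closed shapes


@dataclass(frozen=True)
class EnergyModel:
    """Elastic parameters of the two-membrane system.

    ``kappa`` is the bending modulus (arbitrary energy units; minimizing
    shapes do not depend on its value).  ``d`` is the intermembrane
    distance in nm.  The spontaneous curvature is identically zero.
    """

    d: float = 10.0
    kappa: float = 1.0
    spontaneous_curvature: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise InvalidParameterError("bending modulus kappa must be positive")
        if not self.d > 0:
            raise InvalidParameterError("intermembrane distance d must be positive")


@dataclass(frozen=True)
class SolverOptions:
    """Numerical options for the constrained minimizer."""

    n_modes: int = 16          # Fourier modes of the tilt profile
    n_quad: int = 400          # quadrature intervals on the half-profile (even)
    n_nodes: int = 201         # nodes of the exported full profile
    max_iter: int = 500
    residual_tol: float = 1e-4       # relative tolerance on A and ΔA
    continuation_step: float = 0.01  # default step in ΔA/A
    max_step_halvings: int = 5
    perturbation: float = 1e-3       # symmetry-breaking amplitude, units of R0
    seed: int = 0


@dataclass
class ShapeSolution:
    """A converged (or diagnostic) constrained minimum."""

    shape: AxisymmetricShape
    target_dAoverA: float
    achieved_dAoverA: float
    energy: float                   # units of kappa
    constraint_residuals: dict      # relative residuals on A and ΔA
    sphericity: float
    shape_class: str                # sphere | elongated | peanut
    iterations: int
    converged: bool
    coefficients: np.ndarray        # (h, a_1..a_K) in units of R0


class _HalfProfile:
    """Precomputed discretization of the mirror-symmetric half profile."""

    def __init__(self, n_quad: int, n_modes: int):
        if n_quad % 2:
            n_quad += 1
        self.t = np.linspace(0.0, 1.0, n_quad + 1)
        dt = self.t[1] - self.t[0]
        w = np.ones(n_quad + 1)
        w[1:-1:2], w[2:-1:2] = 4.0, 2.0
        self.w = w * dt / 3.0  # composite Simpson weights
        k = np.arange(1, n_modes + 1)
        self.sin = np.sin(np.pi * np.outer(self.t, k))
        self.dcos = np.cos(np.pi * np.outer(self.t, k)) * (np.pi * k)
        self.n_modes = n_modes

    def fields(self, x: np.ndarray):
        h, a = x[0], x[1:]
        psi = 0.5 * np.pi * self.t + self.sin @ a
        dpsi_dt = 0.5 * np.pi + self.dcos @ a
        cos_psi, sin_psi = np.cos(psi), np.sin(psi)
        r = h * cumulative_trapezoid(cos_psi, self.t, initial=0.0)
        return h, psi, dpsi_dt, cos_psi, sin_psi, r

    def quantities(self, x: np.ndarray):
        """Reduced-unit area, integrated curvature, volume, ∮J²dA, r-penalty."""
        h, psi, dpsi_dt, _, sin_psi, r = self.fields(x)
        w = self.w
        area = 4.0 * np.pi * h * (w @ r)
        M = 4.0 * np.pi * ((w @ (r * dpsi_dt)) + h * (w @ sin_psi))
        volume = 2.0 * np.pi * h * (w @ (r**2 * sin_psi))
        safe_r = np.where(r > 1e-12, r, 1.0)
        J = dpsi_dt / h + np.where(r > 1e-12, sin_psi / safe_r, 0.0)
        J[0] = 2.0 * dpsi_dt[0] / h
        willmore = 4.0 * np.pi * h * (w @ (J**2 * r))
        penalty = 1e6 * float(np.sum(np.minimum(r, 0.0) ** 2))
        return area, M, volume, willmore, penalty


@lru_cache(maxsize=8)
def _discretization(n_quad: int, n_modes: int) -> _HalfProfile:
    return _HalfProfile(n_quad, n_modes)


def bending_energy(shape: AxisymmetricShape, model: EnergyModel) -> float:
    """Total bending energy F = κ ∮J²dA of the two-membrane system.

    Both membranes carry the mid-surface curvature to leading order in
    d·J, so their energies add to a single Willmore-type integral.
    """
    shape.require_closed()
    return model.kappa * willmore_energy(shape)


def sphere_dAoverA(mid_area: float, d: float) -> float:
    """Area-difference ratio of the sphere itself: 2d/R0."""
    R0 = np.sqrt(mid_area / (4.0 * np.pi))
    return 2.0 * d / R0


def _build_full_shape(x: np.ndarray, R0: float, n_nodes: int) -> AxisymmetricShape:
    """Mirror the half-profile solution into a closed full profile (nm)."""
    h = x[0]
    n_half = max(n_nodes // 2 + 1, 8)
    t = np.linspace(0.0, 1.0, n_half)
    k = np.arange(1, x.size)
    psi_half = 0.5 * np.pi * t + np.sin(np.pi * np.outer(t, k)) @ x[1:]
    s_half = t * h
    s_full = np.concatenate([s_half, 2.0 * h - s_half[-2::-1]])
    psi_full = np.concatenate([psi_half, np.pi - psi_half[-2::-1]])
    return AxisymmetricShape.from_tilt_profile(R0 * s_full, psi_full, closed=True)


def classify_shape(solution: ShapeSolution) -> str:
    """Classify a converged solution as sphere, elongated, or peanut.

    Sphere: sphericity ≥ 0.999.  Peanut: the radius profile has an
    interior local minimum whose depth below the flanking maxima is at
    least 2% of the maximal radius.  Otherwise elongated.
    """
    if solution.sphericity >= 0.999:
        return "sphere"
    r = solution.shape.r
    r_max = float(r.max())
    interior = slice(1, len(r) - 1)
    is_min = (r[interior] <= r[:-2]) & (r[interior] <= r[2:])
    for i in np.flatnonzero(is_min) + 1:
        left_max = float(r[: i + 1].max())
        right_max = float(r[i:].max())
        depth = min(left_max, right_max) - r[i]
        if depth >= 0.02 * r_max:
            return "peanut"
    return "elongated"


def _solve_reduced(
    target_m: float, x0: np.ndarray, disc: _HalfProfile, options: SolverOptions
):
    """One SLSQP solve in reduced units (R0 = 1, mid-area 4π)."""
    A0 = 4.0 * np.pi

    def objective(x):
        q = disc.quantities(x)
        return q[3] + q[4]

    constraints = [
        {"type": "eq", "fun": lambda x: disc.quantities(x)[0] / A0 - 1.0},
        {"type": "eq", "fun": lambda x: disc.quantities(x)[1] / target_m - 1.0},
    ]
    bounds = [(0.3, 80.0)] + [(-5.0, 5.0)] * disc.n_modes
    return minimize(
        objective,
        x0,
        method="SLSQP",
        bounds=bounds,
        constraints=constraints,
        options={"maxiter": options.max_iter, "ftol": 1e-12},
    )


def _solution_from_x(
    x, mid_area, target, model, options, disc, iterations, converged
) -> ShapeSolution:
    R0 = float(np.sqrt(mid_area / (4.0 * np.pi)))
    area, M, volume, willmore, _ = disc.quantities(x)
    d_red = model.d / R0
    achieved = d_red * M / area
    residuals = {
        "area": abs(area / (4.0 * np.pi) - 1.0),
        "area_diff": abs(achieved / target - 1.0),
    }
    shape = _build_full_shape(x, R0, options.n_nodes)
    sphericity = 36.0 * np.pi * volume**2 / area**3
    sol = ShapeSolution(
        shape=shape,
        target_dAoverA=target,
        achieved_dAoverA=achieved,
        energy=model.kappa * willmore,
        constraint_residuals=residuals,
        sphericity=float(sphericity),
        shape_class="",
        iterations=iterations,
        converged=converged,
        coefficients=np.array(x, dtype=float),
    )
    sol.shape_class = classify_shape(sol)
    return sol


def _perturbed_sphere(options: SolverOptions) -> np.ndarray:
    """Sphere iterate with a small seeded symmetry-breaking perturbation."""
    rng = np.random.default_rng(options.seed)
    x = np.zeros(1 + options.n_modes)
    x[0] = 0.5 * np.pi
    x[1:] = options.perturbation * rng.standard_normal(options.n_modes)
    return x


def _continuation_advance(
    x: np.ndarray,
    current: float,
    target: float,
    mid_area: float,
    d_red: float,
    disc: _HalfProfile,
    options: SolverOptions,
    retry_rng: np.random.Generator,
):
    """Advance the continuation from ``current`` to ``target`` in ΔA/A.

    Each substep is accepted only if SLSQP converged, both constraint
    residuals are within tolerance, and the energy does not exceed the
    prolate-spheroid trial upper bound for that target — the landscape
    just above the sphere holds higher-energy multi-lobed local minima,
    and the bound cheaply rejects steps that fall onto them.  Rejected
    steps are halved and retried from a freshly perturbed iterate.
    """
    A0 = 4.0 * np.pi
    while current < target - 1e-12:
        step = min(options.continuation_step, target - current)
        tries = 0
        while True:
            nxt = current + step
            try:
                upper = trial_prolate_oracle(mid_area, nxt, d_red *
                                             np.sqrt(mid_area / A0))
            except UnreachableTargetError:
                upper = np.inf
            res = _solve_reduced(A0 * nxt / d_red, x, disc, options)
            q = disc.quantities(res.x)
            ok = (
                res.success
                and abs(q[0] / A0 - 1.0) < options.residual_tol
                and abs(d_red * q[1] / q[0] / nxt - 1.0) < options.residual_tol
                and q[3] <= upper * (1.0 + 1e-9)
            )
            if ok:
                x, current = res.x, nxt
                break
            tries += 1
            if tries > options.max_step_halvings + 3:
                return x, current, res.nit, False
            step /= 2.0
            kick = options.perturbation * 0.1 * retry_rng.standard_normal(
                disc.n_modes
            )
            x = x + np.concatenate([[0.0], kick])
        if current >= target - 1e-12:
            return x, current, res.nit, True
    return x, current, 0, True


def minimize_shape(
    mid_area: float,
    target_dAoverA: float,
    model: EnergyModel,
    options: SolverOptions | None = None,
    _x0: np.ndarray | None = None,
) -> ShapeSolution:
    """Minimize the bending energy at fixed mid-area and area difference.

    Parameters
    ----------
    mid_area : float
        Mid-surface area in nm².
    target_dAoverA : float
        Target ΔA/A.  Must be at least the sphere's own value 2d/R0;
        smaller targets belong to the oblate branch, which is not
        modelled.
    model : EnergyModel
        Bending modulus and intermembrane distance.
    options : SolverOptions, optional
        Discretization and convergence controls.

    Returns
    -------
    ShapeSolution
        Converged shape with achieved constraints, energy (units of κ),
        sphericity and morphological class.

    Raises
    ------
    BranchError
        If the target lies below the sphere value.
    SolverError
        On non-convergence; the last iterate is attached as ``solution``.
    """
    if not mid_area > 0:
        raise InvalidParameterError("mid_area must be positive")
    options = options or SolverOptions()
    sphere_value = sphere_dAoverA(mid_area, model.d)
    if target_dAoverA < sphere_value * (1.0 - 1e-9):
        raise BranchError(
            f"target ΔA/A = {target_dAoverA:.4g} is below the sphere value "
            f"{sphere_value:.4g}; the oblate branch is not modelled"
        )
    disc = _discretization(options.n_quad, options.n_modes)
    R0 = float(np.sqrt(mid_area / (4.0 * np.pi)))
    d_red = model.d / R0

    if _x0 is not None:
        x, start = np.array(_x0, dtype=float), None
    else:
        x, start = _perturbed_sphere(options), sphere_value

    retry_rng = np.random.default_rng(options.seed + 1000)
    total_iter = 0
    if start is not None and target_dAoverA > start:
        x, reached, nit, ok = _continuation_advance(
            x, start, target_dAoverA, mid_area, d_red, disc, options, retry_rng
        )
        total_iter += nit
        if not ok:
            last = _solution_from_x(
                x, mid_area, reached, model, options, disc, total_iter, False
            )
            raise SolverError(
                f"continuation stalled at ΔA/A = {reached:.4g}", solution=last
            )
        final = x
    else:
        res = _solve_reduced(
            4.0 * np.pi * target_dAoverA / d_red, x, disc, options
        )
        total_iter += res.nit
        final = res.x

    sol = _solution_from_x(
        final, mid_area, target_dAoverA, model, options, disc, total_iter, True
    )
    if max(sol.constraint_residuals.values()) > options.residual_tol:
        sol.converged = False
        raise SolverError(
            "constraint residuals exceed tolerance "
            f"({sol.constraint_residuals})",
            solution=sol,
        )
    return sol


def shape_family(
    mid_area: float,
    d: float,
    targets,
    model: EnergyModel | None = None,
    options: SolverOptions | None = None,
) -> list[ShapeSolution]:
    """Continuation along increasing ΔA/A, each solve warm-started.

    ``targets`` must be strictly increasing with the first at or above
    the sphere value 2d/R0.  Returns solutions in target order; along the
    family sphericity is non-increasing and energy non-decreasing.  A
    non-converging member raises SolverError with the partial list
    attached as ``solution``.
    """
    targets = list(targets)
    if any(b <= a for a, b in zip(targets, targets[1:])):
        raise InvalidParameterError("targets must be strictly increasing")
    model = model or EnergyModel(d=d)
    if model.d != d:
        model = replace(model, d=d)
    options = options or SolverOptions()
    sphere_value = sphere_dAoverA(mid_area, d)
    if targets[0] < sphere_value * (1.0 - 1e-9):
        raise BranchError(
            f"first target {targets[0]:.4g} below sphere value {sphere_value:.4g}"
        )
    disc = _discretization(options.n_quad, options.n_modes)
    R0 = float(np.sqrt(mid_area / (4.0 * np.pi)))
    d_red = d / R0

    solutions: list[ShapeSolution] = []
    x = _perturbed_sphere(options)
    retry_rng = np.random.default_rng(options.seed + 1000)
    current = sphere_value
    for tgt in targets:
        x, current, nit, ok = _continuation_advance(
            x, current, tgt, mid_area, d_red, disc, options, retry_rng
        )
        if not ok:
            raise SolverError(
                f"family member ΔA/A = {tgt:.4g} failed to converge "
                f"(stalled at {current:.4g})",
                solution=solutions,
            )
        if tgt <= sphere_value * (1.0 + 1e-12):
            # target at the sphere itself: solve directly
            res = _solve_reduced(4.0 * np.pi * tgt / d_red, x, disc, options)
            if res.success:
                x, nit = res.x, res.nit
        solutions.append(
            _solution_from_x(x, mid_area, tgt, model, options, disc, nit, True)
        )
    return solutions


def trial_prolate_oracle(
    mid_area: float,
    target_dAoverA: float,
    d: float,
    kappa: float = 1.0,
    aspect_cap: float = 50.0,
) -> float:
    """Bending energy of the constraint-matching prolate spheroid.

    Scans the one-parameter prolate-spheroid family (rescaled to the
    given mid-area) for the member whose d·M/A matches the target, and
    returns its bending energy — a rigorous upper bound for the
    constrained minimum.  Curvatures are evaluated analytically from the
    elliptic parametrization, independently of the profile-based
    finite-difference route.
    """
    sphere_value = sphere_dAoverA(mid_area, d)
    reduced = target_dAoverA / sphere_value  # = M / sqrt(16π A), 1 for sphere
    if reduced < 1.0 - 1e-9:
        raise BranchError("target below the sphere value")
    if reduced <= 1.0 + 1e-12:
        return kappa * WILLMORE_BOUND

    def _reduced_m(aspect: float) -> float:
        A, M, _ = _spheroid_invariants(aspect)
        return M / np.sqrt(16.0 * np.pi * A)

    if _reduced_m(aspect_cap) < reduced:
        raise UnreachableTargetError(
            f"target ΔA/A = {target_dAoverA:.4g} unreachable within the "
            f"spheroid family at aspect ratio ≤ {aspect_cap}"
        )
    aspect = brentq(lambda c: _reduced_m(c) - reduced, 1.0 + 1e-10, aspect_cap,
                    xtol=1e-12)
    _, _, W = _spheroid_invariants(aspect)
    return kappa * W


def _spheroid_invariants(aspect: float, n: int = 4001):
    """Scale-invariant (A, M, ∮J²dA) of a prolate spheroid, b = 1, a = aspect."""
    a, b = aspect, 1.0
    theta = np.linspace(0.0, np.pi, n)
    r = b * np.sin(theta)
    dr, dz = b * np.cos(theta), a * np.sin(theta)
    d2r, d2z = -b * np.sin(theta), a * np.cos(theta)
    g = np.sqrt(dr**2 + dz**2)
    c_meridional = (dr * d2z - dz * d2r) / g**3
    with np.errstate(divide="ignore", invalid="ignore"):
        c_azimuthal = np.where(r > 1e-12, dz / np.where(r > 1e-12, r, 1.0) / g,
                               c_meridional)
    J = c_meridional + c_azimuthal
    dA = 2.0 * np.pi * r * g
    from scipy.integrate import simpson

    return (
        float(simpson(dA, x=theta)),
        float(simpson(J * dA, x=theta)),
        float(simpson(J**2 * dA, x=theta)),
    )
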