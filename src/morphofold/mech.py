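"""Morphoelastic neo-Hookean model and damped-dynamics steady-state solver.

The deformation gradient of each material point factors multiplicatively into
an elastic part and a prescribed growth part, ``F = Fe @ Fg``.  Growth
saturates in time with independent magnitudes along and transverse to the
reference surface normal ``N``::

    Fg(t) = I + lam_N * s(t) * N⊗N + lam_T * s(t) * (I - N⊗N),
    s(t)  = 1 - exp(-beta * t)

Only the elastic part stores energy.  The material is compressible
neo-Hookean with strain energy density::

    Psi = mu/2 * (tr(Fe Fe^T) * J^(-2/3) - 3) + K * (J - ln J - 1),  J = det Fe

whose Cauchy stress is ``sigma = mu * J^(-5/3) * dev(Fe Fe^T) + K*(1 - 1/J)*I``.
Moduli derive from Young's modulus and Poisson's ratio as
``mu = E / (2(1+nu))`` and ``K = E / (3(1-2nu))``.

The steady state is found by damped explicit dynamics (Newton's second law
with fictitious lumped unit nodal masses and viscous drag), ramping growth in
simulation time and then relaxing until the residual force vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from morphofold import _kernels
from morphofold.mesh import LayeredTetMesh

__all__ = [
    "ElasticConstants",
    "GrowthLaw",
    "SolverConfig",
    "SimState",
    "ElementInversionError",
    "ConvergenceError",
    "compute_moduli",
    "growth_tensor",
    "elastic_part",
    "strain_energy",
    "cauchy_stress",
    "first_piola",
    "assemble_internal_forces",
    "contact_forces",
    "relax_to_steady_state",
    "total_elastic_energy",
    "deformed_surface",
]

#: Poisson ratios above this are rejected: linear tetrahedra with a single
#: quadrature point lock near incompressibility.
NU_SOLVER_CAP = 0.45


class ElementInversionError(RuntimeError):
    """An element reached non-positive elastic volume (det Fe <= 0)."""

    def __init__(self, element: int):
        super().__init__(f"element {element} inverted (det Fe <= 0)")
        self.element = element


class ConvergenceError(RuntimeError):
    """The relaxation failed to reach the force tolerance within max_steps.

    Carries the residual ``history`` (step, time, residual, energy) and the
    last node ``positions`` for post-mortem inspection.
    """

    def __init__(self, message, history, positions=None):
        super().__init__(message)
        self.history = history
        self.positions = positions


def compute_moduli(E: float, nu: float) -> tuple[float, float]:
    """Shear and bulk moduli from Young's modulus and Poisson's ratio.

    ``mu = E / (2(1+nu))``, ``K = E / (3(1-2nu))``.
    """
    if E <= 0:
        raise ValueError(f"Young's modulus must be positive, got {E}")
    if not -1.0 < nu < 0.499:
        raise ValueError(
            f"Poisson's ratio {nu} outside the supported open interval "
            "(-1, 0.499); the incompressible limit nu -> 1/2 is singular"
        )
    mu = E / (2.0 * (1.0 + nu))
    K = E / (3.0 * (1.0 - 2.0 * nu))
    return mu, K


@dataclass(frozen=True)
class ElasticConstants:
    """Layer material constants; moduli in units of the dermis modulus."""

    E: float
    nu: float
    mu: float = field(init=False)
    K: float = field(init=False)

    def __post_init__(self):
        mu, K = compute_moduli(self.E, self.nu)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "K", K)


@dataclass(frozen=True)
class GrowthLaw:
    """Saturating growth magnitudes: final normal / tangential relative growth.

    ``lambda_N`` and ``lambda_T`` are the asymptotic relative growths along
    and transverse to the reference normal; ``beta`` sets the saturation rate
    (1/time, simulation units).
    """

    lambda_N: float = 0.0
    lambda_T: float = 0.0
    beta: float = 1.0

    def __post_init__(self):
        if self.lambda_N < 0 or self.lambda_T < 0:
            raise ValueError("growth magnitudes must be non-negative")
        if self.beta <= 0:
            raise ValueError("growth rate beta must be positive")

    def scale(self, t: float) -> float:
        """Saturation factor ``s(t) = 1 - exp(-beta t)``."""
        return -np.expm1(-self.beta * t)


def growth_tensor(g: GrowthLaw, N: np.ndarray, t: float) -> np.ndarray:
    """Growth deformation gradient Fg(t) for unit normal N.

    ``Fg = I + lam_N s N⊗N + lam_T s (I - N⊗N)``; symmetric positive
    definite, with tangential eigenvalue ``1 + lam_T s`` (twice) and normal
    eigenvalue ``1 + lam_N s``.
    """
    N = np.asarray(N, dtype=float)
    if not np.isclose(np.linalg.norm(N), 1.0, atol=1e-8):
        raise ValueError("N must be a unit vector")
    if t < 0:
        raise ValueError("time must be non-negative")
    s = g.scale(t)
    nn = np.outer(N, N)
    eye = np.eye(3)
    return eye + g.lambda_N * s * nn + g.lambda_T * s * (eye - nn)


def elastic_part(F: np.ndarray, Fg: np.ndarray) -> np.ndarray:
    """Elastic deformation gradient ``Fe = F @ Fg^{-1}`` (batched over leading dims)."""
    F = np.asarray(F, dtype=float)
    Fg = np.asarray(Fg, dtype=float)
    det = np.linalg.det(Fg)
    if np.any(det <= 0):
        raise ValueError("growth tensor must have positive determinant")
    return F @ np.linalg.inv(Fg)


def _det_and_check(Fe: np.ndarray) -> np.ndarray:
    J = np.linalg.det(np.asarray(Fe, dtype=float))
    if np.any(J <= 0):
        raise ValueError("inverted elastic state: det Fe <= 0")
    return J


def strain_energy(Fe: np.ndarray, mu, K) -> np.ndarray:
    """Neo-Hookean strain energy density (batched over leading dims)."""
    Fe = np.asarray(Fe, dtype=float)
    J = _det_and_check(Fe)
    I1 = np.einsum("...ij,...ij->...", Fe, Fe)
    return 0.5 * mu * (I1 * J ** (-2.0 / 3.0) - 3.0) + K * (J - np.log(J) - 1.0)


def cauchy_stress(Fe: np.ndarray, mu, K) -> np.ndarray:
    """Cauchy stress ``sigma = mu J^{-5/3} dev(Fe Fe^T) + K (1 - 1/J) I``."""
    Fe = np.asarray(Fe, dtype=float)
    J = _det_and_check(Fe)
    B = Fe @ np.swapaxes(Fe, -1, -2)
    tr = np.einsum("...ii->...", B)
    dev = B - (tr / 3.0)[..., None, None] * np.eye(3)
    mu = np.asarray(mu, dtype=float)
    K = np.asarray(K, dtype=float)
    vol = (K * (1.0 - 1.0 / J))[..., None, None] * np.eye(3)
    return (mu * J ** (-5.0 / 3.0))[..., None, None] * dev + vol


def first_piola(Fe: np.ndarray, mu, K) -> np.ndarray:
    """First Piola–Kirchhoff stress ``P = dPsi/dFe`` (batched)."""
    Fe = np.asarray(Fe, dtype=float)
    J = _det_and_check(Fe)
    I1 = np.einsum("...ij,...ij->...", Fe, Fe)
    FeinvT = np.swapaxes(np.linalg.inv(Fe), -1, -2)
    mu = np.asarray(mu, dtype=float)
    K = np.asarray(K, dtype=float)
    return (mu * J ** (-2.0 / 3.0))[..., None, None] * Fe + (
        K * (J - 1.0) - mu * J ** (-2.0 / 3.0) * I1 / 3.0
    )[..., None, None] * FeinvT


# ---------------------------------------------------------------------------
# solver


@dataclass
class SolverConfig:
    """Damped-dynamics solver controls.

    All quantities are in simulation units (dermis modulus = 1, growth rate
    beta = 1 unless overridden per layer).  ``time_step=None`` derives an
    explicit stability estimate from the stiffest node; ``force_tolerance=None``
    converges when the residual falls below ``rel_force_tolerance`` times the
    peak residual seen after the growth ramp.
    """

    time_step: float | None = None
    damping_coefficient: float = 1.0
    contact_stiffness: float | None = None
    contact_range: float | None = None
    force_tolerance: float | None = None
    max_steps: int = 400_000
    growth_ramp_end: float = 5.0
    rel_force_tolerance: float = 1e-3
    cfl: float = 0.25
    perturbation: float = 1e-4
    check_every: int = 20
    contact_rebuild: int = 25
    enable_contact: bool = True
    use_fire: bool = True  # adaptive inertial relaxation after the growth ramp
    fire_dt_max_factor: float = 20.0  # FIRE time-step ceiling over the base dt
    confirm_steps: int = 3000  # steps the residual must stay low before accepting
    progress_every: int = 0  # print a progress line every N steps (0 = silent)

    def __post_init__(self):
        for name in ("damping_coefficient", "rel_force_tolerance", "cfl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")
        if self.growth_ramp_end < 5.0:
            raise ValueError(
                "growth_ramp_end must be >= 5 (>= 99.3% of growth saturation)"
            )


@dataclass
class SimState:
    """Nodal and per-element state of a simulation snapshot."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float
    F: np.ndarray
    Fg: np.ndarray
    Fe: np.ndarray
    sigma: np.ndarray
    psi: np.ndarray
    J: np.ndarray
    residual: float = np.nan
    history: np.ndarray | None = None  # columns: step, time, residual


def _element_basis(mesh: LayeredTetMesh) -> tuple[np.ndarray, np.ndarray]:
    p = mesh.points[mesh.tets]
    Dm = np.swapaxes(p[:, 1:] - p[:, :1], -1, -2)  # columns = edge vectors
    V0 = np.linalg.det(Dm) / 6.0
    return np.linalg.inv(Dm), V0


def _per_element_params(mesh, materials, growth):
    lay = mesh.layer
    mu = np.empty(mesh.n_elements)
    K = np.empty(mesh.n_elements)
    lamN = np.empty(mesh.n_elements)
    lamT = np.empty(mesh.n_elements)
    beta = np.empty(mesh.n_elements)
    for code in np.unique(lay):
        mat = materials[code]
        if mat.nu > NU_SOLVER_CAP:
            raise ValueError(
                f"nu={mat.nu} > {NU_SOLVER_CAP}: near-incompressible materials "
                "are unsupported by the single-point linear-tet discretization"
            )
        g = growth[code] if growth is not None else GrowthLaw()
        sel = lay == code
        mu[sel] = mat.mu
        K[sel] = mat.K
        lamN[sel] = g.lambda_N
        lamT[sel] = g.lambda_T
        beta[sel] = g.beta
    return mu, K, lamN, lamT, beta


def compute_state(
    mesh: LayeredTetMesh,
    positions: np.ndarray,
    materials: dict,
    growth: dict | None,
    t: float,
    velocities: np.ndarray | None = None,
) -> SimState:
    """Full per-element kinematic and stress state at given node positions."""
    Bm, _ = _element_basis(mesh)
    mu, K, lamN, lamT, beta = _per_element_params(mesh, materials, growth)
    p = positions[mesh.tets]
    Ds = np.swapaxes(p[:, 1:] - p[:, :1], -1, -2)
    F = Ds @ Bm
    s = -np.expm1(-beta * t)
    nn = mesh.normals[:, :, None] * mesh.normals[:, None, :]
    eye = np.eye(3)
    Fg = eye + (lamN * s)[:, None, None] * nn + (lamT * s)[:, None, None] * (eye - nn)
    Fe = F @ np.linalg.inv(Fg)
    J = np.linalg.det(Fe)
    if np.any(J <= 0):
        raise ElementInversionError(int(np.argmax(J <= 0)))
    sigma = cauchy_stress(Fe, mu, K)
    psi = strain_energy(Fe, mu, K)
    if velocities is None:
        velocities = np.zeros_like(positions)
    return SimState(
        positions=positions,
        velocities=velocities,
        time=t,
        F=F,
        Fg=Fg,
        Fe=Fe,
        sigma=sigma,
        psi=psi,
        J=J,
    )


def assemble_internal_forces(
    mesh: LayeredTetMesh,
    positions: np.ndarray,
    materials: dict,
    growth: dict | None = None,
    t: float = 0.0,
) -> np.ndarray:
    """Elastic nodal forces (linear tets, one quadrature point per element).

    For a fully free body the net force and net torque vanish to rounding.
    Raises :class:`ElementInversionError` carrying the offending element if
    any element has ``det Fe <= 0``.
    """
    Bm, V0 = _element_basis(mesh)
    mu, K, lamN, lamT, beta = _per_element_params(mesh, materials, growth)
    s = -np.expm1(-beta * t)
    ga = 1.0 + lamN * s
    gb = 1.0 + lamT * s
    f = np.zeros_like(mesh.points)
    bad, _ = _kernels.internal_forces(
        np.ascontiguousarray(positions, dtype=np.float64),
        mesh.tets,
        np.ascontiguousarray(Bm),
        np.ascontiguousarray(V0),
        mesh.normals,
        ga,
        gb,
        mu,
        K,
        f,
    )
    if bad >= 0:
        raise ElementInversionError(bad)
    return f


def total_elastic_energy(
    mesh: LayeredTetMesh,
    positions: np.ndarray,
    materials: dict,
    growth: dict | None = None,
    t: float = 0.0,
) -> float:
    """Total stored elastic energy, integrating Psi over the grown volume."""
    state = compute_state(mesh, positions, materials, growth, t)
    _, V0 = _element_basis(mesh)
    Jg = np.linalg.det(state.Fg)
    return float(np.sum(state.psi * Jg * V0))


class _ContactTracker:
    """Maintains node–triangle candidate pairs for the penalty contact model.

    Candidates are rebuilt periodically with a kd-tree on triangle centroids.
    Pairs that are close already in the *reference* configuration (the node's
    own neighbourhood of the surface) are excluded, so the skin repels only
    genuinely approaching, non-neighbouring surface.
    """

    def __init__(self, mesh: LayeredTetMesh, crange: float):
        from scipy import sparse

        self.tris = mesh.surface_tris
        self.crange = crange
        self.surf_nodes = np.unique(self.tris)
        n = mesh.n_nodes
        m = len(self.tris)
        # node-node surface adjacency (incl. self)
        pairs = np.vstack(
            [
                self.tris[:, [0, 1]],
                self.tris[:, [1, 2]],
                self.tris[:, [2, 0]],
            ]
        )
        A = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        A = ((A + A.T + sparse.eye(n)) > 0).tocsr()
        ring2 = (A @ A) > 0
        # triangle incidence
        T = sparse.csr_matrix(
            (np.ones(3 * m), (self.tris.T.ravel(), np.tile(np.arange(m), 3))),
            shape=(n, m),
        )
        #: excluded[i, t] > 0 iff triangle t touches the two-ring of node i
        self.excluded = ((ring2 @ T) > 0).tocsr()
        self.cand_node = np.empty(0, dtype=np.int64)
        self.cand_tri = np.empty(0, dtype=np.int64)

    def rebuild(self, pos: np.ndarray) -> None:
        centroids = pos[self.tris].mean(axis=1)
        radii = np.linalg.norm(pos[self.tris] - centroids[:, None, :], axis=2).max(
            axis=1
        )
        # per-triangle search radius: its own size plus range and drift slack
        tree = cKDTree(pos[self.surf_nodes])
        hits = tree.query_ball_point(centroids, radii + 5.0 * self.crange)
        counts = np.fromiter((len(h) for h in hits), dtype=np.int64, count=len(hits))
        if counts.sum() == 0:
            self.cand_node = np.empty(0, dtype=np.int64)
            self.cand_tri = np.empty(0, dtype=np.int64)
            return
        tris = np.repeat(np.arange(len(self.tris)), counts)
        nodes = self.surf_nodes[
            np.concatenate([np.asarray(h, dtype=np.int64) for h in hits])
        ]
        keep = np.asarray(self.excluded[nodes, tris]).ravel() == 0
        self.cand_node = nodes[keep]
        self.cand_tri = tris[keep]

    def accumulate(self, pos: np.ndarray, stiffness: float, out_f: np.ndarray) -> int:
        if len(self.cand_node) == 0:
            return 0
        return _kernels.contact_forces(
            pos, self.tris, self.cand_node, self.cand_tri, stiffness, self.crange, out_f
        )


def contact_forces(
    mesh: LayeredTetMesh,
    positions: np.ndarray,
    config: SolverConfig,
) -> np.ndarray:
    """Penalty contact forces between non-neighbouring surface primitives."""
    crange, stiffness = _contact_defaults(mesh, config)
    tracker = _ContactTracker(mesh, crange)
    tracker.rebuild(positions)
    f = np.zeros_like(positions)
    tracker.accumulate(positions, stiffness, f)
    return f


def _contact_defaults(mesh, config):
    edges = mesh.edge_lengths()
    mean_edge = float(edges.mean())
    crange = (
        config.contact_range if config.contact_range is not None else 0.5 * mean_edge
    )
    stiffness = (
        config.contact_stiffness if config.contact_stiffness is not None else 10.0
    )
    return crange, stiffness


def relax_to_steady_state(
    mesh: LayeredTetMesh,
    materials: dict,
    growth: dict,
    config: SolverConfig | None = None,
    seed: int = 0,
    initial_positions: np.ndarray | None = None,
) -> SimState:
    """Quasi-static solve: ramp growth, then relax to force equilibrium.

    Damped explicit dynamics with lumped unit nodal masses integrate the
    growth ramp; at the end of the ramp a tiny seeded perturbation of the
    free nodes (``config.perturbation`` times the mean edge length) breaks
    the symmetry of bifurcating (wrinkling) solutions, and relaxation
    continues — by default with FIRE-style adaptive time stepping — until
    the residual force falls below tolerance. Raises
    :class:`ConvergenceError` if that never happens within ``max_steps``.
    """
    if config is None:
        config = SolverConfig()
    mesh.validate()
    Bm, V0 = _element_basis(mesh)
    mu, K, lamN, lamT, beta = _per_element_params(mesh, materials, growth)

    # explicit stability estimate: stiffest node vs unit nodal mass
    growth_factor = (1.0 + np.maximum(lamN, lamT)) ** 2
    k_el = (K + 4.0 * mu / 3.0) * growth_factor * np.cbrt(V0)
    k_node = np.zeros(mesh.n_nodes)
    np.add.at(k_node, mesh.tets.ravel(), np.repeat(k_el, 4))
    dt0 = (
        config.time_step
        if config.time_step is not None
        else config.cfl * 2.0 / np.sqrt(k_node.max())
    )
    dt = dt0
    gamma = config.damping_coefficient

    rng = np.random.default_rng(seed)
    mean_edge = float(mesh.edge_lengths().mean())
    pos = mesh.points.copy() if initial_positions is None else initial_positions.copy()
    free3 = mesh.free_dof_mask()
    vel = np.zeros_like(pos)

    tracker = None
    if config.enable_contact:
        crange, cstiff = _contact_defaults(mesh, config)
        tracker = _ContactTracker(mesh, crange)

    f = np.zeros_like(pos)
    t = 0.0
    ramp_end_t = config.growth_ramp_end / beta.min()
    peak_residual = 0.0
    history = []
    converged = False
    perturbed = False
    # FIRE state (post-ramp adaptive relaxation)
    fire_alpha = 0.1
    fire_npos = 0
    dt_max = config.fire_dt_max_factor * dt0
    pos_prev = pos.copy()
    residual = np.inf
    confirm_start = None
    for step in range(config.max_steps):
        t += dt
        s = -np.expm1(-beta * t)
        ga = 1.0 + lamN * s
        gb = 1.0 + lamT * s
        bad, energy = _kernels.internal_forces(
            pos, mesh.tets, Bm, V0, mesh.normals, ga, gb, mu, K, f
        )
        if bad >= 0:
            if perturbed and config.use_fire and dt > 1e-3 * dt0:
                # FIRE overshoot: backtrack and restart with a smaller step
                pos[:] = pos_prev
                vel[:] = 0.0
                dt *= 0.25
                fire_npos = 0
                fire_alpha = 0.1
                continue
            raise ElementInversionError(bad)
        if tracker is not None:
            if step % config.contact_rebuild == 0:
                tracker.rebuild(pos)
            tracker.accumulate(pos, cstiff, f)
        f[~free3] = 0.0
        residual = float(np.abs(f).max())

        if not perturbed and t >= ramp_end_t:
            # symmetry-breaking kick at the end of the growth ramp
            pos[free3] += config.perturbation * mean_edge * rng.standard_normal(
                int(free3.sum())
            )
            vel[:] = 0.0
            perturbed = True
            continue

        pos_prev[:] = pos
        if perturbed and config.use_fire:
            power = float(np.sum(f * vel))
            if power > 0.0:
                fire_npos += 1
                if fire_npos > 5:
                    dt = min(dt * 1.1, dt_max)
                    fire_alpha *= 0.99
                fnorm = float(np.linalg.norm(f))
                vnorm = float(np.linalg.norm(vel))
                if fnorm > 0.0:
                    vel = (1.0 - fire_alpha) * vel + fire_alpha * (vnorm / fnorm) * f
            else:
                fire_npos = 0
                dt = max(dt * 0.5, 0.02 * dt0)
                fire_alpha = 0.1
                vel[:] = 0.0
            vel += dt * f
            # cap nodal displacement per step for robustness at large dt
            vmax = float(np.abs(vel).max())
            cap = 0.05 * mean_edge
            if vmax * dt > cap:
                vel *= cap / (vmax * dt)
            vel[~free3] = 0.0
            pos += dt * vel
        else:
            vel = (vel + dt * f) / (1.0 + gamma * dt)
            vel[~free3] = 0.0
            pos += dt * vel

        if config.progress_every and step % config.progress_every == 0:
            import sys

            print(
                f"  step {step} t={t:.1f} dt={dt:.2e} res={residual:.3e} "
                f"E={energy:.6e}",
                file=sys.stderr,
                flush=True,
            )
        if perturbed:
            peak_residual = max(peak_residual, residual)
            if step % config.check_every == 0:
                history.append((step, t, residual, energy))
                tol = (
                    config.force_tolerance
                    if config.force_tolerance is not None
                    else max(config.rel_force_tolerance * peak_residual, 1e-12)
                )
                if residual < tol:
                    if confirm_start is None:
                        confirm_start = step
                    elif step - confirm_start >= config.confirm_steps:
                        # residual stayed at tolerance long enough: no slowly
                        # growing instability is hiding below it
                        converged = True
                        break
                elif confirm_start is not None and residual > 3.0 * tol:
                    confirm_start = None  # a mode was still growing; keep going
    if not converged:
        hist = np.asarray(history)
        raise ConvergenceError(
            f"no convergence in {config.max_steps} steps "
            f"(last residual {residual:.3e})",
            hist,
            positions=pos,
        )
    state = compute_state(mesh, pos, materials, growth, t, velocities=vel)
    state.residual = residual
    state.history = np.asarray(history)
    return state


def deformed_surface(mesh: LayeredTetMesh, state_or_positions) -> "trimesh.Trimesh":
    """Deformed boundary surface as a trimesh (outward oriented)."""
    import trimesh

    pos = getattr(state_or_positions, "positions", state_or_positions)
    return trimesh.Trimesh(
        vertices=np.asarray(pos, dtype=float),
        faces=mesh.surface_tris,
        process=False,
    )
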