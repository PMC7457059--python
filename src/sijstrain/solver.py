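"""Static equilibrium of the two free rigid bodies by energy minimization.

The configuration is a 12-vector: translation (mm) and rotation vector
(rad) for the sacrum, then the same for the first caudal vertebra.  Total
potential energy is

    sum of spring energies (tension-only)
    + sacrocaudal joint energy (compression-only)
    + SIJ compression-penalty energy
    + grounding-regularization energy
    - work of the applied dead load at the load point,

which is exactly zero at the reference pose under zero load.  The energy is
C1 (forces are continuous across stiffness-band boundaries) but only
piecewise C2, so a quasi-Newton minimizer (L-BFGS-B with analytic
gradients) is used, followed by a Newton polish on the gradient with a
finite-difference Hessian; away from band boundaries the energy is locally
smooth and the polish drives the residual to near machine precision.

A tiny isotropic spring grounds each free body (default 1e-6 N/mm) so the
pose stays determinate even when every tension-only element is slack; a
warning is emitted if its energy is not negligible at convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .assembly import Attachment, Model

__all__ = [
    "LoadScenario",
    "SolverOptions",
    "EquilibriumResult",
    "SolverError",
    "potential_energy",
    "potential_energy_gradient",
    "solve_static",
    "element_strain",
    "net_loads",
]

_BODIES = ("sacrum", "c1")
_NDOF = 12


class SolverError(RuntimeError):
    """Mechanism-level failure (unbounded drift or excessive rotation)."""


@dataclass(frozen=True)
class LoadScenario:
    """A dead (direction-fixed) force applied at the sacral load point.

    Forces in N; x is lateral (right positive), y dorsal, z cranial (always
    zero in the standard battery).
    """

    id: int
    fx: float
    fy: float
    fz: float = 0.0

    @property
    def force(self) -> np.ndarray:
        return np.array([self.fx, self.fy, self.fz], dtype=float)


@dataclass(frozen=True)
class SolverOptions:
    grad_tol: float = 1.0e-6  # N (mixed N / N*mm gradient norm)
    max_iter: int = 2000
    newton_polish: bool = True
    rotation_guard: float = 0.5  # rad
    translation_guard: float = 100.0  # mm
    reg_rho: float = 50.0  # mm; rotational arm of the grounding spring


@dataclass
class EquilibriumResult:
    converged: bool
    pose: np.ndarray  # (12,)
    spring_strain: dict[str, float]
    spring_force: dict[str, float]
    joint_gap_strain: float  # signed: positive = compression
    gradient_norm: float
    energy: float
    n_iter: int
    scenario: LoadScenario

    def pose_of(self, body: str) -> tuple[np.ndarray, np.ndarray]:
        i = _BODIES.index(body) * 6
        return self.pose[i : i + 3], self.pose[i + 3 : i + 6]


# --------------------------------------------------------------------------
# Rotation helpers (rotation-vector parameterization)
# --------------------------------------------------------------------------

def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


def _rotation_matrix(theta: np.ndarray) -> np.ndarray:
    """Rodrigues formula with a series fallback near zero angle."""
    t = float(np.linalg.norm(theta))
    K = _skew(theta)
    if t < 1.0e-8:
        return np.eye(3) + K + 0.5 * (K @ K)
    return (
        np.eye(3)
        + (np.sin(t) / t) * K
        + ((1.0 - np.cos(t)) / t**2) * (K @ K)
    )


def _right_jacobian(theta: np.ndarray) -> np.ndarray:
    """Right Jacobian J_r of SO(3): exp(theta + d) = exp(theta) exp(J_r d)."""
    t = float(np.linalg.norm(theta))
    K = _skew(theta)
    if t < 1.0e-8:
        return np.eye(3) - 0.5 * K + (1.0 / 6.0) * (K @ K)
    return (
        np.eye(3)
        - ((1.0 - np.cos(t)) / t**2) * K
        + ((t - np.sin(t)) / t**3) * (K @ K)
    )


class _Kinematics:
    """World positions of body-attached points for a given pose vector."""

    def __init__(self, model: Model, x: np.ndarray):
        x = np.asarray(x, dtype=float).reshape(_NDOF)
        self.model = model
        self.t = {b: x[i * 6 : i * 6 + 3] for i, b in enumerate(_BODIES)}
        self.theta = {b: x[i * 6 + 3 : i * 6 + 6] for i, b in enumerate(_BODIES)}
        self.R = {b: _rotation_matrix(self.theta[b]) for b in _BODIES}
        self.Jr = {b: _right_jacobian(self.theta[b]) for b in _BODIES}
        self.origin = {
            b: np.asarray(model.bodies[b].origin, dtype=float) for b in _BODIES
        }

    def world(self, att: Attachment) -> np.ndarray:
        p = np.asarray(att.point, dtype=float)
        if att.body == "world":
            return p
        o = self.origin[att.body]
        return o + self.t[att.body] + self.R[att.body] @ (p - o)

    def accumulate(self, att: Attachment, dE_dp: np.ndarray, grad: np.ndarray) -> None:
        """Add the contribution of dE/d(point) to the pose gradient."""
        if att.body == "world":
            return
        i = _BODIES.index(att.body) * 6
        grad[i : i + 3] += dE_dp
        p_local = np.asarray(att.point, dtype=float) - self.origin[att.body]
        # d(R p)/d(theta) = -R [p]_x J_r
        dp_dtheta = -self.R[att.body] @ _skew(p_local) @ self.Jr[att.body]
        grad[i + 3 : i + 6] += dE_dp @ dp_dtheta


# --------------------------------------------------------------------------
# Energy and gradient
# --------------------------------------------------------------------------

class _SpringArrays:
    """Vectorized spring data: endpoint body indices, local coords, rest lengths.

    Body index 0 is the fixed world; 1 and 2 are the free bodies in
    ``_BODIES`` order.  Cached on the model (springs are immutable after
    assembly).
    """

    def __init__(self, model: Model):
        n = len(model.springs)
        self.body_a = np.zeros(n, dtype=int)
        self.body_b = np.zeros(n, dtype=int)
        self.pt_a = np.zeros((n, 3))
        self.pt_b = np.zeros((n, 3))
        self.rest = np.zeros(n)
        self.sij = np.zeros(n, dtype=bool)
        for i, s in enumerate(model.springs):
            for (att, body_arr, pt_arr) in (
                (s.end_a, self.body_a, self.pt_a),
                (s.end_b, self.body_b, self.pt_b),
            ):
                body_arr[i] = 0 if att.body == "world" else 1 + _BODIES.index(att.body)
                pt_arr[i] = att.point
            self.rest[i] = s.rest_length
            self.sij[i] = s.group == "sij"
        self.law = model.springs[0].law
        if any(s.law is not self.law for s in model.springs):
            raise ValueError("all springs must share one ligament law")


def _spring_arrays(model: Model) -> _SpringArrays:
    cache = model.__dict__.get("_spring_cache")
    if cache is None or cache[0] is not model.springs:
        cache = (model.springs, _SpringArrays(model))
        model.__dict__["_spring_cache"] = cache
    return cache[1]


def _energy_terms(model: Model, kin: _Kinematics, scenario: LoadScenario,
                  opts: SolverOptions, grad: np.ndarray | None):
    """Total energy; optionally accumulates the analytic gradient in place."""
    E = 0.0
    E_reg = 0.0
    pen_k = model.sij_penalty_stiffness
    sa = _spring_arrays(model)

    # world positions of every spring endpoint (batch rigid transform)
    def positions(body_idx, pts):
        out = pts.copy()
        for bi, b in enumerate(_BODIES, start=1):
            m = body_idx == bi
            if m.any():
                o = kin.origin[b]
                out[m] = o + kin.t[b] + (pts[m] - o) @ kin.R[b].T
        return out

    pa = positions(sa.body_a, sa.pt_a)
    pb = positions(sa.body_b, sa.pt_b)
    d = pb - pa
    L = np.linalg.norm(d, axis=1)
    strain = (L - sa.rest) / sa.rest
    E += float(np.sum(sa.law.energy(strain, sa.rest)))
    dE_dL = np.asarray(sa.law.force(strain, sa.rest), dtype=float)
    if pen_k > 0:
        comp = np.where(sa.sij & (L < sa.rest), sa.rest - L, 0.0)
        E += 0.5 * pen_k * float(np.sum(comp**2))
        dE_dL -= pen_k * comp
    if grad is not None:
        u = d / L[:, None]
        f_pts = dE_dL[:, None] * u  # dE/d(pb); dE/d(pa) is the negative
        for sign, body_idx, pts, gp in (
            (1.0, sa.body_b, sa.pt_b, f_pts),
            (-1.0, sa.body_a, sa.pt_a, f_pts),
        ):
            for bi, b in enumerate(_BODIES, start=1):
                m = body_idx == bi
                if not m.any():
                    continue
                gsel = sign * gp[m]
                i = (bi - 1) * 6
                grad[i : i + 3] += gsel.sum(axis=0)
                # dE/dtheta = -Jr^T sum_i (R^T dE/dp_i) x p_local_i
                q = gsel @ kin.R[b]
                p_local = pts[m] - kin.origin[b]
                s_vec = np.cross(q, p_local).sum(axis=0)
                grad[i + 3 : i + 6] += -(kin.Jr[b].T @ s_vec)

    j = model.joint
    pa = kin.world(j.face_sacrum)
    pb = kin.world(j.face_c1)
    d = pb - pa
    g = float(np.linalg.norm(d))
    eps = (j.rest_thickness - g) / j.rest_thickness  # >0 in compression
    E += j.area * j.rest_thickness * j.law.energy_density(eps)
    if grad is not None and eps > 0:
        dE_dg = -j.area * float(j.law.stress(eps))
        u = d / g
        kin.accumulate(j.face_sacrum, -dE_dg * u, grad)
        kin.accumulate(j.face_c1, dE_dg * u, grad)

    k_reg = model.regularization_stiffness
    if k_reg > 0:
        rho2 = opts.reg_rho**2
        for i, b in enumerate(_BODIES):
            t = kin.t[b]
            th = kin.theta[b]
            E_reg += 0.5 * k_reg * (t @ t + rho2 * (th @ th))
            if grad is not None:
                grad[i * 6 : i * 6 + 3] += k_reg * t
                grad[i * 6 + 3 : i * 6 + 6] += k_reg * rho2 * th
    E += E_reg

    F = scenario.force
    if np.any(F != 0.0):
        p_load = kin.world(model.load_point)
        p_ref = np.asarray(model.load_point.point, dtype=float)
        E -= float(F @ (p_load - p_ref))
        if grad is not None:
            kin.accumulate(model.load_point, -F, grad)

    return E, E_reg


def potential_energy(model: Model, pose, scenario: LoadScenario,
                     opts: SolverOptions | None = None) -> float:
    """Total potential energy (N*mm) of the model at the given pose."""
    opts = opts or SolverOptions()
    kin = _Kinematics(model, pose)
    E, _ = _energy_terms(model, kin, scenario, opts, None)
    return E


def potential_energy_gradient(model: Model, pose, scenario: LoadScenario,
                              opts: SolverOptions | None = None) -> np.ndarray:
    """Analytic gradient of the potential energy w.r.t. the 12 pose DOFs."""
    opts = opts or SolverOptions()
    kin = _Kinematics(model, pose)
    grad = np.zeros(_NDOF)
    _energy_terms(model, kin, scenario, opts, grad)
    return grad


def _value_and_grad(model, scenario, opts):
    def fun(x):
        kin = _Kinematics(model, x)
        grad = np.zeros(_NDOF)
        E, _ = _energy_terms(model, kin, scenario, opts, grad)
        return E, grad

    return fun


# --------------------------------------------------------------------------
# Solve
# --------------------------------------------------------------------------

def _newton_polish(fun_grad, x, tol, max_steps=60):
    """Damped Newton iteration on the gradient with an FD Hessian.

    The energy is smooth away from stiffness-band boundaries, so this
    converges quadratically and pushes the gradient norm far below what the
    quasi-Newton stage achieves.
    """
    h = 1.0e-6
    g = fun_grad(x)
    for it in range(max_steps):
        gn = float(np.linalg.norm(g))
        if gn <= tol:
            return x, g, it
        H = np.empty((_NDOF, _NDOF))
        for k in range(_NDOF):
            dx = np.zeros(_NDOF)
            dx[k] = h
            H[:, k] = (fun_grad(x + dx) - fun_grad(x - dx)) / (2.0 * h)
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(H, -g, rcond=None)
        # backtracking on the gradient norm
        alpha = 1.0
        for _ in range(30):
            x_new = x + alpha * step
            g_new = fun_grad(x_new)
            if np.linalg.norm(g_new) < gn:
                x, g = x_new, g_new
                break
            alpha *= 0.5
        else:
            return x, g, it  # no further progress possible
    return x, g, max_steps


def solve_static(
    model: Model,
    scenario: LoadScenario,
    opts: SolverOptions | None = None,
) -> EquilibriumResult:
    """Find the static equilibrium pose under the scenario's dead load.

    Minimizes total potential energy from the reference pose with L-BFGS-B
    (analytic gradient), then polishes with damped Newton until the
    gradient norm is below ``opts.grad_tol``.  Deterministic for fixed
    inputs.  Raises :class:`SolverError` if the solution drifts beyond the
    translation/rotation guards (a mechanism rather than a supported
    structure); returns ``converged=False`` (with diagnostics) if the
    tolerance is not reached.
    """
    opts = opts or SolverOptions()
    fun = _value_and_grad(model, scenario, opts)
    grad_only = lambda x: fun(x)[1]

    x0 = np.zeros(_NDOF)
    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": opts.max_iter,
            "ftol": 1.0e-18,
            "gtol": 1.0e-12,
            "maxcor": 30,
        },
    )
    x = res.x
    n_iter = int(res.nit)
    g = grad_only(x)
    if opts.newton_polish and np.linalg.norm(g) > opts.grad_tol * 1.0e-4:
        x, g, polish_iters = _newton_polish(grad_only, x, opts.grad_tol * 1.0e-4)
        n_iter += polish_iters

    for i, b in enumerate(_BODIES):
        t = x[i * 6 : i * 6 + 3]
        th = x[i * 6 + 3 : i * 6 + 6]
        if np.linalg.norm(th) > opts.rotation_guard:
            raise SolverError(
                f"{b} rotation {np.linalg.norm(th):.3f} rad exceeds the "
                f"{opts.rotation_guard} rad guard (scenario {scenario.id})"
            )
        if np.linalg.norm(t) > opts.translation_guard:
            raise SolverError(
                f"{b} translation {np.linalg.norm(t):.1f} mm exceeds the "
                f"{opts.translation_guard} mm guard (scenario {scenario.id}): "
                "the model is behaving as a mechanism"
            )

    kin = _Kinematics(model, x)
    E, E_reg = _energy_terms(model, kin, scenario, opts, None)
    elastic = E + float(scenario.force @ (kin.world(model.load_point)
                                          - np.asarray(model.load_point.point)))
    if E_reg > 1.0e-6 * max(abs(elastic), 1.0e-9) and E_reg > 1.0e-12:
        warnings.warn(
            f"grounding-spring energy {E_reg:.3e} N*mm is not negligible "
            f"(elastic {elastic:.3e}); pose may be regularization-dominated",
            stacklevel=2,
        )

    strains: dict[str, float] = {}
    forces: dict[str, float] = {}
    for s in model.springs:
        L = float(np.linalg.norm(kin.world(s.end_b) - kin.world(s.end_a)))
        strain = (L - s.rest_length) / s.rest_length
        strains[s.name] = strain
        forces[s.name] = float(s.law.force(strain, s.rest_length))
    jgap = float(
        np.linalg.norm(kin.world(model.joint.face_c1) - kin.world(model.joint.face_sacrum))
    )
    joint_eps = (model.joint.rest_thickness - jgap) / model.joint.rest_thickness

    gn = float(np.linalg.norm(g))
    return EquilibriumResult(
        converged=gn <= opts.grad_tol,
        pose=x,
        spring_strain=strains,
        spring_force=forces,
        joint_gap_strain=joint_eps,
        gradient_norm=gn,
        energy=E,
        n_iter=n_iter,
        scenario=scenario,
    )


def element_strain(model: Model, element_name: str, pose) -> float:
    """Engineering strain of a named spring (or 'joint') at a given pose."""
    kin = _Kinematics(model, pose)
    if element_name == "joint":
        g = float(
            np.linalg.norm(kin.world(model.joint.face_c1) - kin.world(model.joint.face_sacrum))
        )
        return (model.joint.rest_thickness - g) / model.joint.rest_thickness
    for s in model.springs:
        if s.name == element_name:
            L = float(np.linalg.norm(kin.world(s.end_b) - kin.world(s.end_a)))
            return (L - s.rest_length) / s.rest_length
    raise KeyError(f"no element named {element_name!r}")


def net_loads(model: Model, result: EquilibriumResult,
              opts: SolverOptions | None = None) -> dict[str, dict[str, np.ndarray]]:
    """Net force (N) and moment (N*mm, about the body origin) on each body.

    Sums spring, joint, penalty, regularization and applied forces acting
    on each free body at the equilibrium pose.  At a converged solution
    both should vanish to tolerance.  (Tests verify this with their own
    independent summation; this helper is for diagnostics.)
    """
    opts = opts or SolverOptions()
    kin = _Kinematics(model, result.pose)
    out = {b: {"force": np.zeros(3), "moment": np.zeros(3)} for b in _BODIES}

    def apply(att: Attachment, f: np.ndarray) -> None:
        if att.body == "world":
            return
        p = kin.world(att)
        arm = p - (kin.origin[att.body] + kin.t[att.body])
        out[att.body]["force"] += f
        out[att.body]["moment"] += np.cross(arm, f)

    pen_k = model.sij_penalty_stiffness
    for s in model.springs:
        pa, pb = kin.world(s.end_a), kin.world(s.end_b)
        d = pb - pa
        L = float(np.linalg.norm(d))
        u = d / L
        f = float(s.law.force((L - s.rest_length) / s.rest_length, s.rest_length))
        if pen_k > 0 and s.group == "sij" and L < s.rest_length:
            f += -pen_k * (s.rest_length - L)
        apply(s.end_a, f * u)   # pulled towards b when f > 0
        apply(s.end_b, -f * u)

    jm = model.joint
    pa, pb = kin.world(jm.face_sacrum), kin.world(jm.face_c1)
    d = pb - pa
    g = float(np.linalg.norm(d))
    eps = (jm.rest_thickness - g) / jm.rest_thickness
    if eps > 0:
        fj = jm.area * float(jm.law.stress(eps))  # pushes the faces apart
        u = d / g
        apply(jm.face_sacrum, -fj * u)
        apply(jm.face_c1, fj * u)

    k_reg = model.regularization_stiffness
    rho2 = opts.reg_rho**2
    for i, b in enumerate(_BODIES):
        out[b]["force"] += -k_reg * kin.t[b]
        out[b]["moment"] += -k_reg * rho2 * kin.theta[b]

    apply(model.load_point, result.scenario.force)
    return out
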