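"""Quasi-static equilibrium by total-potential-energy minimization.

Each free segment carries up to six rigid-body coordinates (3 translations
in mm, 3 exponential-map rotation parameters in radians) about its build
frame origin.  The total potential is the sum of

* element strain energies — exact integrals of the tension-only force laws
  (``L0 * a * (expm1(b*eps)/b - eps)`` for the exponential law, quadratic
  for linear laws and graft limbs), with muscles contributing the work
  potential ``F * (L - L_build)`` of their constant force;
* compression-only foundation energies at the contact patches (plane,
  sphere or cylinder support surfaces; frictionless, so the energy depends
  only on normal penetration);
* the external-load potential of the vertical axial load on the tibia.

Because every tie is tension-only and every contact one-sided, the load
potential is unbounded below far from the assembled configuration: the
physical equilibrium is a *local* minimum.  The solver therefore tracks the
equilibrium branch with load continuation (warm-started load increments)
and minimizes each increment with a trust-region damped-Newton method
(finite-difference Hessian of the analytic gradient, step-size control,
energy-decrease guard) that cannot leave the physical basin.  Convergence
is declared on the physical residual: net force per free segment and net
torque scaled by a characteristic length.  Everything is deterministic for
a fixed model and start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assembly import ContactPair, FootModel, Segment

__all__ = [
    "SolverSettings",
    "EquilibriumResult",
    "build_pose",
    "potential_energy",
    "energy_and_gradient",
    "segment_loads",
    "residual_norm",
    "solve_equilibrium",
    "rotation_matrix",
    "left_jacobian",
]

_LAW_EXP, _LAW_LINEAR, _LAW_MUSCLE = 0, 1, 2


# ---------------------------------------------------------------------------
# SO(3) helpers (exponential map)
# ---------------------------------------------------------------------------


def _hat(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])


def rotation_matrix(phi: np.ndarray) -> np.ndarray:
    """Rodrigues rotation for an exponential-map vector ``phi`` (radians)."""
    theta = float(np.linalg.norm(phi))
    K = _hat(phi)
    if theta < 1e-8:
        return np.eye(3) + K + 0.5 * (K @ K)
    s = math.sin(theta) / theta
    c = (1.0 - math.cos(theta)) / (theta * theta)
    return np.eye(3) + s * K + c * (K @ K)


def left_jacobian(phi: np.ndarray) -> np.ndarray:
    """Left Jacobian of SO(3): maps rates of ``phi`` to spatial angular velocity."""
    theta = float(np.linalg.norm(phi))
    K = _hat(phi)
    if theta < 1e-8:
        return np.eye(3) + 0.5 * K + (K @ K) / 6.0
    a = (1.0 - math.cos(theta)) / (theta * theta)
    b = (theta - math.sin(theta)) / (theta**3)
    return np.eye(3) + a * K + b * (K @ K)


# ---------------------------------------------------------------------------
# assembled arrays (cached per model instance)
# ---------------------------------------------------------------------------


class _Assembled:
    """Flat array view of a FootModel for fast energy/gradient evaluation."""

    def __init__(self, model: FootModel):
        from .constitutive import ExpLawParams, GraftParams, LigamentSpec

        self.model = model
        self.seg_names = list(model.segments.keys())
        self.seg_index = {n: i for i, n in enumerate(self.seg_names)}
        self.nseg = len(self.seg_names)
        self.origins = np.array([model.segments[n].origin for n in self.seg_names])

        # dof packing
        self.dof_index = np.full((self.nseg, 6), -1, dtype=int)
        n = 0
        for i, name in enumerate(self.seg_names):
            for k, free in enumerate(model.segments[name].free_dofs):
                if free:
                    self.dof_index[i, k] = n
                    n += 1
        self.ndof = n

        # element route points / legs
        pt_seg, pt_local = [], []
        leg_start, leg_end, leg_elem = [], [], []
        el_first_leg = []
        law_type, p1, p2, L0 = [], [], [], []
        nleg = 0
        for ei, el in enumerate(model.elements):
            base = len(pt_seg)
            for rp in el.route:
                pt_seg.append(self.seg_index[rp.segment])
                pt_local.append(rp.local)
            el_first_leg.append(nleg)
            for j in range(len(el.route) - 1):
                leg_start.append(base + j)
                leg_end.append(base + j + 1)
                leg_elem.append(ei)
                nleg += 1
            spec = el.spec
            if el.kind == "muscle":
                law_type.append(_LAW_MUSCLE)
                p1.append(spec.constant_force)
                p2.append(0.0)
            elif el.kind == "graft":
                law_type.append(_LAW_LINEAR)
                p1.append(spec.elastic_modulus * spec.area / spec.slack_length)
                p2.append(0.0)
            else:  # ligament
                eff = spec.effective_law
                if isinstance(eff, ExpLawParams):
                    law_type.append(_LAW_EXP)
                    p1.append(eff.a)
                    p2.append(eff.b)
                else:
                    law_type.append(_LAW_LINEAR)
                    p1.append(eff.k)
                    p2.append(0.0)
            L0.append(el.slack_length)
        self.pt_seg = np.array(pt_seg, dtype=int)
        self.pt_local = (
            np.array(pt_local) if pt_local else np.zeros((0, 3))
        )
        self.leg_start = np.array(leg_start, dtype=int)
        self.leg_end = np.array(leg_end, dtype=int)
        self.leg_elem = np.array(leg_elem, dtype=int)
        self.el_first_leg = np.array(el_first_leg, dtype=int)
        self.law_type = np.array(law_type, dtype=int)
        self.p1 = np.array(p1)
        self.p2 = np.array(p2)
        self.L0 = np.array(L0)
        self.slack_reg = np.array([el.slack_reg for el in model.elements])
        self.is_exp = self.law_type == _LAW_EXP
        self.is_lin = self.law_type == _LAW_LINEAR
        self.is_mus = self.law_type == _LAW_MUSCLE
        # per-segment point index lists
        self.seg_points = [np.flatnonzero(self.pt_seg == i) for i in range(self.nseg)]

        # contact patches
        self.patch_data = []
        for pair in model.contact_pairs:
            patch = pair.patch
            ia = self.seg_index[patch.point_segment]
            locs = patch.points - self.origins[ia]
            if patch.surface_segment == "ground":
                ib = -1
                surf_local = patch.surface.point
            else:
                ib = self.seg_index[patch.surface_segment]
                surf_local = patch.surface.point - self.origins[ib]
            self.patch_data.append((pair, ia, ib, locs, surf_local))

        lc = model.load_case
        self.load_seg = self.seg_index[lc.segment]
        self.load_vec = float(lc.axial_load) * np.asarray(lc.direction, dtype=float)

    # -- kinematics ---------------------------------------------------------

    def states(self, x: np.ndarray):
        R = np.empty((self.nseg, 3, 3))
        t = np.empty((self.nseg, 3))
        phi = np.empty((self.nseg, 3))
        for i in range(self.nseg):
            q = np.zeros(6)
            idx = self.dof_index[i]
            for k in range(6):
                if idx[k] >= 0:
                    q[k] = x[idx[k]]
            t[i] = q[:3]
            phi[i] = q[3:]
            R[i] = rotation_matrix(phi[i])
        return R, t, phi

    def element_points(self, R, t):
        P = np.empty((len(self.pt_seg), 3))
        for i in range(self.nseg):
            idx = self.seg_points[i]
            if len(idx):
                P[idx] = self.pt_local[idx] @ R[i].T + self.origins[i] + t[i]
        return P

    def element_lengths_tensions(self, P):
        legs = P[self.leg_end] - P[self.leg_start]
        lens = np.linalg.norm(legs, axis=1)
        L = np.zeros(len(self.law_type))
        np.add.at(L, self.leg_elem, lens)
        dl = L - self.L0
        # slack-activation smoothing (see assembly.ELEMENT_SLACK_REG_MM)
        r = self.slack_reg
        smooth = (r > 0) & (dl < r)
        s = np.where(smooth, dl * dl / (2.0 * np.maximum(r, 1e-300)), dl - 0.5 * r)
        sp = np.where(smooth, dl / np.maximum(r, 1e-300), 1.0)
        T = np.zeros_like(L)
        V = np.zeros_like(L)
        m = self.is_exp & (dl > 0)
        if np.any(m):
            eps = s[m] / self.L0[m]
            be = self.p2[m] * eps
            T[m] = self.p1[m] * np.expm1(be) * sp[m]
            V[m] = self.L0[m] * self.p1[m] * (np.expm1(be) / self.p2[m] - eps)
        m = self.is_lin & (dl > 0)
        if np.any(m):
            T[m] = self.p1[m] * s[m] * sp[m]
            V[m] = 0.5 * self.p1[m] * s[m] ** 2
        m = self.is_mus
        if np.any(m):
            T[m] = self.p1[m]
            V[m] = self.p1[m] * dl[m]
        return legs, lens, L, T, V

    def contact_eval(self, pair_data, R, t):
        pair, ia, ib, locs, surf_local = pair_data
        patch = pair.patch
        P = locs @ R[ia].T + self.origins[ia] + t[ia]
        surf = patch.surface
        if ib < 0:
            q, n = surf.point, surf.normal
        else:
            q = self.origins[ib] + t[ib] + R[ib] @ surf_local
            n = R[ib] @ surf.normal
        if surf.kind == "plane":
            gap = (P - q) @ n
            delta = np.maximum(0.0, -gap)
            dirs = np.broadcast_to(n, P.shape)
        elif surf.kind == "sphere":
            w = P - q
            d = np.maximum(np.linalg.norm(w, axis=1), 1e-12)
            delta = np.maximum(0.0, surf.radius - d)
            dirs = w / d[:, None]
        else:  # cylinder with axis n
            w = P - q
            wpar = np.outer(w @ n, n)
            wperp = w - wpar
            d = np.maximum(np.linalg.norm(wperp, axis=1), 1e-12)
            delta = np.maximum(0.0, surf.radius - d)
            dirs = wperp / d[:, None]
        return P, delta, dirs, q, n


def _assembled(model: FootModel) -> _Assembled:
    cache = model.__dict__.get("_assembled")
    if cache is None:
        cache = _Assembled(model)
        model.__dict__["_assembled"] = cache
    return cache


def build_pose(model: FootModel) -> np.ndarray:
    """The build (neutral) pose vector: all coordinates zero."""
    return np.zeros(_assembled(model).ndof)


def _smoothed(f, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Regularized penetration s(d) and its slope (activation smoothing)."""
    s = np.where(d >= f.reg, d - 0.5 * f.reg, d * d / (2.0 * f.reg))
    sp = np.where(d >= f.reg, 1.0, d / f.reg)
    return s, sp


def _pressures(pair: ContactPair, delta: np.ndarray) -> np.ndarray:
    f = pair.foundation
    p = np.zeros_like(delta)
    m = delta > 0
    if np.any(m):
        s, sp = _smoothed(f, delta[m])
        if f.kind == "linear":
            p[m] = f.stiffness * s * sp
        else:
            p[m] = f.p0 * np.expm1(s / f.d0) * sp
    return p


def _pressure_energies(pair: ContactPair, delta: np.ndarray) -> np.ndarray:
    f = pair.foundation
    e = np.zeros_like(delta)
    m = delta > 0
    if np.any(m):
        s, _ = _smoothed(f, delta[m])
        if f.kind == "linear":
            e[m] = 0.5 * f.stiffness * s * s
        else:
            e[m] = f.p0 * (f.d0 * np.expm1(s / f.d0) - s)
    return e


# ---------------------------------------------------------------------------
# energy and gradient
# ---------------------------------------------------------------------------


def energy_and_gradient(model: FootModel, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Total potential energy (N mm) and its analytic gradient at pose ``x``."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("pose vector must be finite")
    asm = _assembled(model)
    R, t, phi = asm.states(x)
    centers = asm.origins + t

    V = 0.0
    g_trans = np.zeros((asm.nseg, 3))
    g_rot = np.zeros((asm.nseg, 3))

    # --- line elements ---
    P = asm.element_points(R, t)
    legs, lens, L, T, Vel = asm.element_lengths_tensions(P)
    V += float(Vel.sum())
    Tleg = T[asm.leg_elem]
    nz = Tleg != 0.0
    if np.any(nz):
        units = legs[nz] / np.maximum(lens[nz], 1e-12)[:, None]
        G = np.zeros((len(asm.pt_seg), 3))
        f_leg = Tleg[nz, None] * units
        np.add.at(G, asm.leg_start[nz], -f_leg)
        np.add.at(G, asm.leg_end[nz], f_leg)
        for i in range(asm.nseg):
            idx = asm.seg_points[i]
            if len(idx):
                Gi = G[idx]
                g_trans[i] += Gi.sum(axis=0)
                g_rot[i] += np.cross(P[idx] - centers[i], Gi).sum(axis=0)

    # --- contact ---
    for pair_data in asm.patch_data:
        pair, ia, ib, _, _ = pair_data
        patch = pair.patch
        Pc, delta, dirs, q, n = asm.contact_eval(pair_data, R, t)
        if not np.any(delta > 0.0):
            continue
        areas = patch.areas
        V += float((_pressure_energies(pair, delta) * areas).sum())
        f_mag = _pressures(pair, delta) * areas
        idx = np.flatnonzero(delta > 0.0)
        F = f_mag[idx, None] * dirs[idx]
        g_trans[ia] += (-F).sum(axis=0)
        g_rot[ia] += np.cross(Pc[idx] - centers[ia], -F).sum(axis=0)
        if ib >= 0:
            Fsum = F.sum(axis=0)
            g_trans[ib] += Fsum
            g_rot[ib] += np.cross(q - centers[ib], Fsum)
            surf = patch.surface
            if surf.kind == "plane":
                g_rot[ib] += np.cross(n, -(f_mag[idx, None] * (Pc[idx] - q)).sum(axis=0))
            elif surf.kind == "cylinder":
                w = Pc[idx] - q
                wn = w @ n
                wperp = w - np.outer(wn, n)
                dperp = np.maximum(np.linalg.norm(wperp, axis=1), 1e-12)
                g_m = ((f_mag[idx] * wn / dperp)[:, None] * w).sum(axis=0)
                g_rot[ib] += np.cross(n, g_m)

    # --- external axial load ---
    if model.load_case.axial_load != 0.0:
        V += -float(asm.load_vec @ t[asm.load_seg])
        g_trans[asm.load_seg] += -asm.load_vec

    # --- pack gradient ---
    grad = np.zeros(asm.ndof)
    for i in range(asm.nseg):
        idx = asm.dof_index[i]
        gr = left_jacobian(phi[i]).T @ g_rot[i]
        for k in range(3):
            if idx[k] >= 0:
                grad[idx[k]] = g_trans[i][k]
            if idx[3 + k] >= 0:
                grad[idx[3 + k]] = gr[k]
    return float(V), grad


def potential_energy(model: FootModel, pose: np.ndarray) -> float:
    """Total potential energy (N mm) at pose vector ``pose``."""
    return energy_and_gradient(model, pose)[0]


# ---------------------------------------------------------------------------
# physical force balance (independent of the optimizer)
# ---------------------------------------------------------------------------


def segment_loads(model: FootModel, x: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Net force (N) and net torque (N mm, about each segment's rotation
    center) on every segment, assembled from the physical element tensions,
    contact pressures and the external load."""
    asm = _assembled(model)
    R, t, _ = asm.states(x)
    centers = asm.origins + t
    F = np.zeros((asm.nseg, 3))
    M = np.zeros((asm.nseg, 3))

    P = asm.element_points(R, t)
    legs, lens, L, T, _ = asm.element_lengths_tensions(P)
    Tleg = T[asm.leg_elem]
    nz = Tleg != 0.0
    if np.any(nz):
        units = legs[nz] / np.maximum(lens[nz], 1e-12)[:, None]
        G = np.zeros((len(asm.pt_seg), 3))
        f_leg = Tleg[nz, None] * units
        np.add.at(G, asm.leg_start[nz], f_leg)  # pulled toward next point
        np.add.at(G, asm.leg_end[nz], -f_leg)  # pulled toward previous point
        for i in range(asm.nseg):
            idx = asm.seg_points[i]
            if len(idx):
                Gi = G[idx]
                F[i] += Gi.sum(axis=0)
                M[i] += np.cross(P[idx] - centers[i], Gi).sum(axis=0)

    for pair_data in asm.patch_data:
        pair, ia, ib, _, _ = pair_data
        Pc, delta, dirs, _, _ = asm.contact_eval(pair_data, R, t)
        f_mag = _pressures(pair, delta) * pair.patch.areas
        idx = np.flatnonzero(delta > 0.0)
        if len(idx) == 0:
            continue
        Fc = f_mag[idx, None] * dirs[idx]
        F[ia] += Fc.sum(axis=0)
        M[ia] += np.cross(Pc[idx] - centers[ia], Fc).sum(axis=0)
        if ib >= 0:
            F[ib] += (-Fc).sum(axis=0)
            M[ib] += np.cross(Pc[idx] - centers[ib], -Fc).sum(axis=0)

    if model.load_case.axial_load != 0.0:
        F[asm.load_seg] += asm.load_vec

    return {name: (F[i], M[i]) for i, name in enumerate(asm.seg_names)}


def residual_norm(model: FootModel, x: np.ndarray, char_length: float = 100.0) -> float:
    """Max generalized residual over free DOFs: |net force| components in N
    and |net torque|/char_length in N (torques scaled by ``char_length`` mm)."""
    loads = segment_loads(model, x)
    worst = 0.0
    for seg in model.segments.values():
        f, tau = loads[seg.name]
        for k in range(3):
            if seg.free_dofs[k]:
                worst = max(worst, abs(float(f[k])))
            if seg.free_dofs[3 + k]:
                worst = max(worst, abs(float(tau[k])) / char_length)
    return worst


# ---------------------------------------------------------------------------
# solve: trust-region damped Newton with load continuation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverSettings:
    """Equilibrium solver settings (documented defaults).

    The axial load (with proportional muscle forces) is applied in
    ``ramp_steps`` warm-started increments; each increment is minimized by a
    trust-region damped-Newton method on a finite-difference Hessian of the
    analytic gradient.  ``trust_init``/``trust_max`` are step bounds in
    scaled coordinates (rotations weighted by ``char_length``), keeping the
    iterates on the physical equilibrium branch.
    """

    residual_tol: float = 1e-3  # N (generalized; torques scaled by char_length)
    char_length: float = 100.0  # mm
    max_iterations: int = 500  # Newton iterations per load stage
    hessian_fd_step: float = 1e-6
    ramp_steps: int = 6
    trust_init: float = 1.0  # mm-equivalent
    trust_max: float = 8.0
    trust_min: float = 1e-10
    stall_window: int = 25


@dataclass
class EquilibriumResult:
    """Converged (or diagnostic) equilibrium state of a FootModel.

    The results object: segment poses, residuals, per-element forces and
    per-patch contact pressures, plus iterate histories for diagnostics.
    """

    model: FootModel
    pose: np.ndarray
    converged: bool
    residual_norm: float
    energy: float
    element_forces: dict[str, float]
    element_lengths: dict[str, float]
    contact_pressures: dict[str, np.ndarray]  # patch name -> MPa per point
    iterations: int
    energy_history: np.ndarray
    residual_history: np.ndarray
    tolerance: float = 1e-3
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and not (self.residual_norm <= self.tolerance):
            raise RuntimeError("internal: converged result above tolerance")

    # -- derived quantities --------------------------------------------------

    def segment_states(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """segment name -> (rotation matrix, translation) at equilibrium."""
        asm = _assembled(self.model)
        R, t, _ = asm.states(self.pose)
        return {name: (R[i], t[i]) for i, name in enumerate(asm.seg_names)}

    def landmark_positions(self) -> dict[str, np.ndarray]:
        """All geometry landmarks carried to the equilibrium pose."""
        states = self.segment_states()
        out = {}
        for name, lm in self.model.geometry.landmarks.items():
            seg = self.model.segments[lm.segment]
            R, t = states[lm.segment]
            out[name] = seg.origin + t + R @ (lm.position - seg.origin)
        return out

    def contact_details(self) -> dict[str, dict[str, np.ndarray]]:
        """Per patch: world points, penetrations, pressures, outward
        directions and force vectors at equilibrium."""
        asm = _assembled(self.model)
        R, t, _ = asm.states(self.pose)
        out = {}
        for pair_data in asm.patch_data:
            pair = pair_data[0]
            P, delta, dirs, _, _ = asm.contact_eval(pair_data, R, t)
            pressures = _pressures(pair, delta)
            forces = (pressures * pair.patch.areas)[:, None] * dirs
            out[pair.patch.name] = {
                "joint": pair.patch.joint,
                "points": P,
                "penetration": delta,
                "pressure": pressures,
                "areas": pair.patch.areas.copy(),
                "direction": np.array(dirs),
                "force": forces,
            }
        return out

    def summary(self) -> str:
        """Human-readable solve summary (scenario, convergence, key forces)."""
        from . import measures

        lines = [
            "Equilibrium solve",
            "=" * 54,
            f"scenario:       {self.model.scenario}",
            f"axial load:     {self.model.load_case.axial_load:.1f} N",
            f"converged:      {self.converged}",
            f"iterations:     {self.iterations}",
            f"residual norm:  {self.residual_norm:.3e} N",
            f"energy:         {self.energy:.3f} N mm",
            "",
            "largest element tensions (N):",
        ]
        top = sorted(self.element_forces.items(), key=lambda kv: -kv[1])[:8]
        for name, f in top:
            lines.append(f"  {name:<36s} {f:8.1f}")
        lines.append("")
        lines.append("joint contact (mean MPa / peak MPa / area mm^2):")
        for joint in ("tibiotalar", "subtalar", "talonavicular", "calcaneocuboid"):
            st = measures.contact_statistics(self, joint)
            lines.append(
                f"  {joint:<16s} {st.mean_pressure:6.3f} / {st.peak_pressure:6.3f} / {st.area:8.1f}"
            )
        return "\n".join(lines)


def _fd_hessian(model: FootModel, x: np.ndarray, h: float) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for k in range(n):
        xp = x.copy()
        xp[k] += h
        _, gp = energy_and_gradient(model, xp)
        xm = x.copy()
        xm[k] -= h
        _, gm = energy_and_gradient(model, xm)
        H[:, k] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _dof_scaling(asm: _Assembled, char_length: float) -> np.ndarray:
    """Per-DOF scale: 1 for translations (mm), char_length for rotations, so
    trust radii are in mm-equivalents."""
    d = np.ones(asm.ndof)
    for i in range(asm.nseg):
        for k in range(3):
            if asm.dof_index[i, 3 + k] >= 0:
                d[asm.dof_index[i, 3 + k]] = char_length
    return d


def _minimize_stage(model, x, settings, tol, energy_history=None, residual_history=None):
    """Trust-region damped Newton in scaled coordinates.

    The Hessian is eigenvalue-shifted to positive definiteness (soft spin
    modes can be geometrically destabilized by joint compression), steps are
    bounded by the trust radius, and acceptance uses an actual/predicted
    decrease ratio.  Returns (x, iterations, message).
    """
    asm = _assembled(model)
    D = _dof_scaling(asm, settings.char_length)
    Dinv = 1.0 / D
    trust = settings.trust_init
    message = ""
    r = residual_norm(model, x, settings.char_length)
    if residual_history is not None:
        residual_history.append(r)
    if energy_history is not None:
        energy_history.append(potential_energy(model, x))
    best_r = r
    since_best = 0
    it = 0
    eye = np.eye(len(x))
    while r > tol and it < settings.max_iterations:
        it += 1
        V0, g = energy_and_gradient(model, x)
        H = _fd_hessian(model, x, settings.hessian_fd_step)
        Hs = (Dinv[:, None] * H) * Dinv[None, :]
        gs = Dinv * g
        evals = np.linalg.eigvalsh(Hs)
        scale = max(1e-9, float(np.abs(evals).max()))
        lam = max(0.0, -float(evals.min())) + 1e-9 * scale
        accepted = False
        for _ in range(60):
            try:
                step_s = np.linalg.solve(Hs + lam * eye, -gs)
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-9 * scale)
                continue
            norm = float(np.linalg.norm(step_s))
            if norm > trust:
                lam = max(lam * 4.0, 1e-9 * scale)
                continue
            step = Dinv * step_s
            V_try = potential_energy(model, x + step)
            pred = -(gs @ step_s) - 0.5 * float(step_s @ (Hs @ step_s))
            actual = V0 - V_try
            ok = np.isfinite(V_try) and (
                actual >= 1e-4 * pred if pred > 0 else actual > 0.0
            )
            if ok:
                x = x + step
                accepted = True
                if pred > 0 and actual > 0.75 * pred and norm > 0.8 * trust:
                    trust = min(trust * 2.0, settings.trust_max)
                elif pred > 0 and actual < 0.25 * pred:
                    trust = max(trust * 0.5, settings.trust_min)
                if energy_history is not None:
                    energy_history.append(V_try)
                break
            lam = max(lam * 10.0, 1e-9 * scale)
            trust = max(trust * 0.5, settings.trust_min)
        if not accepted:
            message = "trust-region Newton could not decrease the energy"
            break
        r = residual_norm(model, x, settings.char_length)
        if residual_history is not None:
            residual_history.append(r)
        if r < best_r * 0.99:
            best_r = r
            since_best = 0
        else:
            since_best += 1
            if since_best >= settings.stall_window:
                message = "residual stalled in trust-region Newton"
                break
    return x, it, message


def _lm_polish(model, x, settings, tol, residual_history=None):
    """Levenberg-Marquardt on the scaled generalized force residual.

    Minimizes ||W g(x)||^2 (W weights torque components by 1/char_length)
    with the FD Hessian as the Jacobian of g.  Robust on the nearly flat
    energy valleys where curvature information is at the noise floor;
    returns (x, iterations, message).
    """
    asm = _assembled(model)
    Wd = 1.0 / _dof_scaling(asm, settings.char_length)

    def scaled_grad(z):
        _, g = energy_and_gradient(model, z)
        return Wd * g

    gs = scaled_grad(x)
    r = residual_norm(model, x, settings.char_length)
    mu = 1e-6
    it = 0
    while r > tol and it < settings.max_iterations:
        it += 1
        H = _fd_hessian(model, x, settings.hessian_fd_step)
        J = Wd[:, None] * H
        A = J.T @ J
        b = -J.T @ gs
        scale = max(1e-12, float(np.trace(A)) / len(x))
        accepted = False
        for _ in range(50):
            try:
                step = np.linalg.solve(A + mu * scale * np.eye(len(x)), b)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            if np.linalg.norm(step) > settings.trust_max:
                mu *= 4.0
                continue
            gs_try = scaled_grad(x + step)
            if np.linalg.norm(gs_try) < np.linalg.norm(gs):
                x = x + step
                gs = gs_try
                mu = max(mu / 3.0, 1e-12)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            return x, it, "LM polish could not reduce the force residual"
        r = residual_norm(model, x, settings.char_length)
        if residual_history is not None:
            residual_history.append(r)
    msg = "" if r <= tol else "LM polish hit the iteration cap"
    return x, it, msg


def solve_equilibrium(
    model: FootModel,
    start: np.ndarray | None = None,
    settings: SolverSettings | None = None,
) -> EquilibriumResult:
    """Find the static equilibrium pose of ``model``.

    With no ``start``, the axial load (and the proportional muscle forces)
    ramps up in ``settings.ramp_steps`` warm-started increments from the
    unloaded pretension equilibrium.  A supplied ``start`` skips the ramp
    (used by load sweeps).  Deterministic for a fixed model and start.
    Non-convergence returns a result with ``converged=False`` and the last
    iterate plus histories — never a silent bad pose.
    """
    settings = settings or SolverSettings()
    asm = _assembled(model)
    ndof = asm.ndof
    W = model.load_case.axial_load

    energy_history: list[float] = []
    residual_history: list[float] = []
    total_iters = 0

    if start is None:
        x = np.zeros(ndof)
        if W > 0.0 and settings.ramp_steps > 1:
            # pretension settle, then load ramp (coarse tolerances: the
            # intermediate stages only provide warm starts)
            stage_tol = max(10.0 * settings.residual_tol, 1e-3 * W)
            for frac in np.linspace(0.0, 1.0, settings.ramp_steps + 1)[:-1]:
                sub = model.with_load(frac * W)
                x, it, _ = _minimize_stage(sub, x, settings, tol=stage_tol)
                total_iters += it
    else:
        x = np.array(start, dtype=float)
        if x.shape != (ndof,):
            raise ValueError(f"start pose must have {ndof} coordinates, got {x.shape}")

    x, it, message = _minimize_stage(
        model, x, settings, settings.residual_tol, energy_history, residual_history
    )
    total_iters += it
    if message:
        # flat-valley polish: drive the force residual down directly
        x, it, message = _lm_polish(model, x, settings, settings.residual_tol, residual_history)
        total_iters += it

    r = residual_norm(model, x, settings.char_length)
    converged = bool(r <= settings.residual_tol)
    if not converged and not message:
        message = f"residual {r:.3e} N above tolerance {settings.residual_tol:.1e} N"

    V_final = potential_energy(model, x)
    R, t, _ = asm.states(x)
    P = asm.element_points(R, t)
    _, _, L, T, _ = asm.element_lengths_tensions(P)
    el_forces = {el.name: float(T[i]) for i, el in enumerate(model.elements)}
    el_lengths = {el.name: float(L[i]) for i, el in enumerate(model.elements)}

    contact_pressures = {}
    for pair_data in asm.patch_data:
        pair = pair_data[0]
        _, delta, _, _, _ = asm.contact_eval(pair_data, R, t)
        contact_pressures[pair.patch.name] = _pressures(pair, delta)

    return EquilibriumResult(
        model=model,
        pose=x,
        converged=converged,
        residual_norm=float(r),
        energy=float(V_final),
        element_forces=el_forces,
        element_lengths=el_lengths,
        contact_pressures=contact_pressures,
        iterations=total_iters,
        energy_history=np.array(energy_history),
        residual_history=np.array(residual_history),
        tolerance=settings.residual_tol,
        message=message,
    )
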