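"""Continuation/Newton driver for the mixed equilibrium problem.

Each continuation step solves the stationary weak form
``int_Omega P : grad(v) + q (J - 1) dX = 0`` with either prescribed
boundary displacements (the nine stretch/shear protocols) or zero traction
plus rigid-mode Lagrange multipliers (free contraction).  The previous
step's solution is the initial guess for the next one; Newton uses the
exact consistent tangent and a sparse direct linear solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import geometry as geo
from .fem import TaylorHoodSpace
from .materials import ActiveTransient, MaterialParams

__all__ = [
    "SimulationConfig",
    "SolutionState",
    "NewtonError",
    "JacobianCache",
    "PROTOCOLS",
    "solve_step",
    "run_protocol",
    "run_contraction",
]

# protocol -> (face-pair axis, displacement axis); the face pair is
# (S1,S2) for axis 0, (S3,S4) for axis 1, (S5,S6) for axis 2; the second
# face of the pair is moved.
PROTOCOLS = {
    "FF": (0, 0), "FS": (0, 1), "FN": (0, 2),
    "SS": (1, 1), "SF": (1, 0), "SN": (1, 2),
    "NN": (2, 2), "NF": (2, 0), "NS": (2, 1),
}
_FIXED_FACE = {0: geo.S1, 1: geo.S3, 2: geo.S5}
_MOVED_FACE = {0: geo.S2, 1: geo.S4, 2: geo.S6}


@dataclass
class SimulationConfig:
    """Protocol definition and numerical controls for one virtual test."""

    protocol: str = "FF"
    magnitude: float | ActiveTransient = 0.1
    n_steps: int = 10
    newton_rtol: float = 1e-10
    newton_atol: float = 1e-10
    # iterations are cheap under the frozen-Jacobian scheme; the cap
    # bounds total work per continuation step, not full factorizations
    newton_max_iter: int = 60
    max_bisections: int = 3
    incompressibility_tol: float = 1e-6
    quad_degree: int = 5
    # augmented-Lagrangian stabilization modulus (kPa): penalizes the
    # pointwise volume changes that the weak P1 constraint cannot see
    # (thin matrix layers next to the membrane); the weak incompressibility
    # equation itself is unchanged.  None resolves to 25 for contraction
    # and 200 for the boundary-driven stretch/shear protocols, which
    # squeeze the pad harder
    stabilization: float | None = None

    def __post_init__(self):
        if self.protocol not in PROTOCOLS and self.protocol != "CONTRACT":
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.protocol != "CONTRACT" and float(self.magnitude) < 0:
            raise ValueError("magnitude must be >= 0")
        if self.stabilization is None:
            self.stabilization = 25.0 if self.protocol == "CONTRACT" \
                else 200.0


@dataclass
class SolutionState:
    """Converged mixed solution at one continuation step."""

    u: np.ndarray                 # (n2, 3) um
    p: np.ndarray                 # (nv,) kPa
    multipliers: np.ndarray | None
    step_value: float             # stretch/shear fraction, or time in ms
    step_index: int
    gamma: float = 0.0
    kappa: float = 0.0           # stabilization modulus used by the solver
    newton_iters: int = 0
    residual_history: list = field(default_factory=list)
    max_J_dev: float = 0.0
    raw_residual: np.ndarray | None = None   # pre-BC residual (reactions)


class NewtonError(RuntimeError):
    def __init__(self, msg, state=None, history=None):
        super().__init__(msg)
        self.state = state
        self.history = history or []


def _gamma_el(space: TaylorHoodSpace, gamma: float) -> np.ndarray:
    return np.where(space.intra_el, gamma, 0.0)


def dirichlet_data(space: TaylorHoodSpace, protocol: str, value: float):
    """(dofs, values): both active faces fully clamped, the moved face
    displaced uniformly by value * (box extent along the pair axis)."""
    axis, direction = PROTOCOLS[protocol]
    fixed_nodes = space.facet_nodes(_FIXED_FACE[axis])
    moved_nodes = space.facet_nodes(_MOVED_FACE[axis])
    disp = value * space.mesh.box[axis]
    dofs = np.concatenate([space.u_dofs_of_nodes(fixed_nodes),
                           space.u_dofs_of_nodes(moved_nodes)])
    vals = np.zeros(len(dofs))
    off = 3 * len(fixed_nodes)
    mv = dofs[off:]
    vals[off:][mv % 3 == direction] = disp
    return dofs, vals


class JacobianCache:
    """A factorized (possibly stale) Newton matrix, reusable across
    iterations and continuation steps.

    Residual assembly is two orders of magnitude cheaper than a sparse LU
    factorization here, so the driver iterates with a frozen factorization
    and refactors only when the observed contraction degrades.
    """

    def __init__(self):
        self.lu = None
        self.K = None
        self.fresh = False
        self.safe = False
        # limited-memory Broyden secant pairs updating the frozen inverse
        self.pairs: list = []

    def factor(self, space, params, u, p, gamma_el, C, sysmask,
               kappa: float = 0.0, safe: bool = False):
        _, K, _ = space.assemble(u, p, gamma_el, params, True, kappa=kappa)
        if C is not None:
            Ksys = sp.bmat([[K, C.T], [C, None]], format="csr")
        else:
            Ksys = K
        d_free = sp.diags(sysmask.astype(float))
        d_fix = sp.diags((~sysmask).astype(float))
        Ksys = (d_free @ Ksys @ d_free + d_fix).tocsr()
        self.K = Ksys.tocsc()
        # symmetric equilibration: displacement and pressure rows differ in
        # scale by orders of magnitude, which makes threshold pivoting
        # reject pivots and inflate fill; scale rows/cols to unit max first
        rowmax = np.maximum(np.abs(Ksys).max(axis=1).toarray().ravel(),
                            1e-300)
        self.scale = 1.0 / np.sqrt(rowmax)
        D = sp.diags(self.scale)
        Keq = (D @ Ksys @ D).tocsc()
        self._Keq = Keq
        if safe:
            # full partial pivoting: slower ordering/factorization but
            # robust when the tangent is nearly singular
            self.lu = spla.splu(Keq)
        else:
            self.lu = spla.splu(Keq, permc_spec="MMD_AT_PLUS_A",
                                options={"SymmetricMode": True,
                                         "DiagPivotThresh": 0.01})
        self.fresh = True
        self.safe = safe
        self.pairs = []

    def solve(self, rhs):
        """Solve with iterative refinement; returns (delta, rel_residual)."""
        s = self.scale
        d = s * self.lu.solve(s * rhs)
        nrm = np.linalg.norm(rhs)
        if nrm == 0.0:
            return d, 0.0
        for _ in range(2):
            r = rhs - self.K @ d
            rel = np.linalg.norm(r) / nrm
            if rel < 1e-9 or not np.isfinite(rel):
                break
            d = d + s * self.lu.solve(s * r)
        r = rhs - self.K @ d
        return d, float(np.linalg.norm(r) / nrm)

    def apply_inverse(self, v):
        """Broyden-updated approximate inverse of the current tangent."""
        w = self.scale * self.lu.solve(self.scale * v)
        for dx, c, denom in self.pairs:
            w = w + (dx - c) * ((dx @ w) / denom)
        return w

    def secant_update(self, dx, dr):
        """Good-Broyden rank-one update from an accepted step.

        dx is the taken step, dr the observed residual change; the update
        makes the approximate inverse satisfy the secant equation.
        """
        if len(self.pairs) >= 30:
            self.pairs = self.pairs[15:]   # keep the most recent secants
        c = self.apply_inverse(dr)
        denom = float(dx @ c)
        guard = 1e-10 * np.linalg.norm(dx) * np.linalg.norm(c)
        if abs(denom) > guard and np.isfinite(denom):
            self.pairs.append((dx, c, denom))


#: refactor the Jacobian when the quasi-Newton contraction exceeds this
_REFACTOR_CONTRACTION = 0.9


def _newton(space, params, gamma, dirichlet, C, u0, p0, lam0, cfg,
            jac: JacobianCache | None = None):
    """(Quasi-)Newton iteration at fixed step data -> SolutionState."""
    jac = jac if jac is not None else JacobianCache()
    jac.fresh = False          # 'fresh' = factored at the current iterate
    u = u0.copy()
    p = p0.copy()
    lam = None if C is None else lam0.copy()
    ndof = space.ndof
    freemask = np.ones(ndof, dtype=bool)
    if dirichlet is not None:
        dofs, vals = dirichlet
        u.reshape(-1)[dofs] = vals
        freemask[dofs] = False
    n_sys = ndof + (C.shape[0] if C is not None else 0)
    sysmask = np.ones(n_sys, dtype=bool)
    sysmask[:ndof] = freemask
    gamma_el = _gamma_el(space, gamma)
    history = []

    kappa = cfg.stabilization

    def evaluate(uu, pp, ll):
        """raw residual, masked full residual, its norm, max|J-1|."""
        R, _, dev = space.assemble(uu, pp, gamma_el, params, False,
                                   kappa=kappa)
        raw = R
        if C is not None:
            Rfull = np.concatenate(
                [R + C.T @ ll, C @ np.concatenate([uu.ravel(), pp])])
        else:
            Rfull = R.copy()
        Rfull[:ndof][~freemask] = 0.0
        with np.errstate(over="ignore", invalid="ignore"):
            nrm = float(np.linalg.norm(Rfull))
        return raw, Rfull, nrm, dev

    try:
        raw, Rfull, rnorm, maxdev = evaluate(u, p, lam)
    except FloatingPointError as exc:
        raise NewtonError(f"initial iterate inadmissible: {exc}") from exc
    history.append(rnorm)
    r0 = max(rnorm, 1e-300)
    slow_streak = 0

    def state_now(iters):
        return SolutionState(
            u=u, p=p, multipliers=lam, step_value=np.nan, step_index=-1,
            gamma=gamma, newton_iters=iters, residual_history=history,
            max_J_dev=maxdev, raw_residual=raw)

    for it in range(cfg.newton_max_iter):
        if rnorm < cfg.newton_atol or rnorm < cfg.newton_rtol * r0:
            return state_now(it)
        if jac.lu is None:
            jac.factor(space, params, u, p, gamma_el, C, sysmask, kappa)
        rhs = -Rfull
        accepted = None
        for _attempt in range(3):
            if jac.pairs:
                delta = jac.apply_inverse(rhs)
                bad = not np.all(np.isfinite(delta))
            else:
                delta, linres = jac.solve(rhs)
                bad = not np.all(np.isfinite(delta)) or linres > 1e-6
            if bad:
                # restricted-pivoting factorization lost accuracy (tangent
                # close to singular): refactor with full pivoting
                if jac.safe and jac.fresh:
                    raise NewtonError("linear solver failed on the exact "
                                      "tangent", history=history)
                jac.factor(space, params, u, p, gamma_el, C, sysmask,
                           kappa, safe=True)
                continue
            du = delta[:space.nu].reshape(-1, 3)
            dp = delta[space.nu:ndof]
            dl = delta[ndof:] if C is not None else None
            # backtracking: reject trial points that invert elements or
            # fail to reduce the residual
            alpha = 1.0
            for _ in range(12):
                try:
                    cand = evaluate(u + alpha * du, p + alpha * dp,
                                    lam + alpha * dl if C is not None
                                    else lam)
                except FloatingPointError:
                    alpha *= 0.5
                    continue
                if cand[2] < rnorm or cand[2] < cfg.newton_atol:
                    accepted = (alpha, du, dp, dl, cand)
                    break
                alpha *= 0.5
            if accepted is not None or jac.fresh:
                break
            # a stale Jacobian made no progress: refactor and retry once
            jac.factor(space, params, u, p, gamma_el, C, sysmask, kappa)
        if accepted is None:
            raise NewtonError("line search failed (element inversion or "
                              "residual stagnation)", history=history,
                              state=state_now(it))
        alpha, du, dp, dl, (raw, Rnew, rnew, maxdev) = accepted
        u = u + alpha * du
        p = p + alpha * dp
        if C is not None:
            lam = lam + alpha * dl
        # secant update of the frozen inverse from the observed step
        jac.secant_update(alpha * delta, Rnew - Rfull)
        Rfull = Rnew
        contraction = rnew / max(rnorm, 1e-300)
        rnorm = rnew
        history.append(rnorm)
        slow_streak = slow_streak + 1 \
            if contraction > _REFACTOR_CONTRACTION else 0
        if slow_streak >= 2:
            # even the secant-corrected Jacobian is too slow: rebuild
            if not jac.fresh:
                jac.lu = None
                slow_streak = 0
        jac.fresh = False
    if rnorm < cfg.newton_atol or rnorm < cfg.newton_rtol * r0:
        return state_now(cfg.newton_max_iter)
    raise NewtonError(
        f"Newton failed to converge in {cfg.newton_max_iter} iterations "
        f"(residual {history[-1]:.3e})",
        state=state_now(cfg.newton_max_iter), history=history)


def solve_step(space: TaylorHoodSpace, params: MaterialParams,
               config: SimulationConfig, step_value: float,
               initial: SolutionState | None = None,
               jac: JacobianCache | None = None) -> SolutionState:
    """Solve one continuation step.

    For stretch/shear protocols ``step_value`` is the current stretch/shear
    fraction; for CONTRACT it is the current activation gamma.
    """
    if initial is None:
        initial = reference_state(space)
    contract = config.protocol == "CONTRACT"
    C = space.rigid_constraint_matrix() if contract else None
    dirichlet = None if contract else dirichlet_data(
        space, config.protocol, step_value)
    gamma = step_value if contract else 0.0
    lam0 = initial.multipliers if initial.multipliers is not None \
        else np.zeros(6)
    u0 = initial.u
    if not contract:
        # affine lifting of the boundary increment: compatible with both
        # clamped faces and keeps the first iterate far from element
        # inversion even on thin boundary slabs
        axis, direction = PROTOCOLS[config.protocol]
        prev_val = initial.step_value if np.isfinite(initial.step_value) \
            else 0.0
        u0 = initial.u.copy()
        u0[:, direction] += (step_value - prev_val) \
            * space.p2_coords[:, axis]
    st = _newton(space, params, gamma, dirichlet, C,
                 u0, initial.p, lam0, config, jac=jac)
    st.step_value = step_value
    st.kappa = config.stabilization
    st.space = space          # for postprocessing defaults
    st.params = params
    return st


def reference_state(space: TaylorHoodSpace) -> SolutionState:
    return SolutionState(u=np.zeros((space.n2, 3)), p=np.zeros(space.nv),
                         multipliers=None, step_value=0.0, step_index=0)


def _continuation(space, params, config, targets, jac=None):
    """March through target step values with bisection on failure."""
    jac = jac if jac is not None else JacobianCache()
    states = []
    prev = reference_state(space)
    prev_val = 0.0
    for i, tv in enumerate(targets):
        try:
            st = solve_step(space, params, config, tv, prev, jac=jac)
        except NewtonError:
            st = _bisect(space, params, config, prev, prev_val, tv,
                         config.max_bisections, jac)
        st.step_index = i + 1
        states.append(st)
        prev, prev_val = st, tv
    return states


def _bisect(space, params, config, prev, lo, hi, depth, jac=None):
    if depth <= 0:
        raise NewtonError(
            f"continuation failed near step value {hi:.4g} after bisection")
    mid = 0.5 * (lo + hi)
    try:
        st_mid = solve_step(space, params, config, mid, prev, jac=jac)
    except NewtonError:
        st_mid = _bisect(space, params, config, prev, lo, mid, depth - 1,
                         jac)
    try:
        return solve_step(space, params, config, hi, st_mid, jac=jac)
    except NewtonError:
        return _bisect(space, params, config, st_mid, mid, hi, depth - 1,
                       jac)


def run_protocol(mesh: geo.MeshBundle, params: MaterialParams,
                 config: SimulationConfig, space: TaylorHoodSpace = None):
    """Run a stretch/shear protocol; returns (states, LoadCurve)."""
    from .postprocess import LoadCurve, surface_load
    if config.protocol == "CONTRACT":
        return run_contraction(mesh, params, config.magnitude,
                               config.n_steps, space=space)
    space = space or TaylorHoodSpace(mesh, config.quad_degree)
    mag = float(config.magnitude)
    targets = np.linspace(0.0, mag, config.n_steps + 1)[1:]
    states = _continuation(space, params, config, targets)
    axis, direction = PROTOCOLS[config.protocol]
    surf = _MOVED_FACE[axis]
    normal_dir = np.eye(3)[axis]
    shear_dir = np.eye(3)[direction]
    values = [0.0] + [s.step_value for s in states]
    normal = [0.0]
    shear = [0.0]
    for s in states:
        normal.append(surface_load(s, surf, normal_dir, space=space))
        shear.append(surface_load(s, surf, shear_dir, space=space))
    curve = LoadCurve(mode=config.protocol,
                      step_values=np.array(values),
                      normal_load=np.array(normal),
                      shear_load=np.array(shear))
    return states, curve


def run_contraction(mesh: geo.MeshBundle, params: MaterialParams,
                    transient: ActiveTransient, n_steps: int,
                    t_end: float | None = None,
                    config: SimulationConfig | None = None,
                    space: TaylorHoodSpace = None):
    """Traction-free contraction along the activation transient.

    Returns (states, AveragedTrace); the time grid always contains the
    transient peak so peak stress is sampled exactly.
    """
    from .postprocess import averaged_trace
    config = config or SimulationConfig(protocol="CONTRACT",
                                        magnitude=transient, n_steps=n_steps)
    config = replace(config, protocol="CONTRACT")
    space = space or TaylorHoodSpace(mesh, config.quad_degree)
    t_end = transient.t_end if t_end is None else t_end
    times = np.linspace(0.0, t_end, n_steps + 1)
    if transient.t_peak <= t_end:
        times = np.unique(np.concatenate([times, [transient.t_peak]]))
    gammas = transient(times)
    states = []
    prev = reference_state(space)
    jac = JacobianCache()
    for i, (t, g) in enumerate(zip(times[1:], gammas[1:]), start=1):
        st = solve_step(space, params, config, float(g), prev, jac=jac)
        st.step_value = float(t)
        st.gamma = float(g)
        st.step_index = i
        states.append(st)
        prev = st
    trace = averaged_trace(states, space)
    return states, trace
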