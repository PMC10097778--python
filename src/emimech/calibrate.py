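"""Parameter estimation against stretch/shear load data, and Sobol
sensitivity analysis.

Experiment schema
-----------------
One sample is a directory (or explicit file mapping) holding

* ``dimensions.json`` — ``{"sample_id": ..., "length_mm": L, "width_mm": W,
  "height_mm": H}`` with the reference block dimensions along the fiber,
  sheet and normal axes;
* one ``<MODE>.csv`` per deformation mode (FF..NS) with columns
  ``displacement_mm, force_N``.

The reader converts to stretch ``lambda = 1 + d / L_axis`` (the reference
extent along the mode's face-pair axis) and load ``force / A_ref`` (kPa,
with the reference cross-sectional area of the loaded face); rows with
negative displacement are dropped.  This mirrors the structure of the
published ovine left-ventricle stretch/shear dataset without requiring a
download; :func:`generate_synthetic_experiment` writes the same schema
from simulated loads.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .geometry import CellGeometrySpec, build_single_cell_mesh
from .materials import PARAM_NAMES, MaterialParams
from .solver import PROTOCOLS, NewtonError, SimulationConfig

__all__ = [
    "ExperimentSample",
    "SobolResult",
    "read_experiment",
    "generate_synthetic_experiment",
    "simulate_loads",
    "objective",
    "fit_parameters",
    "sobol_sensitivity",
    "DEFAULT_BOUNDS",
    "SOBOL_RANGE",
    "STRETCH_MAGNITUDE",
    "SHEAR_MAGNITUDE",
]

MODES = tuple(PROTOCOLS)
#: box-constraint interval for each material parameter during fitting
DEFAULT_BOUNDS = (0.01, 40.0)
#: per-parameter range explored by the sensitivity analysis
SOBOL_RANGE = (0.1, 30.0)
#: protocol magnitudes: stretch to 10%, shear to 40%
STRETCH_MAGNITUDE = 0.10
SHEAR_MAGNITUDE = 0.40

_STRETCH_MODES = ("FF", "SS", "NN")


def mode_magnitude(mode: str) -> float:
    return STRETCH_MAGNITUDE if mode in _STRETCH_MODES else SHEAR_MAGNITUDE


@dataclass
class ExperimentSample:
    """Per-sample reference dimensions and per-mode (stretch, load) arrays."""

    sample_id: str
    length_mm: float
    width_mm: float
    height_mm: float
    modes: dict = field(default_factory=dict)  # mode -> (lam, load_kPa)

    def axis_extent(self, axis: int) -> float:
        return (self.length_mm, self.width_mm, self.height_mm)[axis]

    def face_area(self, axis: int) -> float:
        dims = [self.length_mm, self.width_mm, self.height_mm]
        dims.pop(axis)
        return dims[0] * dims[1]


def _mode_axis(mode: str) -> int:
    return PROTOCOLS[mode][0]


def read_experiment(path) -> ExperimentSample:
    """Read one sample directory in the documented schema."""
    path = Path(path)
    dims_file = path / "dimensions.json"
    if not dims_file.exists():
        raise FileNotFoundError(f"missing {dims_file}")
    with open(dims_file) as fh:
        dims = json.load(fh)
    sample = ExperimentSample(
        sample_id=str(dims.get("sample_id", path.name)),
        length_mm=float(dims["length_mm"]),
        width_mm=float(dims["width_mm"]),
        height_mm=float(dims["height_mm"]))
    found = False
    for mode in MODES:
        f = path / f"{mode}.csv"
        if not f.exists():
            continue
        found = True
        df = pd.read_csv(f)
        for i, col in enumerate(("displacement_mm", "force_N")):
            if col not in df.columns:
                raise ValueError(f"{f}: line 1: missing column {col!r}")
        bad = df.index[df.isna().any(axis=1)]
        if len(bad):
            raise ValueError(f"{f}: line {bad[0] + 2}: malformed row")
        # only the tensile/positive-shear branch is retained
        df = df[df["displacement_mm"] >= 0.0]
        axis = _mode_axis(mode)
        lam = 1.0 + df["displacement_mm"].to_numpy() / sample.axis_extent(axis)
        area_mm2 = sample.face_area(axis)
        load = df["force_N"].to_numpy() / area_mm2 * 1e3   # N/mm^2 -> kPa
        order = np.argsort(lam)
        sample.modes[mode] = (lam[order], load[order])
    missing = [m for m in MODES if m not in sample.modes]
    if missing and found:
        warnings.warn(f"sample {sample.sample_id}: missing modes "
                      f"{', '.join(missing)}; using the rest")
    if not found:
        raise FileNotFoundError(f"no mode CSV files found under {path}")
    return sample


def write_experiment(sample: ExperimentSample, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "dimensions.json", "w") as fh:
        json.dump({"sample_id": sample.sample_id,
                   "length_mm": sample.length_mm,
                   "width_mm": sample.width_mm,
                   "height_mm": sample.height_mm}, fh, indent=1)
    for mode, (lam, load) in sample.modes.items():
        axis = _mode_axis(mode)
        disp = (lam - 1.0) * sample.axis_extent(axis)
        force = load * sample.face_area(axis) * 1e-3       # kPa*mm^2 -> N
        pd.DataFrame({"displacement_mm": disp,
                      "force_N": force}).to_csv(path / f"{mode}.csv",
                                                index=False)


# ---------------------------------------------------------------------------
# virtual experiments
# ---------------------------------------------------------------------------

def simulate_loads(params: MaterialParams, mesh=None, resolution: float = 20.0,
                   modes=MODES, n_steps: int = 4,
                   spec: CellGeometrySpec | None = None,
                   space_cache: dict | None = None,
                   magnitudes: dict | None = None,
                   stabilization: float | None = None,
                   solver_options: dict | None = None) -> dict:
    """Run the virtual protocols; returns mode -> (step_values, loads).

    The tracked load component is the one the mode drives: the face-normal
    component for stretches, the in-plane shear component for shears.

    Passing the same ``space_cache`` dict across calls reuses the
    assembled space and warm-starts every continuation step from the
    previous call's converged state (static hyperelasticity is
    path-independent, so the warm start only changes the iteration count,
    not the solution).  This makes parameter sweeps with slowly varying
    parameters — optimization, sensitivity analysis — far cheaper.
    """
    from .fem import TaylorHoodSpace
    from .postprocess import surface_load
    from .solver import (JacobianCache, _MOVED_FACE, _bisect,
                         reference_state, solve_step)
    spec = spec or CellGeometrySpec()
    if space_cache is None:
        space_cache = {}
    if mesh is None:
        mesh = space_cache.get("mesh")
        if mesh is None:
            mesh = build_single_cell_mesh(spec, resolution)
            space_cache["mesh"] = mesh
    space = space_cache.setdefault("space", TaylorHoodSpace(mesh))
    warm = space_cache.setdefault("warm", {})
    out = {}
    for mode in modes:
        mag = (magnitudes or {}).get(mode, mode_magnitude(mode))
        cfg = SimulationConfig(protocol=mode, magnitude=mag,
                               n_steps=n_steps,
                               stabilization=stabilization,
                               **(solver_options or {}))
        targets = np.linspace(0.0, float(cfg.magnitude), n_steps + 1)[1:]
        axis, direction = PROTOCOLS[mode]
        surf = _MOVED_FACE[axis]
        e_dir = np.eye(3)[axis if axis == direction else direction]
        jac = warm.setdefault((mode, "jac"), JacobianCache())
        prev = reference_state(space)
        steps = [0.0]
        loads = [0.0]
        for k, tv in enumerate(targets):
            init = warm.get((mode, k), prev)
            try:
                st = solve_step(space, params, cfg, float(tv), init,
                                jac=jac)
            except NewtonError:
                # cold starts or large parameter jumps may need smaller
                # continuation increments
                lo = prev.step_value if np.isfinite(prev.step_value) else 0.0
                st = _bisect(space, params, cfg, prev, float(lo), float(tv),
                             cfg.max_bisections, jac)
            warm[(mode, k)] = st
            steps.append(tv)
            loads.append(surface_load(st, surf, e_dir, space=space))
            prev = st
        out[mode] = (np.array(steps), np.array(loads))
    return out


def generate_synthetic_experiment(params: MaterialParams,
                                  resolution: float = 20.0,
                                  noise_sd: float = 0.0,
                                  modes=MODES,
                                  seed: int = 0,
                                  n_steps: int = 4,
                                  dims_mm=(10.0, 10.0, 10.0),
                                  path=None,
                                  spec: CellGeometrySpec | None = None,
                                  space_cache: dict | None = None,
                                  magnitudes: dict | None = None,
                                  stabilization: float | None = None
                                  ) -> ExperimentSample:
    """Simulate the nine protocols and package them as an experiment sample.

    Gaussian noise of standard deviation ``noise_sd`` (kPa) is added
    independently to every load value; the reference state (zero load at
    lambda = 1) is kept exact.
    """
    rng = np.random.default_rng(seed)
    loads = simulate_loads(params, resolution=resolution, modes=modes,
                           n_steps=n_steps, spec=spec,
                           space_cache=space_cache, magnitudes=magnitudes,
                           stabilization=stabilization)
    sample = ExperimentSample(sample_id=f"synthetic-{seed}",
                              length_mm=dims_mm[0], width_mm=dims_mm[1],
                              height_mm=dims_mm[2])
    for mode in modes:
        steps, vals = loads[mode]
        vals = np.asarray(vals, dtype=float).copy()
        noise = rng.normal(0.0, noise_sd, size=len(vals)) if noise_sd > 0 \
            else np.zeros(len(vals))
        noise[steps == 0.0] = 0.0
        axis = _mode_axis(mode)
        lam = 1.0 + steps          # steps are stretch/shear fractions
        sample.modes[mode] = (lam, vals + noise)
    if path is not None:
        write_experiment(sample, path)
    return sample


#: penalty (kPa) returned when the simulator fails at a required stretch,
#: so bounded optimization can continue past pathological parameter sets
FAILURE_PENALTY = 1e4


def _residual_vector(params: MaterialParams, samples,
                     sim_config: dict | None = None) -> np.ndarray:
    """Per-point load differences (simulated minus experimental, kPa)."""
    if isinstance(samples, ExperimentSample):
        samples = [samples]
    sim_config = sim_config or {}
    modes = sorted({m for s in samples for m in s.modes})
    n_pts = sum(len(s.modes[m][0]) for s in samples for m in s.modes)
    try:
        sim = simulate_loads(params, modes=modes, **sim_config)
    except NewtonError:
        return np.full(n_pts, FAILURE_PENALTY / max(np.sqrt(n_pts), 1.0))
    out = []
    for s in samples:
        for mode in s.modes:
            lam_exp, load_exp = s.modes[mode]
            steps, load_sim = sim[mode]
            lam_sim = 1.0 + steps
            if lam_exp.max() > lam_sim.max() + 1e-9:
                raise ValueError(
                    f"experimental stretch {lam_exp.max():.3f} exceeds the "
                    f"simulated range for mode {mode}")
            out.append(np.interp(lam_exp, lam_sim, load_sim) - load_exp)
    return np.concatenate(out)


def objective(params: MaterialParams, samples, sim_config: dict | None = None,
              _cache: dict | None = None) -> float:
    """L2 misfit between experimental and simulated loads over all modes.

    The simulated load curve is interpolated linearly in stretch onto each
    experimental stretch value; the objective is the square root of the sum
    of squared differences over every retained point of every mode of every
    sample.
    """
    return float(np.linalg.norm(_residual_vector(params, samples,
                                                 sim_config)))


@dataclass
class FitResult:
    params: MaterialParams
    objective: float
    initial_objective: float
    n_evaluations: int
    success: bool
    message: str
    history: list = field(default_factory=list)


def fit_parameters(samples, bounds=DEFAULT_BOUNDS,
                   initial: MaterialParams | None = None,
                   sim_config: dict | None = None,
                   free: tuple = PARAM_NAMES,
                   n_starts: int = 1, seed: int = 0,
                   maxiter: int = 60) -> FitResult:
    """Bounded local minimization of the load misfit.

    ``free`` selects which of the six parameters vary (the others stay at
    their initial values).  The minimizer is bounded Gauss–Newton
    (trust-region-reflective least squares on the per-point residuals),
    which reaches the quadratic basin in far fewer simulator calls than a
    scalar quasi-Newton method.  With ``n_starts > 1``, additional starts
    are drawn log-uniformly inside the bounds (the data are known to
    admit local minima) and the best result is returned.
    """
    initial = initial or MaterialParams()
    lo, hi = bounds
    idx = [PARAM_NAMES.index(n) for n in free]
    x_full = initial.as_array().copy()
    x_full = np.clip(x_full, lo, hi)
    history = []
    neval = [0]

    def resvec(x):
        arr = x_full.copy()
        arr[idx] = x
        r = _residual_vector(MaterialParams.from_array(arr), samples,
                             sim_config)
        neval[0] += 1
        history.append((arr.tolist(), float(np.linalg.norm(r))))
        return r

    f0 = float(np.linalg.norm(resvec(x_full[idx])))
    rng = np.random.default_rng(seed)
    starts = [x_full[idx]]
    for _ in range(n_starts - 1):
        starts.append(np.exp(rng.uniform(np.log(max(lo, 1e-3)), np.log(hi),
                                         size=len(idx))))
    best = None
    ok = False
    msg = ""
    for x0 in starts:
        try:
            res = least_squares(resvec, x0, bounds=(lo, hi), method="trf",
                                diff_step=1e-3, xtol=1e-12, ftol=1e-12,
                                gtol=1e-12,
                                max_nfev=maxiter * (len(idx) + 1))
            cand = (float(np.linalg.norm(res.fun)), res.x,
                    res.status > 0, str(res.message))
        except Exception as exc:          # optimizer failure: keep best-so-far
            cand = (np.inf, x0, False, f"optimizer failure: {exc}")
        if best is None or cand[0] < best[0]:
            best = cand
    fbest, xbest, ok, msg = best
    if not np.isfinite(fbest):
        vals = [h for h in history if np.isfinite(h[1])]
        if vals:
            arr, fbest = min(vals, key=lambda h: h[1])
            xbest = np.asarray(arr)[idx]
        ok = False
    arr = x_full.copy()
    arr[idx] = np.clip(xbest, lo, hi)
    return FitResult(params=MaterialParams.from_array(arr),
                     objective=float(fbest), initial_objective=float(f0),
                     n_evaluations=neval[0], success=bool(ok), message=msg,
                     history=history)


# ---------------------------------------------------------------------------
# Sobol sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SobolResult:
    """First-order and total Sobol indices with bootstrap intervals."""

    S1: np.ndarray                 # (D,)
    ST: np.ndarray                 # (D,)
    S1_conf: np.ndarray            # (D,) half-width of 95% CI
    ST_conf: np.ndarray
    names: tuple
    n_base: int
    ranges: tuple
    seed: int
    n_evaluations: int
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.names, "S1": self.S1,
                             "S1_conf": self.S1_conf, "ST": self.ST,
                             "ST_conf": self.ST_conf})


def saltelli_design(n_base: int, dim: int, ranges=SOBOL_RANGE,
                    seed: int = 0) -> np.ndarray:
    """Classic Saltelli cross-sampling design: N (D + 2) rows.

    Rows are ordered [A; B; AB_1; ...; AB_D] where AB_i is A with column i
    replaced from B.  The base matrices come from a scrambled Sobol'
    sequence.
    """
    sampler = qmc.Sobol(d=2 * dim, scramble=True, rng=np.random.default_rng(seed))
    base = sampler.random(n_base)
    lo, hi = ranges
    A = lo + (hi - lo) * base[:, :dim]
    B = lo + (hi - lo) * base[:, dim:]
    blocks = [A, B]
    for i in range(dim):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        blocks.append(ABi)
    return np.vstack(blocks)


def sobol_sensitivity(output_fn, n_base: int = 512, dim: int = 6,
                      ranges=SOBOL_RANGE, seed: int = 0,
                      names=PARAM_NAMES, n_boot: int = 200,
                      eval_order: str = "sequential") -> SobolResult:
    """Variance-based sensitivity of ``output_fn`` (vector of params -> scalar).

    Uses the Saltelli design with the Saltelli-2010 first-order estimator
    and the Jansen total-order estimator; confidence intervals by bootstrap
    over the base sample.  ``eval_order='grouped'`` evaluates each base row
    together with its one-coordinate resamples — the estimates are
    identical, but expensive simulator-backed outputs that warm-start from
    the previous evaluation converge much faster this way.
    """
    X = saltelli_design(n_base, dim, ranges, seed)
    y = np.empty(len(X))
    if eval_order == "grouped":
        order = []
        for j in range(n_base):
            order.append(j)
            order.extend(2 * n_base + i * n_base + j for i in range(dim))
            order.append(n_base + j)
        for idx in order:
            y[idx] = float(output_fn(X[idx]))
    else:
        y[:] = [float(output_fn(x)) for x in X]
    if not np.all(np.isfinite(y)):
        raise ValueError("output function returned non-finite values")
    N = n_base
    fA, fB = y[:N], y[N:2 * N]
    fAB = y[2 * N:].reshape(dim, N)
    return _sobol_from_evals(fA, fB, fAB, names, ranges, seed, n_boot,
                             len(y))


def _sobol_from_evals(fA, fB, fAB, names, ranges, seed, n_boot, nev):
    N = len(fA)
    dim = fAB.shape[0]

    def estimate(idx):
        a, b, ab = fA[idx], fB[idx], fAB[:, idx]
        var = np.var(np.concatenate([a, b]), ddof=0)
        if var < 1e-30:
            return np.zeros(dim), np.zeros(dim), True
        S1 = np.mean(b * (ab - a[None, :]), axis=1) / var
        ST = 0.5 * np.mean((a[None, :] - ab) ** 2, axis=1) / var
        return S1, ST, False

    S1, ST, degen = estimate(np.arange(N))
    rng = np.random.default_rng(seed + 1)
    if degen or n_boot <= 0:
        c1 = cT = np.zeros(dim)
    else:
        s1s, sts = [], []
        for _ in range(n_boot):
            idx = rng.integers(0, N, N)
            s1, st, d = estimate(idx)
            if not d:
                s1s.append(s1)
                sts.append(st)
        c1 = 1.96 * np.std(np.array(s1s), axis=0)
        cT = 1.96 * np.std(np.array(sts), axis=0)
    return SobolResult(S1=S1, ST=ST, S1_conf=c1, ST_conf=cT,
                       names=tuple(names), n_base=N, ranges=tuple(ranges),
                       seed=seed, n_evaluations=nev, degenerate=degen)
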