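"""Equilibrium branches, Hopf detection, limit-cycle envelopes, 2-parameter scans.

The oscillatory regimes of the model are organized by Hopf bifurcations: an
equilibrium loses stability when a complex-conjugate eigenvalue pair of the
Jacobian crosses the imaginary axis, and a "Hopf bubble" is a parameter
window bounded by two such crossings inside which limit cycles exist.  The
machinery here scans an equilibrium branch on a grid (natural-parameter
continuation with Newton), watches the leading complex pair, and refines
each axis crossing by bisection.  Dose is always treated in frozen mode
(constant drive) so the scanned systems are autonomous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .dynamics import ROOT_TOL, plc_g_equilibrium
from .model_core import DoseParams, InjectionProtocol, make_rhs, make_rhs_subsystem

__all__ = [
    "EquilibriumBranch",
    "HopfPoint",
    "OrbitEnvelope",
    "ParametricSystem",
    "make_system",
    "jacobian_fd",
    "equilibrium_branch",
    "find_hopf",
    "orbit_envelope",
    "two_parameter_hopf",
    "bubble_boundary",
]

SYSTEMS = ("reduced_cy", "subsystem_cyp", "full_frozen")

#: imaginary parts below this are treated as real eigenvalues
IMAG_TOL = 1e-10
#: refinement target for |Re| of the crossing pair
HOPF_RE_TOL = 1e-8
#: envelope width above which a point is classified oscillatory (uM)
AMP_THRESHOLD = 1e-3


def jacobian_fd(f, x: np.ndarray, rel_step: float = 1e-7) -> np.ndarray:
    """Jacobian of ``f`` at ``x`` by central finite differences."""
    x = np.asarray(x, dtype=float)
    n = x.size
    J = np.empty((n, n))
    for i in range(n):
        h = rel_step * max(abs(x[i]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (f(xp) - f(xm)) / (2.0 * h)
    return J


def leading_complex_real(eigvals: np.ndarray) -> float:
    """Max real part over complex-conjugate eigenvalue pairs (-inf if none)."""
    cplx = eigvals[np.abs(eigvals.imag) > IMAG_TOL]
    return float(np.max(cplx.real)) if cplx.size else -np.inf


class ParametricSystem:
    """An autonomous system with one scalar parameter exposed for scanning.

    ``rhs_at(value)`` returns the vector field ``f(x)`` with the scanned
    parameter set to ``value``.  The scanned parameter may be a kinetic
    constant, the frozen dose ``a``, the constant IP3 level ``p`` of the
    reduced (c, y) model, or the constant ``PLC`` of the (c, y, p)
    subsystem.
    """

    def __init__(self, system: str, params: DoseParams, proto: InjectionProtocol,
                 param_name: str):
        if system not in SYSTEMS:
            raise ValueError(f"system must be one of {SYSTEMS}, got {system!r}")
        self.system = system
        self.params = params
        self.proto = replace(proto, frozen=True)
        self.param_name = param_name
        self.dim = {"reduced_cy": 2, "subsystem_cyp": 3, "full_frozen": 5}[system]
        fixed_names = {"reduced_cy": ("p",), "subsystem_cyp": ("PLC",)}.get(system, ())
        is_kinetic = param_name in {f for f in params.to_dict()}
        if not (is_kinetic or param_name == "a" or param_name in fixed_names):
            raise ValueError(
                f"cannot scan {param_name!r} in system {system!r}"
            )

    def _resolve(self, value: float):
        params, proto = self.params, self.proto
        fixed = None
        if self.param_name == "a":
            proto = replace(proto, a=value)
        elif self.param_name in ("p", "PLC") and self.param_name in (
            ("p",) if self.system == "reduced_cy" else ("PLC",)
        ):
            fixed = value
        else:
            params = params.with_updates(**{self.param_name: value})
        return params, proto, fixed

    def rhs_at(self, value: float, fixed_default: float | None = None):
        params, proto, fixed = self._resolve(value)
        if self.system == "full_frozen":
            f5 = make_rhs(params, proto)
            return lambda x: f5(0.0, x)
        if self.system == "subsystem_cyp":
            plc = fixed if fixed is not None else fixed_default
            if plc is None:
                raise ValueError("subsystem_cyp needs a PLC level")
            f3 = make_rhs_subsystem(plc, params, proto)
            return lambda x: f3(0.0, x)
        p_level = fixed if fixed is not None else fixed_default
        if p_level is None:
            raise ValueError("reduced_cy needs an IP3 level")
        from .model_core import rhs_reduced_cy

        return lambda x: rhs_reduced_cy(0.0, x, p_level, params)

    @staticmethod
    def is_physical(x: np.ndarray) -> bool:
        return _physical(x)

    def default_seed(self, value: float) -> np.ndarray:
        if self.system == "full_frozen":
            params, proto, _ = self._resolve(value)
            plc0, g0 = plc_g_equilibrium(params, proto.a)
            return np.array([0.05, 0.5, 0.1, plc0, g0])
        if self.system == "subsystem_cyp":
            return np.array([0.05, 0.5, 0.1])
        return np.array([0.05, 0.5])


def make_system(system: str, params: DoseParams, proto: InjectionProtocol,
                param_name: str) -> ParametricSystem:
    return ParametricSystem(system, params, proto, param_name)


@dataclass(frozen=True)
class EquilibriumBranch:
    """Equilibria and their Jacobian spectra along a one-parameter grid."""

    param_name: str
    param_values: np.ndarray
    equilibria: np.ndarray       # (n, dim)
    eigenvalues: np.ndarray      # (n, dim), complex
    stable: np.ndarray           # (n,), bool
    system: ParametricSystem
    fixed_default: float | None = None

    def __len__(self) -> int:
        return self.param_values.size


@dataclass(frozen=True)
class HopfPoint:
    """A refined imaginary-axis crossing of a complex-conjugate pair."""

    param_value: float
    frequency: float             # |Im| of the crossing pair (rad/s)
    bracket: tuple[float, float]  # grid interval that contained the crossing


@dataclass(frozen=True)
class OrbitEnvelope:
    """Attractor extrema of c along a parameter grid."""

    param_values: np.ndarray
    c_max: np.ndarray
    c_min: np.ndarray
    oscillatory: np.ndarray      # bool per grid point
    failed: np.ndarray           # bool per grid point (solver failure)


def _physical(x: np.ndarray) -> bool:
    """Reject non-physical roots (negative concentrations, y outside [0, 1])."""
    if not np.all(np.isfinite(x)):
        return False
    if x[0] <= 0.0 or not (0.0 <= x[1] <= 1.0):
        return False
    if x.size >= 3 and x[2] < 0.0:
        return False
    return True


def _newton(f, x0: np.ndarray, tol: float = ROOT_TOL,
            maxit: int = 60, guard=None) -> np.ndarray | None:
    """Damped Newton iteration with a backtracking line search."""
    ok = guard if guard is not None else (lambda x: True)
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(maxit):
        fx = f(x)
        n0 = np.linalg.norm(fx)
        if n0 < tol:
            return x if ok(x) else None
        try:
            dx = np.linalg.solve(jacobian_fd(f, x), -fx)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        for _ in range(40):
            xn = x + lam * dx
            if np.linalg.norm(f(xn)) < n0:
                break
            lam *= 0.5
        else:
            return None
        x = xn
    return x if (np.linalg.norm(f(x)) < tol and ok(x)) else None


def _solve_equilibrium(f, seed: np.ndarray, relax: bool = True,
                       guard=None) -> np.ndarray | None:
    x = _newton(f, seed, guard=guard)
    if x is not None:
        return x
    sol = root(f, seed, method="hybr")
    if sol.success:
        x = _newton(f, sol.x, maxit=10, guard=guard)
        if x is not None:
            return x
    if relax:
        ivp = solve_ivp(lambda t, z: f(z), (0.0, 5000.0), seed,
                        method="LSODA", rtol=1e-8, atol=1e-10)
        if ivp.success:
            x = _newton(f, ivp.y[:, -1], guard=guard)
            if x is not None:
                return x
    return None


def _substep(ps: "ParametricSystem", fixed_default, v_from: float, v_to: float,
             x_from: np.ndarray, max_depth: int = 14) -> np.ndarray | None:
    """Walk the parameter from ``v_from`` to ``v_to`` with step halving.

    Used when a single continuation step is too large for Newton to follow
    the branch (the equilibrium can move rapidly at small PLC levels).
    """
    dv = v_to - v_from
    n_sub = 2
    for _ in range(max_depth):
        x = x_from
        ok = True
        for j in range(1, n_sub + 1):
            f = ps.rhs_at(v_from + dv * j / n_sub, fixed_default)
            x_next = _newton(f, x, guard=getattr(ps, "is_physical", None))
            if x_next is None:
                ok = False
                break
            x = x_next
        if ok:
            return x
        n_sub *= 2
    return None


def equilibrium_branch(
    system: str,
    params: DoseParams,
    proto: InjectionProtocol,
    param_name: str,
    grid: np.ndarray,
    fixed_default: float | None = None,
    seed: np.ndarray | None = None,
) -> EquilibriumBranch:
    """Continue an equilibrium along ``grid`` and record its spectrum.

    Natural-parameter continuation: each point is Newton-solved from the
    previous solution (the first from a low-calcium seed, with a relaxation
    fallback).  Newton divergence truncates the branch with a warning.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D, nonempty and strictly increasing")
    ps = make_system(system, params, proto, param_name)
    xs, eigs, stab, kept = [], [], [], []
    x_prev = seed if seed is not None else ps.default_seed(grid[0])
    v_prev: float | None = None
    for k, value in enumerate(grid):
        f = ps.rhs_at(value, fixed_default)
        x = _solve_equilibrium(f, x_prev, relax=(k == 0),
                               guard=getattr(ps, "is_physical", None))
        if x is None and v_prev is not None:
            x = _substep(ps, fixed_default, v_prev, value, x_prev)
        if x is None:
            warnings.warn(
                f"equilibrium continuation diverged at {param_name}={value}; "
                f"branch truncated after {len(xs)} points"
            )
            break
        ev = np.linalg.eigvals(jacobian_fd(f, x))
        xs.append(x)
        eigs.append(ev)
        stab.append(bool(np.max(ev.real) < 0.0))
        kept.append(value)
        x_prev = x
        v_prev = value
    return EquilibriumBranch(
        param_name=param_name,
        param_values=np.array(kept),
        equilibria=np.array(xs),
        eigenvalues=np.array(eigs),
        stable=np.array(stab, dtype=bool),
        system=ps,
        fixed_default=fixed_default,
    )


def _complex_real_at(branch: EquilibriumBranch, value: float,
                     seed: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(Re, |Im|, equilibrium) of the leading complex pair at one parameter value."""
    f = branch.system.rhs_at(value, branch.fixed_default)
    x = _solve_equilibrium(f, seed, relax=False,
                           guard=getattr(branch.system, "is_physical", None))
    if x is None:
        raise RuntimeError(f"equilibrium lost during Hopf refinement at {value}")
    ev = np.linalg.eigvals(jacobian_fd(f, x))
    cplx = ev[np.abs(ev.imag) > IMAG_TOL]
    if cplx.size == 0:
        # the pair has collapsed to real eigenvalues on this side of the
        # crossing; report -inf so bisection treats it as the stable side
        return -np.inf, np.nan, x
    lead = cplx[np.argmax(cplx.real)]
    return float(lead.real), float(abs(lead.imag)), x


def find_hopf(branch: EquilibriumBranch) -> list[HopfPoint]:
    """Locate Hopf bifurcations along a branch.

    Detects sign changes of the real part of the leading complex-conjugate
    eigenvalue pair between adjacent grid points and bisects each to
    |Re| < 1e-8.  Real-eigenvalue crossings (saddle-node type) do not
    register because only complex pairs are tracked.
    """
    if len(branch) < 2:
        return []
    re = np.array([leading_complex_real(ev) for ev in branch.eigenvalues])
    # a missing complex pair (-inf) counts as the stable side: the pair can
    # collapse to real eigenvalues before the grid point on one flank
    points: list[HopfPoint] = []
    for k in range(len(branch) - 1):
        r0, r1 = re[k], re[k + 1]
        neg0, neg1 = (r0 < 0.0), (r1 < 0.0)
        if np.isnan(r0) or np.isnan(r1) or r0 == 0.0 or neg0 == neg1:
            continue
        lo, hi = branch.param_values[k], branch.param_values[k + 1]
        x_lo = branch.equilibria[k].copy()
        x_hi = branch.equilibria[k + 1].copy()
        neg_lo = neg0
        freq = np.nan
        last_freq = np.nan
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            seed = 0.5 * (x_lo + x_hi)
            r_mid, freq, x_mid = _complex_real_at(branch, mid, seed)
            if np.isfinite(freq):
                last_freq = freq
            if (np.isfinite(r_mid) and abs(r_mid) < HOPF_RE_TOL) \
                    or (hi - lo) < 1e-15 * max(1.0, abs(mid)):
                lo = hi = mid
                break
            if (r_mid < 0.0) != neg_lo:
                hi, x_hi = mid, x_mid
            else:
                lo, x_lo, neg_lo = mid, x_mid, (r_mid < 0.0)
        points.append(HopfPoint(
            param_value=0.5 * (lo + hi),
            frequency=freq if np.isfinite(freq) else last_freq,
            bracket=(float(branch.param_values[k]), float(branch.param_values[k + 1])),
        ))
    return points


def orbit_envelope(
    system: str,
    params: DoseParams,
    proto: InjectionProtocol,
    param_name: str,
    grid: np.ndarray,
    t_transient: float = 500.0,
    t_window: float = 500.0,
    fixed_default: float | None = None,
    amp_threshold: float = AMP_THRESHOLD,
) -> OrbitEnvelope:
    """Attractor extrema of c over the grid.

    Each point integrates from a small perturbation off the continued
    equilibrium, discards ``t_transient`` seconds, then records min/max of c
    over ``t_window``.  Solver failures flag the point without aborting the
    scan.
    """
    if t_transient <= 0 or t_window <= 0:
        raise ValueError("t_transient and t_window must be positive")
    branch = equilibrium_branch(system, params, proto, param_name, grid,
                                fixed_default=fixed_default)
    n = len(branch)
    c_max = np.full(n, np.nan)
    c_min = np.full(n, np.nan)
    failed = np.zeros(n, dtype=bool)
    for k in range(n):
        f = branch.system.rhs_at(branch.param_values[k], fixed_default)
        x0 = branch.equilibria[k] * 1.0
        x0[0] = x0[0] * 1.02 + 1e-4  # nudge c off the fixed point
        try:
            sol = solve_ivp(lambda t, z: f(z), (0.0, t_transient + t_window), x0,
                            method="LSODA", rtol=1e-8, atol=1e-10,
                            dense_output=False, max_step=np.inf,
                            t_eval=np.linspace(t_transient, t_transient + t_window,
                                               max(2000, int(t_window / 0.05))))
            if not sol.success:
                raise RuntimeError(sol.message)
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            warnings.warn(f"orbit integration failed at "
                          f"{param_name}={branch.param_values[k]}: {exc}")
            failed[k] = True
            continue
        c = sol.y[0]
        c_max[k] = c.max()
        c_min[k] = c.min()
    osc = (c_max - c_min) > amp_threshold
    osc[failed] = False
    return OrbitEnvelope(param_values=branch.param_values, c_max=c_max,
                         c_min=c_min, oscillatory=osc, failed=failed)


def two_parameter_hopf(
    system: str,
    params: DoseParams,
    proto: InjectionProtocol,
    p1_name: str,
    p1_grid: np.ndarray,
    p2_name: str,
    p2_grid: np.ndarray,
    fixed_default: float | None = None,
) -> list[tuple[float, list[HopfPoint]]]:
    """Track Hopf locations in ``p1`` as a second parameter ``p2`` varies.

    Returns one entry per p2 value: ``(p2_value, hopf points in p1)``.  The
    set of (p1, p2) pairs traces the boundary of the oscillation region.
    """
    p2_grid = np.asarray(p2_grid, dtype=float)
    curve: list[tuple[float, list[HopfPoint]]] = []
    for v2 in p2_grid:
        if p2_name == "a":
            params2, proto2 = params, replace(proto, a=v2, frozen=True)
        else:
            params2, proto2 = params.with_updates(**{p2_name: v2}), proto
        branch = equilibrium_branch(system, params2, proto2, p1_name, p1_grid,
                                    fixed_default=fixed_default)
        curve.append((float(v2), find_hopf(branch)))
    return curve


def bubble_boundary(
    system: str,
    params: DoseParams,
    proto: InjectionProtocol,
    scan_name: str,
    scan_grid: np.ndarray,
    ctrl_name: str,
    ctrl_inside: float,
    ctrl_outside: float,
    target_count: int = 2,
    xtol: float = 1e-4,
    fixed_default: float | None = None,
) -> float:
    """Bisect a control parameter to the edge of the two-Hopf (bubble) region.

    ``ctrl_inside`` must produce exactly ``target_count`` Hopf points in the
    scan window and ``ctrl_outside`` must not; the returned value is the
    control-parameter boundary to within ``xtol``.
    """

    def count(ctrl_value: float) -> int:
        if ctrl_name == "a":
            params2, proto2 = params, replace(proto, a=ctrl_value, frozen=True)
        else:
            params2 = params.with_updates(**{ctrl_name: ctrl_value})
            proto2 = proto
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            branch = equilibrium_branch(system, params2, proto2, scan_name,
                                        scan_grid, fixed_default=fixed_default)
            return len(find_hopf(branch))

    if count(ctrl_inside) != target_count:
        raise ValueError(f"{ctrl_name}={ctrl_inside} is not inside the bubble region")
    if count(ctrl_outside) == target_count:
        raise ValueError(f"{ctrl_name}={ctrl_outside} is not outside the bubble region")
    lo, hi = ctrl_inside, ctrl_outside
    while abs(hi - lo) > xtol:
        mid = 0.5 * (lo + hi)
        if count(mid) == target_count:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
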