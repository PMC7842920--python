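"""Steady states, forward integration, output scaling and peak metrics."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model_core import (
    CellState,
    DoseParams,
    InjectionProtocol,
    gprotein_drive,
    make_rhs,
)

__all__ = [
    "Trace",
    "ScalingParams",
    "PeakMetrics",
    "plc_g_equilibrium",
    "steady_state",
    "integrate",
    "scale_trace",
    "peak_metrics",
]

STATE_COLUMNS = ("c", "y", "p", "PLC", "G")

#: residual tolerance for an accepted equilibrium
ROOT_TOL = 1e-10


@dataclass(frozen=True)
class Trace:
    """A time-gridded solution of the model.

    ``states`` has one row per grid point, columns (c, y, p, PLC, G).
    ``c_scaled`` holds the indicator-scaled signal (c - c0)/K_D once
    :func:`scale_trace` has been applied.
    """

    t: np.ndarray
    states: np.ndarray
    c_scaled: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        states = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "states", states)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be 1-D and strictly increasing")
        if states.shape != (t.size, 5):
            raise ValueError(f"states must have shape ({t.size}, 5), got {states.shape}")
        if not np.all(np.isfinite(states)):
            raise ValueError("non-finite values in states")
        if self.c_scaled is not None:
            cs = np.asarray(self.c_scaled, dtype=float)
            object.__setattr__(self, "c_scaled", cs)
            if cs.shape != t.shape:
                raise ValueError("c_scaled must match the time grid")

    @property
    def c(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def p(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def PLC(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def G(self) -> np.ndarray:
        return self.states[:, 4]

    def signal(self, which: str) -> np.ndarray:
        if which == "c_scaled":
            if self.c_scaled is None:
                raise ValueError("trace has no scaled signal; apply scale_trace first")
            return self.c_scaled
        if which in STATE_COLUMNS:
            return self.states[:, STATE_COLUMNS.index(which)]
        raise ValueError(f"unknown signal {which!r}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_COLUMNS))
        df.insert(0, "t", self.t)
        if self.c_scaled is not None:
            df["c_scaled"] = self.c_scaled
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path)
        states = df[list(STATE_COLUMNS)].to_numpy()
        cs = df["c_scaled"].to_numpy() if "c_scaled" in df else None
        return cls(t=df["t"].to_numpy(), states=states, c_scaled=cs)


@dataclass(frozen=True)
class ScalingParams:
    """Fluorescence indicator constants used to map Ca2+ to the recorded signal.

    ``K_D`` is the indicator dissociation constant (uM), ``c0`` the resting
    Ca2+ (uM), ``R_f = f_max/f_min`` the dynamic range, ``f_m = f_max/f_0``,
    and ``df_max`` the indicator saturation level of the relative
    fluorescence change; if not given it is computed from the saturation
    relation df_max = (1 - 1/R_f)/(1/R_f + c0/K_D).
    """

    K_D: float = 0.3
    c0: float = 0.05
    R_f: float = 100.0
    f_m: float = 40.0
    df_max: float | None = None

    def __post_init__(self) -> None:
        if self.K_D <= 0 or self.c0 <= 0 or self.f_m <= 0:
            raise ValueError("K_D, c0 and f_m must be positive")
        if self.R_f <= 1:
            raise ValueError(f"R_f must exceed 1, got {self.R_f}")
        if self.df_max is None:
            dfm = (1.0 - 1.0 / self.R_f) / (1.0 / self.R_f + self.c0 / self.K_D)
            object.__setattr__(self, "df_max", dfm)
        elif self.df_max <= 0:
            raise ValueError(f"df_max must be positive, got {self.df_max}")


@dataclass(frozen=True)
class PeakMetrics:
    """Location and height of the global maximum of a trace signal."""

    peak_value: float
    peak_time: float   # seconds, on the trace grid
    latency: float     # peak_time - t1, seconds
    constant: bool = False  # True when the trace never moves (no real peak)


def plc_g_equilibrium(params: DoseParams, q: float) -> tuple[float, float]:
    """Closed-form equilibrium of the PLC / G-protein pair at constant drive q.

    G* = k_c (rho + delta) G_tot / (k_c (rho + delta) + k_d) with
    rho = V_R q / (K_R + q), and PLC* = k_a G* PLC_tot / (k_a G* + k_b).
    """
    rho = gprotein_drive(q, params)
    g = params.k_c * (rho + params.delta) * params.G_tot / (
        params.k_c * (rho + params.delta) + params.k_d
    )
    plc = params.k_a * g * params.PLC_tot / (params.k_a * g + params.k_b)
    return plc, g


def steady_state(
    params: DoseParams,
    q_frozen: float = 0.0,
    with_stability: bool = False,
):
    """Equilibrium of the five-variable system at constant drive ``q_frozen``.

    The PLC and G components come from their closed forms; the (c, y, p)
    components are found by a Newton solve seeded from a low-calcium start,
    falling back to a long integration when Newton alone does not converge.
    When the equilibrium is inside an oscillatory (Hopf) window the returned
    fixed point is unstable; request ``with_stability`` to get the flag from
    the Jacobian spectrum.
    """
    if q_frozen < 0:
        raise ValueError("q_frozen must be non-negative")
    proto = InjectionProtocol(a=q_frozen, frozen=True)
    f = make_rhs(params, proto)
    plc0, g0 = plc_g_equilibrium(params, q_frozen)
    x0 = np.array([0.05, 0.5, 0.1, plc0, g0])

    def try_root(seed):
        sol = root(lambda x: f(0.0, x), seed, method="hybr", tol=1e-13)
        return sol.x if sol.success else None

    x = try_root(x0)
    if x is None or np.linalg.norm(f(0.0, x)) > ROOT_TOL:
        # fall back: relax toward the attractor, then polish with Newton
        ivp = solve_ivp(f, (0.0, 5000.0), x0, method="LSODA",
                        rtol=1e-8, atol=1e-10, dense_output=False)
        if not ivp.success:
            raise RuntimeError(f"relaxation integration failed: {ivp.message}")
        x = try_root(ivp.y[:, -1])
        if x is None or np.linalg.norm(f(0.0, x)) > ROOT_TOL:
            raise RuntimeError(
                "steady-state solve did not converge: residual "
                f"{None if x is None else np.linalg.norm(f(0.0, x))}"
            )
    state = CellState.from_array(x)
    if not with_stability:
        return state
    from .bifurcation import jacobian_fd  # local import to avoid a cycle

    eig = np.linalg.eigvals(jacobian_fd(lambda z: f(0.0, z), x))
    return state, bool(np.max(eig.real) < 0.0)


def integrate(
    params: DoseParams,
    proto: InjectionProtocol,
    t_end: float,
    dt_out: float = 0.1,
    initial: CellState | str = "auto",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trace:
    """Solve the five-ODE system on [0, t_end], sampled every ``dt_out``.

    ``initial="auto"`` starts from the zero-dose steady state, mirroring how
    published simulations are initialized.  The integration is restarted at
    the injection time t1 so the adaptive stepper never straddles the
    discontinuity of the drive.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if initial == "auto":
        x0 = steady_state(params, 0.0).as_array()
    elif isinstance(initial, CellState):
        initial.validate(params)
        x0 = initial.as_array()
    else:
        x0 = np.asarray(initial, dtype=float)
        if x0.shape != (5,):
            raise ValueError("initial must be 'auto', a CellState, or length-5")

    f = make_rhs(params, proto)
    t_grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_grid = t_grid[t_grid <= t_end + 1e-12]

    segments: list[tuple[float, float]] = []
    if not proto.frozen and 0.0 < proto.t1 < t_end:
        segments = [(0.0, proto.t1), (proto.t1, t_end)]
    else:
        segments = [(0.0, t_end)]

    out = np.empty((t_grid.size, 5))
    filled = np.zeros(t_grid.size, dtype=bool)
    x_start = x0
    for (ta, tb) in segments:
        mask = (t_grid >= ta - 1e-12) & (t_grid <= tb + 1e-12) & ~filled
        # evaluate at the grid points plus the segment end for the restart
        t_eval = np.union1d(t_grid[mask], [tb])
        sol = solve_ivp(f, (ta, tb), x_start, method=method,
                        rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(
                f"integration failed on [{ta}, {tb}]: {sol.message}; "
                f"last state {x_start}"
            )
        keep = np.isin(sol.t, t_grid[mask])
        out[mask] = sol.y.T[keep]
        filled |= mask
        x_start = sol.y[:, -1]
    return Trace(t=t_grid, states=out)


def scale_trace(trace: Trace, scaling: ScalingParams) -> Trace:
    """Attach the indicator-scaled signal c_s = (c - c0)/K_D to a trace."""
    cs = (trace.c - scaling.c0) / scaling.K_D
    return replace(trace, c_scaled=cs)


def peak_metrics(trace: Trace, signal: str = "c", t1: float = 0.0) -> PeakMetrics:
    """Global maximum of the chosen signal; ties resolve to the earliest time."""
    values = trace.signal(signal)
    if values.size == 0:
        raise ValueError("empty trace")
    idx = int(np.argmax(values))
    constant = bool(np.all(values == values[0]))
    return PeakMetrics(
        peak_value=float(values[idx]),
        peak_time=float(trace.t[idx]),
        latency=float(trace.t[idx] - t1),
        constant=constant,
    )
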