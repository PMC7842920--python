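"""Core definitions of the closed-cell Ca2+ model driven by intracellular amyloid-beta.

The model tracks five variables: cytosolic free Ca2+ ``c`` (uM), the
proportion of inactivated IP3 receptors ``y``, cytosolic IP3 ``p`` (uM), the
fraction of activated phospholipase C ``PLC``, and the fraction of activated
G-protein ``G``.  Ca2+ exchanges only between cytosol and ER (closed cell):
release through IP3 receptors (Li-Rinzel open-probability kinetics) plus a
passive ER leak, and reuptake through a degree-2 Hill SERCA pump.  IP3 is
produced by active PLC with Ca2+ feedback and degraded by a 3-kinase /
5-phosphatase pair.  Injected amyloid-beta oligomers act upstream: they
behave as a G-protein agonist and raise the maximal rate of PLC-mediated
IP3 production.

This module holds parameter/state containers and all right-hand-side
functions; solvers and analysis live in :mod:`calbeta.dynamics` and
:mod:`calbeta.bifurcation`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields, replace
from importlib import resources

import numpy as np

__all__ = [
    "DoseParams",
    "InjectionProtocol",
    "CellState",
    "DerivedIP3Consts",
    "PARAM_GROUPS",
    "abeta_drive",
    "gprotein_drive",
    "plc_max_rate",
    "ipr_open_probability",
    "serca_flux",
    "er_calcium",
    "rhs_full",
    "rhs_reduced_cy",
    "rhs_subsystem_cyp",
    "make_rhs",
    "make_rhs_subsystem",
]


@dataclass(frozen=True)
class DoseParams:
    """One full kinetic parameter set of the closed-cell model.

    Rates are per second, concentrations in uM, amyloid-beta affinities in
    ug/ml.  Two named constructors, :meth:`small_doses` and
    :meth:`large_doses`, give the published regimes for injections of
    a <= 1 ug/ml and a > 1 ug/ml respectively.
    """

    # cellular
    k_f: float      # maximal Ca2+ release rate through IP3Rs (1/s)
    J_ER: float     # passive ER leak (1/s)
    gamma: float    # cytoplasm/ER volume ratio
    c_t: float      # total Ca2+ over cytoplasmic volume (uM)
    # SERCA
    V_s: float      # maximal SERCA pump rate (uM/s)
    K_s: float      # SERCA half-activation (uM)
    # IP3 receptor (Li-Rinzel / De Young-Keizer constants)
    K1: float       # (1/uM)
    K2: float       # (1/uM)
    K3: float       # (1/uM)
    K4: float       # (1/uM)
    K5: float       # (1/uM)
    k_m2: float     # (1/s)
    k_m4: float     # (1/s)
    # IP3 production and degradation
    V_0: float      # intrinsic PLC-mediated IP3 production (uM)
    V_Q: float      # amyloid-beta influence on IP3 production (uM)
    K_Q: float      # PLC dissociation constant for the A-beta drive (ug/ml)
    K_ip3k: float   # 3-kinase half-activation (uM)
    K_PLC: float    # PLC sensitivity to Ca2+ (uM)
    k_3k: float     # IP3 phosphorylation rate (1/s)
    k_5p: float     # IP3 dephosphorylation rate (1/s)
    # PLC activation
    k_a: float      # PLC activation rate (1/s)
    k_b: float      # PLC deactivation rate (1/s)
    PLC_tot: float  # total PLC fraction
    # G-protein activation
    k_c: float      # G-protein activation rate (1/s)
    k_d: float      # G-protein deactivation rate (1/s)
    delta: float    # intrinsic (background) G-protein activity
    V_R: float      # maximal G-protein activation
    K_R: float      # A-beta concentration producing half-activation (ug/ml)
    G_tot: float    # total G-protein fraction

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v}")
            if f.name != "delta" and v <= 0:
                raise ValueError(f"parameter {f.name} must be positive, got {v}")
        if self.delta < 0:
            raise ValueError(f"delta must be non-negative, got {self.delta}")

    @classmethod
    def small_doses(cls) -> "DoseParams":
        """Published parameter regime for small injections (a <= 1 ug/ml)."""
        return cls.from_config("small_doses")

    @classmethod
    def large_doses(cls) -> "DoseParams":
        """Published parameter regime for large injections (a > 1 ug/ml)."""
        return cls.from_config("large_doses")

    @classmethod
    def from_config(cls, name_or_path: str) -> "DoseParams":
        """Load a parameter set from a packaged fixture name or a JSON path."""
        pkg_files = resources.files("calbeta") / "data" / f"{name_or_path}.json"
        if pkg_files.is_file():
            payload = json.loads(pkg_files.read_text())
        else:
            with open(name_or_path) as fh:
                payload = json.load(fh)
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, d: dict) -> "DoseParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        missing = known - set(d)
        if missing:
            raise KeyError(f"missing parameter names: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_updates(self, **updates: float) -> "DoseParams":
        return replace(self, **updates)

    @property
    def derived_ip3(self) -> "DerivedIP3Consts":
        return DerivedIP3Consts.from_rates(self.k_3k, self.k_5p)


#: Table-style grouping of the kinetic parameters by cellular mechanism,
#: used by subset fits and sensitivity scans.
PARAM_GROUPS: dict[str, tuple[str, ...]] = {
    "Cellular": ("k_f", "J_ER", "gamma", "c_t"),
    "SERCA": ("V_s", "K_s"),
    "IP3Receptor": ("K1", "K2", "K3", "K4", "K5", "k_m2", "k_m4"),
    "IP3Model": ("V_0", "V_Q", "K_Q", "K_ip3k", "K_PLC", "k_3k", "k_5p"),
    "PLC": ("k_a", "k_b", "PLC_tot"),
    "GProtein": ("k_c", "k_d", "delta", "V_R", "K_R", "G_tot"),
}


@dataclass(frozen=True)
class DerivedIP3Consts:
    """Characteristic IP3 turnover time and kinase fraction."""

    tau_p: float  # 1/(k_3k + k_5p), seconds
    eta: float    # k_3k/(k_3k + k_5p), in (0, 1)

    @classmethod
    def from_rates(cls, k_3k: float, k_5p: float) -> "DerivedIP3Consts":
        total = k_3k + k_5p
        return cls(tau_p=1.0 / total, eta=k_3k / total)


@dataclass(frozen=True)
class InjectionProtocol:
    """Amyloid-beta forcing: dose ``a`` injected at ``t1`` decaying at rate ``r``.

    With ``frozen=True`` the drive is held constant at ``a`` for all times,
    which makes the five-ODE system autonomous; bifurcation analysis uses
    this mode.
    """

    a: float = 0.0      # injected dose (ug/ml)
    t1: float = 2.0     # injection time (s)
    r: float = 0.001    # decay rate (1/s)
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"dose a must be non-negative, got {self.a}")
        if self.r < 0:
            raise ValueError(f"decay rate r must be non-negative, got {self.r}")


@dataclass(frozen=True)
class CellState:
    """The five dynamical variables of the closed-cell model."""

    c: float    # cytosolic free Ca2+ (uM)
    y: float    # proportion of inactivated IP3Rs, in [0, 1]
    p: float    # cytosolic IP3 (uM)
    PLC: float  # fraction of activated PLC, in [0, PLC_tot]
    G: float    # fraction of activated G-protein, in [0, G_tot]

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.y, self.p, self.PLC, self.G])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "CellState":
        return cls(*map(float, x))

    def validate(self, params: DoseParams) -> None:
        """Check physical admissibility against a parameter set."""
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError(f"non-finite state: {self}")
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")
        if self.c > params.c_t:
            raise ValueError(
                f"c = {self.c} exceeds total Ca2+ c_t = {params.c_t}; "
                "implied ER Ca2+ would be negative"
            )
        if not 0.0 <= self.y <= 1.0:
            raise ValueError(f"y must lie in [0, 1], got {self.y}")
        if self.p < 0:
            raise ValueError(f"p must be non-negative, got {self.p}")
        if not 0.0 <= self.PLC <= params.PLC_tot:
            raise ValueError(f"PLC must lie in [0, {params.PLC_tot}], got {self.PLC}")
        if not 0.0 <= self.G <= params.G_tot:
            raise ValueError(f"G must lie in [0, {params.G_tot}], got {self.G}")


# ---------------------------------------------------------------------------
# algebraic sub-expressions
# ---------------------------------------------------------------------------

def abeta_drive(t, proto: InjectionProtocol):
    """Amyloid-beta drive q(t): zero before injection, exponential decay after.

    In frozen mode the drive is constant at the dose ``a``.
    Accepts scalar or array ``t``.
    """
    if proto.frozen:
        return proto.a if np.isscalar(t) else np.full(np.shape(t), proto.a)
    t = np.asarray(t, dtype=float)
    q = np.where(t >= proto.t1, proto.a * np.exp(-proto.r * (t - proto.t1)), 0.0)
    return float(q) if q.ndim == 0 else q


def gprotein_drive(q, params: DoseParams):
    """G-protein production term rho = V_R q / (K_R + q); saturates at V_R."""
    return params.V_R * q / (params.K_R + q)


def plc_max_rate(q, params: DoseParams):
    """Maximal PLC-mediated IP3 production V_PLC = V_0 + V_Q q^2/(K_Q^2 + q^2)."""
    q2 = np.square(q)
    return params.V_0 + params.V_Q * q2 / (params.K_Q**2 + q2)


def ipr_open_probability(c, y, p, params: DoseParams):
    """Li-Rinzel open probability of the IP3 receptor.

    P_o = [p c (1 - y) / ((p + K1)(c + K5))]^3, in [0, 1].
    """
    return (p * c * (1.0 - y) / ((p + params.K1) * (c + params.K5))) ** 3


def serca_flux(c, params: DoseParams):
    """SERCA reuptake flux, a Hill function of degree two in c."""
    c2 = np.square(c)
    return params.V_s * c2 / (params.K_s**2 + c2)


def er_calcium(c, params: DoseParams):
    """ER Ca2+ implied by closed-cell conservation: c_e = gamma (c_t - c)."""
    if np.any(np.asarray(c) > params.c_t):
        raise ValueError(f"c exceeds total Ca2+ c_t = {params.c_t}")
    return params.gamma * (params.c_t - c)


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def make_rhs(params: DoseParams, proto: InjectionProtocol):
    """Return a fast ``f(t, x)`` closure for the five-variable system.

    ``x = (c, y, p, PLC, G)``.  All parameters are captured as local floats
    so the closure is cheap enough for ensemble work.
    """
    k_f, J_ER, gamma, c_t = params.k_f, params.J_ER, params.gamma, params.c_t
    V_s, K_s2 = params.V_s, params.K_s**2
    K1, K2, K3, K4, K5 = params.K1, params.K2, params.K3, params.K4, params.K5
    k_m2, k_m4 = params.k_m2, params.k_m4
    V_0, V_Q, K_Q2 = params.V_0, params.V_Q, params.K_Q**2
    K_ip3k2, K_PLC2 = params.K_ip3k**2, params.K_PLC**2
    d = params.derived_ip3
    inv_tau_p, eta = 1.0 / d.tau_p, d.eta
    k_a, k_b, PLC_tot = params.k_a, params.k_b, params.PLC_tot
    k_c, k_d, delta = params.k_c, params.k_d, params.delta
    V_R, K_R, G_tot = params.V_R, params.K_R, params.G_tot
    a, t1, r, frozen = proto.a, proto.t1, proto.r, proto.frozen

    def rhs(t, x):
        c, y, p, PLC, G = x
        if frozen:
            q = a
        elif t >= t1:
            q = a * math.exp(-r * (t - t1))
        else:
            q = 0.0
        c2 = c * c
        P_o = (p * c * (1.0 - y) / ((p + K1) * (c + K5))) ** 3
        dc = (k_f * P_o + J_ER) * (gamma * (c_t - c) - c) - V_s * c2 / (K_s2 + c2)
        dy = ((k_m4 * K1 * K2 + k_m2 * p * K4) * c / (K4 * K2 * (p + K1))) * (1.0 - y) \
            - ((k_m2 * p + k_m4 * K3) / (p + K3)) * y
        V_PLC = V_0 + V_Q * q * q / (K_Q2 + q * q)
        dp = inv_tau_p * (
            V_PLC * PLC * (c2 / (K_PLC2 + c2))
            - (eta * c2 / (K_ip3k2 + c2) + (1.0 - eta)) * p
        )
        dPLC = k_a * G * (PLC_tot - PLC) - k_b * PLC
        rho = V_R * q / (K_R + q)
        dG = k_c * (rho + delta) * (G_tot - G) - k_d * G
        return np.array([dc, dy, dp, dPLC, dG])

    return rhs


def rhs_full(t, state, params: DoseParams, proto: InjectionProtocol) -> np.ndarray:
    """Time derivative of the full five-variable system.

    ``state`` may be a :class:`CellState` or a length-5 array.  The IP3
    equation is returned as dp/dt (the turnover time tau_p already divided
    through).
    """
    x = state.as_array() if isinstance(state, CellState) else np.asarray(state, dtype=float)
    if x.shape != (5,):
        raise ValueError(f"state must have 5 components, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite state: {x}")
    return make_rhs(params, proto)(t, x)


def rhs_reduced_cy(t, cy, p_fixed: float, params: DoseParams | None = None) -> np.ndarray:
    """Two-variable (c, y) model at constant IP3 ``p_fixed``.

    This is the base closed-cell model before IP3/PLC/G-protein dynamics are
    attached; defaults to the published base (small-dose) constants.
    """
    if params is None:
        params = DoseParams.small_doses()
    c, y = cy
    P_o = ipr_open_probability(c, y, p_fixed, params)
    dc = (params.k_f * P_o + params.J_ER) * (params.gamma * (params.c_t - c) - c) \
        - serca_flux(c, params)
    dy = ((params.k_m4 * params.K1 * params.K2 + params.k_m2 * p_fixed * params.K4)
          * c / (params.K4 * params.K2 * (p_fixed + params.K1))) * (1.0 - y) \
        - ((params.k_m2 * p_fixed + params.k_m4 * params.K3) / (p_fixed + params.K3)) * y
    return np.array([dc, dy])


def make_rhs_subsystem(PLC_fixed: float, params: DoseParams, proto: InjectionProtocol):
    """Return ``f(t, (c, y, p))`` for the PLC-driven subsystem.

    The (c, y, p) equations with PLC held constant and the drive frozen at
    the protocol dose; used when PLC is treated as a bifurcation parameter.
    """
    frozen_proto = replace(proto, frozen=True)
    full = make_rhs(params, frozen_proto)

    def rhs(t, cyp):
        x = np.array([cyp[0], cyp[1], cyp[2], PLC_fixed, 0.0])
        return full(t, x)[:3]

    return rhs


def rhs_subsystem_cyp(t, cyp, PLC_fixed: float, params: DoseParams,
                      proto: InjectionProtocol) -> np.ndarray:
    """Time derivative of the (c, y, p) subsystem with PLC as a parameter."""
    return make_rhs_subsystem(PLC_fixed, params, proto)(t, cyp)
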