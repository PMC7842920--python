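"""Least-squares calibration of model parameters to scaled Ca2+ recordings.

The objective is the sum of squared differences between a scaled recording
sed(t_i) and the model's scaled Ca2+ solution interpolated at the data
times, summed over doses when several recordings share one parameter set.
Minimization follows a stochastic scheme: parameter sets are drawn at
random from an admissible space and any draw whose error falls below a
threshold seeds an accept-if-better random walk around it.  No claim of
global optimality is made; the procedure establishes workable parameter
values, not unique ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import ScalingParams, integrate, steady_state
from .model_core import PARAM_GROUPS, DoseParams, InjectionProtocol

__all__ = [
    "ParamSpace",
    "FitResult",
    "simulate_scaled",
    "objective_err",
    "make_objective",
    "random_search",
    "random_walk_refine",
    "fit_subset",
]

#: parameters sampled uniformly within +/-50% (dimensionless fractions);
#: everything else is a rate or affinity and is sampled log-uniformly
DIMENSIONLESS = ("gamma", "PLC_tot", "G_tot", "delta", "V_R")

INFEASIBLE = float("inf")


@dataclass(frozen=True)
class ParamSpace:
    """Sampling rules for a calibration run.

    ``rules`` maps a parameter name to ``(family, lo, hi)`` with family
    "uniform" or "loguniform".  Parameters absent from ``rules`` stay frozen
    at the baseline.
    """

    baseline: DoseParams
    rules: dict[str, tuple[str, float, float]]

    def __post_init__(self) -> None:
        valid = set(self.baseline.to_dict())
        for name, (family, lo, hi) in self.rules.items():
            if name not in valid:
                raise KeyError(f"unknown parameter {name!r}")
            if family not in ("uniform", "loguniform"):
                raise ValueError(f"unknown family {family!r} for {name}")
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}: [{lo}, {hi}]")
            if family == "loguniform" and lo <= 0:
                raise ValueError(f"log-uniform bounds must be positive for {name}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.rules)

    @classmethod
    def default(cls, baseline: DoseParams,
                names: tuple[str, ...] | None = None) -> "ParamSpace":
        """Log-uniform [base/5, base*5] for rates/affinities, uniform +/-50%
        for dimensionless fractions.  A stand-in for unrecoverable published
        sampling distributions; fully overridable."""
        if names is None:
            names = tuple(baseline.to_dict())
        rules = {}
        for name in names:
            base = getattr(baseline, name)
            if name in DIMENSIONLESS:
                rules[name] = ("uniform", 0.5 * base, 1.5 * base)
            else:
                rules[name] = ("loguniform", base / 5.0, base * 5.0)
        return cls(baseline=baseline, rules=rules)

    def sample(self, rng: np.random.Generator) -> DoseParams:
        updates = {}
        for name, (family, lo, hi) in self.rules.items():
            if family == "uniform":
                updates[name] = rng.uniform(lo, hi)
            else:
                updates[name] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        return self.baseline.with_updates(**updates)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a stochastic fit; reproducible from (inputs, seed)."""

    best_params: DoseParams
    best_err: float
    n_evaluated: int
    seed: int
    history: tuple[tuple[float, DoseParams], ...] = field(default_factory=tuple)


def simulate_scaled(
    params: DoseParams,
    proto: InjectionProtocol,
    t_end: float,
    scaling: ScalingParams,
    dt_out: float = 0.5,
    rtol: float = 1e-6,
    atol: float = 1e-9,
):
    """Model run from the zero-dose steady state, scaled relative to rest.

    The scaled signal uses the run's own resting Ca2+ as c0, matching how
    df/f0 recordings are referenced to their own baseline.
    """
    rest = steady_state(params, 0.0)
    trace = integrate(params, proto, t_end, dt_out=dt_out,
                      initial=rest, rtol=rtol, atol=atol)
    c_s = (trace.c - rest.c) / scaling.K_D
    return trace.t, c_s


def objective_err(
    data,
    params: DoseParams,
    proto: InjectionProtocol,
    scaling: ScalingParams,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> float:
    """Sum-of-squares misfit between scaled data and the model solution.

    ``data`` is either a single ``(t, sed)`` pair or a mapping
    ``{dose: (t, sed)}``; dose entries replace ``proto.a`` and their errors
    add.  The model trace is linearly interpolated at the data times.
    Integration failure yields +inf (the sample is rejected upstream).
    """
    if isinstance(data, dict):
        items = [(float(a), np.asarray(t, float), np.asarray(s, float))
                 for a, (t, s) in data.items()]
    else:
        t, s = data
        items = [(proto.a, np.asarray(t, float), np.asarray(s, float))]
    total = 0.0
    for a, t_data, sed in items:
        if t_data.size == 0:
            raise ValueError("empty data trace")
        t_lo, t_hi = float(t_data.min()), float(t_data.max())
        proto_a = InjectionProtocol(a=a, t1=proto.t1, r=proto.r, frozen=proto.frozen)
        try:
            t_model, c_s = simulate_scaled(params, proto_a, t_hi,
                                           scaling, rtol=rtol, atol=atol)
        except (RuntimeError, ValueError):
            return INFEASIBLE
        if t_lo < t_model[0] - 1e-9 or t_hi > t_model[-1] + 1e-9:
            raise ValueError("data time span exceeds the simulated span")
        ic_s = np.interp(t_data, t_model, c_s)
        total += float(np.sum((sed - ic_s) ** 2))
    return total


def make_objective(data, proto: InjectionProtocol, scaling: ScalingParams,
                   rtol: float = 1e-6, atol: float = 1e-9):
    """Bind data/protocol/scaling into an ``objective(params)`` callable."""
    return lambda params: objective_err(data, params, proto, scaling,
                                        rtol=rtol, atol=atol)


def random_walk_refine(
    start: DoseParams,
    objective,
    names: tuple[str, ...],
    step_frac: float = 0.05,
    n_steps: int = 100,
    seed: int = 0,
    start_err: float | None = None,
) -> FitResult:
    """Accept-if-better random walk with multiplicative Gaussian steps.

    Each proposal multiplies every varied parameter by exp(step_frac * z),
    z standard normal; only strict improvements are accepted, so the best
    error is non-increasing.
    """
    if step_frac < 0:
        raise ValueError("step_frac must be non-negative")
    rng = np.random.default_rng(seed)
    best = start
    best_err = objective(start) if start_err is None else start_err
    history = [(best_err, best)]
    evals = 0 if start_err is not None else 1
    for _ in range(n_steps):
        if step_frac == 0.0:
            break
        factors = np.exp(step_frac * rng.standard_normal(len(names)))
        updates = {nm: getattr(best, nm) * f for nm, f in zip(names, factors)}
        try:
            proposal = best.with_updates(**updates)
        except ValueError:
            continue
        err = objective(proposal)
        evals += 1
        if err < best_err:
            best, best_err = proposal, err
            history.append((best_err, best))
    return FitResult(best_params=best, best_err=best_err, n_evaluated=evals,
                     seed=seed, history=tuple(history))


def random_search(
    space: ParamSpace,
    objective,
    n_samples: int,
    threshold: float = math.inf,
    seed: int = 0,
    refine_steps: int = 100,
    refine_step_frac: float = 0.05,
) -> FitResult:
    """Random sampling of the parameter space with random-walk refinement.

    Draws ``n_samples`` sets; any draw with error below ``threshold``
    triggers :func:`random_walk_refine` around it.  Deterministic given the
    seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    best: DoseParams | None = None
    best_err = math.inf
    history: list[tuple[float, DoseParams]] = []
    evals = 0
    any_feasible = False
    for k in range(n_samples):
        candidate = space.sample(rng)
        err = objective(candidate)
        evals += 1
        if math.isfinite(err):
            any_feasible = True
        if err < threshold and math.isfinite(err):
            walk_seed = int(rng.integers(0, 2**31 - 1))
            refined = random_walk_refine(candidate, objective, space.names,
                                         step_frac=refine_step_frac,
                                         n_steps=refine_steps, seed=walk_seed,
                                         start_err=err)
            evals += refined.n_evaluated
            err, candidate = refined.best_err, refined.best_params
        if err < best_err:
            best, best_err = candidate, err
            history.append((best_err, best))
    if not any_feasible or best is None:
        raise RuntimeError("no feasible parameter set found in the search")
    return FitResult(best_params=best, best_err=best_err, n_evaluated=evals,
                     seed=seed, history=tuple(history))


def fit_subset(
    subset: tuple[str, ...],
    data,
    baseline: DoseParams,
    proto: InjectionProtocol,
    scaling: ScalingParams,
    n_samples: int = 200,
    threshold: float = math.inf,
    seed: int = 0,
    **search_kwargs,
) -> FitResult:
    """Fit with only the named parameter groups free, others frozen.

    Group names follow the published parameter table: Cellular, SERCA,
    IP3Receptor, IP3Model, PLC, GProtein.
    """
    names: list[str] = []
    for group in subset:
        if group not in PARAM_GROUPS:
            raise KeyError(
                f"unknown group {group!r}; valid groups: {sorted(PARAM_GROUPS)}"
            )
        names.extend(PARAM_GROUPS[group])
    space = ParamSpace.default(baseline, tuple(names))
    objective = make_objective(data, proto, scaling)
    return random_search(space, objective, n_samples=n_samples,
                         threshold=threshold, seed=seed, **search_kwargs)
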