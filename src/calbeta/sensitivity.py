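"""Uncertainty quantification and PRCC sensitivity analysis.

Parameters are varied independently and uniformly within a percentage band
around a baseline; each sampled set is simulated, and either pointwise
ensemble statistics of the scaled Ca2+ trace (UQ envelopes) or partial rank
correlation coefficients (PRCC) of peak amplitude and time-to-peak are
computed.  The PRCC of parameter j against an outcome is the correlation
between the residuals of rank(x_j) and rank(y) after linearly regressing
each on the ranks of all other sampled parameters; it measures monotone
association corrected for the other inputs, with values in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import ScalingParams, integrate, steady_state
from .model_core import DoseParams, InjectionProtocol

__all__ = [
    "EnsembleSummary",
    "PRCCResult",
    "PRCC_PARAMETERS",
    "sample_parameters",
    "uq_ensemble",
    "prcc",
    "prcc_experiment",
]

#: the 26 kinetic parameters varied in the published sensitivity tables
#: (totals c_t, PLC_tot, G_tot and the protocol/scaling constants are held fixed)
PRCC_PARAMETERS: tuple[str, ...] = (
    "k_f", "J_ER", "gamma", "V_s", "K_s",
    "K1", "K2", "K3", "K4", "K5", "k_m2", "k_m4",
    "V_0", "V_Q", "K_Q", "K_ip3k", "K_PLC", "k_3k", "k_5p",
    "k_a", "k_b", "k_c", "k_d", "delta", "V_R", "K_R",
)

MAX_FAILURE_FRACTION = 0.05


@dataclass(frozen=True)
class EnsembleSummary:
    """Pointwise mean and standard deviation of an ensemble of scaled traces."""

    t: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int          # ensemble size actually summarized
    pct: float      # variation half-width used (e.g. 0.10 for +/-10%)
    seed: int
    n_failed: int = 0


@dataclass(frozen=True)
class PRCCResult:
    """PRCC coefficients with significance, one row per (parameter, outcome, dose)."""

    table: pd.DataFrame  # columns: parameter, outcome, dose, prcc, p_value
    n: int

    def coefficient(self, parameter: str, outcome: str, dose: float) -> float:
        mask = (
            (self.table["parameter"] == parameter)
            & (self.table["outcome"] == outcome)
            & (self.table["dose"] == dose)
        )
        sub = self.table.loc[mask, "prcc"]
        if sub.empty:
            raise KeyError(f"no entry for ({parameter}, {outcome}, {dose})")
        return float(sub.iloc[0])

    def mean_across_doses(self, outcome: str) -> pd.Series:
        sub = self.table[self.table["outcome"] == outcome]
        return sub.groupby("parameter")["prcc"].mean().sort_values()


def sample_parameters(
    base: DoseParams,
    names: tuple[str, ...],
    pct: float,
    n: int,
    seed: int,
) -> np.ndarray:
    """(n, len(names)) matrix, each column i.i.d. Uniform(base*(1-pct), base*(1+pct))."""
    if pct < 0:
        raise ValueError("pct must be non-negative")
    base_vals = np.array([getattr(base, nm) for nm in names])
    rng = np.random.default_rng(seed)
    lo = base_vals * (1.0 - pct)
    hi = base_vals * (1.0 + pct)
    return rng.uniform(lo, hi, size=(n, len(names)))


def _simulate_outcomes(
    base: DoseParams,
    names: tuple[str, ...],
    X: np.ndarray,
    proto: InjectionProtocol,
    t_end: float,
    dt_out: float,
    rtol: float,
    atol: float,
    scaling: ScalingParams | None,
):
    """Run the model for every sampled row; return traces or peak outcomes.

    Every member starts from the *baseline* zero-dose steady state: the
    ensemble represents uncertainty in the kinetics of one prepared resting
    cell, so the initial condition is not re-equilibrated per sample.
    """
    n = X.shape[0]
    rest = steady_state(base, 0.0)
    traces = []
    peaks = np.full(n, np.nan)
    peak_times = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    for i in range(n):
        params = base.with_updates(**dict(zip(names, X[i])))
        try:
            tr = integrate(params, proto, t_end, dt_out=dt_out,
                           initial=rest, rtol=rtol, atol=atol)
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"ensemble member {i} failed: {exc}")
            traces.append(None)
            continue
        ok[i] = True
        if scaling is not None:
            traces.append((tr.c - rest.c) / scaling.K_D)
        else:
            traces.append(None)
        after = tr.t >= proto.t1
        sub_t = tr.t[after]
        sub_c = tr.c[after]
        j = int(np.argmax(sub_c))
        peaks[i] = sub_c[j]
        peak_times[i] = sub_t[j]
    return traces, peaks, peak_times, ok


def uq_ensemble(
    base: DoseParams,
    names: tuple[str, ...],
    pct: float,
    n: int,
    proto: InjectionProtocol,
    seed: int,
    scaling: ScalingParams | None = None,
    t_end: float = 600.0,
    dt_out: float = 0.5,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> EnsembleSummary:
    """Pointwise mean +/- SD of the scaled Ca2+ trace over a sampled ensemble.

    Failed integrations are dropped and counted; more than 5% failures is an
    error.
    """
    if n < 2:
        raise ValueError("ensemble size must be at least 2")
    scaling = scaling or ScalingParams()
    X = sample_parameters(base, names, pct, n, seed)
    traces, _, _, ok = _simulate_outcomes(base, names, X, proto, t_end,
                                          dt_out, rtol, atol, scaling)
    n_failed = int(np.sum(~ok))
    if n_failed > MAX_FAILURE_FRACTION * n:
        raise RuntimeError(f"{n_failed}/{n} ensemble integrations failed")
    stack = np.array([tr for tr, good in zip(traces, ok) if good])
    t_grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_grid = t_grid[t_grid <= t_end + 1e-12]
    return EnsembleSummary(
        t=t_grid,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1),
        n=int(np.sum(ok)),
        pct=pct,
        seed=seed,
        n_failed=n_failed,
    )


def prcc(X: np.ndarray, y: np.ndarray,
         names: tuple[str, ...] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Partial rank correlation of each column of X against the outcome y.

    Ranks (average on ties) replace raw values; column j is correlated with
    y after both are linearly regressed on all other columns plus an
    intercept.  Returns (coefficients, two-sided p-values) with the usual
    t-approximation for partial correlations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError(f"outcome length {y.shape} does not match {n} rows")
    col_range = np.ptp(X, axis=0)
    if np.any(col_range == 0):
        const = [i for i in range(k) if col_range[i] == 0]
        labels = [names[i] for i in const] if names else const
        raise ValueError(f"constant input columns: {labels}")
    R = np.column_stack([stats.rankdata(X[:, j]) for j in range(k)])
    ry = stats.rankdata(y)
    coefs = np.empty(k)
    pvals = np.empty(k)
    dof = n - 2 - (k - 1)
    if dof <= 0:
        raise ValueError(f"too few samples ({n}) for {k} parameters")
    for j in range(k):
        others = np.delete(R, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta_x, _, rank_x, _ = np.linalg.lstsq(design, R[:, j], rcond=None)
        beta_y, _, rank_y, _ = np.linalg.lstsq(design, ry, rcond=None)
        if rank_x < design.shape[1] or rank_y < design.shape[1]:
            label = names[j] if names else j
            raise ValueError(f"rank-deficient regression when partialling out {label}")
        res_x = R[:, j] - design @ beta_x
        res_y = ry - design @ beta_y
        r = float(np.corrcoef(res_x, res_y)[0, 1])
        r = float(np.clip(r, -1.0, 1.0))
        coefs[j] = r
        with np.errstate(divide="ignore"):
            tstat = r * np.sqrt(dof / max(1.0 - r * r, 1e-300))
        pvals[j] = 2.0 * stats.t.sf(abs(tstat), dof)
    return coefs, pvals


def prcc_experiment(
    base: DoseParams,
    doses: tuple[float, ...] = (3.0, 10.0, 30.0),
    names: tuple[str, ...] = PRCC_PARAMETERS,
    pct: float = 0.10,
    n: int = 2000,
    seed: int = 0,
    proto_template: InjectionProtocol | None = None,
    t_end: float = 600.0,
    dt_out: float = 0.1,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> PRCCResult:
    """PRCC of every parameter against peak Ca2+ and time-to-peak, per dose.

    Each dose gets its own sampled ensemble (seeded deterministically from
    ``seed``); outcomes are the post-injection peak of c and the time at
    which it occurs.  The published ranking statistic — the mean PRCC across
    doses — is available from the result object.
    """
    proto_template = proto_template or InjectionProtocol()
    rows = []
    for d_idx, a in enumerate(doses):
        dose_seed = (seed + 7919 * d_idx) % 2**31
        X = sample_parameters(base, names, pct, n, dose_seed)
        proto = InjectionProtocol(a=a, t1=proto_template.t1, r=proto_template.r)
        _, peaks, ptimes, ok = _simulate_outcomes(
            base, names, X, proto, t_end, dt_out, rtol, atol, scaling=None)
        n_failed = int(np.sum(~ok))
        if n_failed > MAX_FAILURE_FRACTION * n:
            raise RuntimeError(f"{n_failed}/{n} integrations failed at dose {a}")
        Xok = X[ok]
        for outcome, yvals in (("peak", peaks[ok]), ("peak_time", ptimes[ok])):
            coefs, pvals = prcc(Xok, yvals, names)
            for nm, r, p in zip(names, coefs, pvals):
                rows.append({"parameter": nm, "outcome": outcome,
                             "dose": float(a), "prcc": r, "p_value": p})
    return PRCCResult(table=pd.DataFrame(rows), n=n)
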