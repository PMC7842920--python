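"""Conversion between relative fluorescence (df/f0) and scaled Ca2+.

Single-wavelength indicator recordings report df = (f - f0)/f0 relative to
the resting fluorescence.  For an indicator with dissociation constant K_D,
dynamic range R_f = f_max/f_min and brightness ratio f_m = f_max/f0, the
Maravall relations link df to the scaled concentration
c_s = (c - c0)/K_D::

    c_s = f_m (1 - 1/R_f) df / ((df_max - df) df_max)

with the saturation level ``df_max = (1 - 1/R_f)/(1/R_f + c0/K_D)`` fixed
by the resting Ca2+ concentration c0.  Both directions of the map are
provided, plus a sensitivity table of df_max over indicator-parameter
ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import ScalingParams

__all__ = [
    "FluorescenceTrace",
    "delta_f_max",
    "fluorescence_to_calcium",
    "calcium_to_fluorescence",
    "scaling_sensitivity",
]

#: samples closer than this to saturation are rejected, not clipped
SATURATION_MARGIN = 1e-9


@dataclass(frozen=True)
class FluorescenceTrace:
    """A df/f0 recording on a time grid."""

    t: np.ndarray
    df: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        df = np.asarray(self.df, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "df", df)
        if t.shape != df.shape:
            raise ValueError("t and df must have matching shapes")
        if not np.all(np.isfinite(df)):
            raise ValueError("non-finite fluorescence values")
        if np.any(df <= -1.0):
            raise ValueError("df/f0 cannot fall below -1 (negative fluorescence)")

    def to_csv(self, path) -> None:
        pd.DataFrame({"t": self.t, "df": self.df}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FluorescenceTrace":
        frame = pd.read_csv(path)
        return cls(t=frame["t"].to_numpy(), df=frame["df"].to_numpy())


def delta_f_max(c0: float, scaling: ScalingParams) -> float:
    """Indicator saturation df_max implied by resting Ca2+ ``c0``.

    df_max = (1 - 1/R_f) / (1/R_f + c0/K_D); approaches R_f - 1 as c0 -> 0.
    """
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    return (1.0 - 1.0 / scaling.R_f) / (1.0 / scaling.R_f + c0 / scaling.K_D)


def fluorescence_to_calcium(trace: FluorescenceTrace,
                            scaling: ScalingParams) -> np.ndarray:
    """Convert df/f0 to scaled Ca2+ c_s = (c - c0)/K_D.

    Strictly increasing in df; samples at or beyond indicator saturation are
    an error (a saturated sample carries no concentration information).
    """
    dfm = scaling.df_max
    bad = np.flatnonzero(trace.df >= dfm - SATURATION_MARGIN)
    if bad.size:
        raise ValueError(
            f"{bad.size} samples at/beyond indicator saturation df_max={dfm:.6g} "
            f"(first offenders at t={trace.t[bad[:5]]})"
        )
    return scaling.f_m * (1.0 - 1.0 / scaling.R_f) * trace.df / (
        (dfm - trace.df) * dfm
    )


def calcium_to_fluorescence(t: np.ndarray, c_s: np.ndarray,
                            scaling: ScalingParams) -> FluorescenceTrace:
    """Exact algebraic inverse of :func:`fluorescence_to_calcium`.

    Maps scaled Ca2+ back to df/f0; output approaches df_max from below as
    c_s grows.  Used to synthesize fluorescence-style recordings from model
    output.
    """
    c_s = np.asarray(c_s, dtype=float)
    dfm = scaling.df_max
    alpha = scaling.f_m * (1.0 - 1.0 / scaling.R_f)
    # invert c_s = alpha df / ((dfm - df) dfm)  =>  df = c_s dfm^2/(alpha + c_s dfm)
    df = c_s * dfm * dfm / (alpha + c_s * dfm)
    return FluorescenceTrace(t=np.asarray(t, dtype=float), df=df)


def scaling_sensitivity(c0_grid, K_D_grid, R_f_grid) -> pd.DataFrame:
    """Tabulate df_max over grids of resting Ca2+ and indicator constants.

    df_max is strictly decreasing in c0, increasing in K_D, and nearly flat
    in R_f over the plausible range of indicator dynamic ranges.
    """
    rows = []
    for c0 in np.atleast_1d(np.asarray(c0_grid, dtype=float)):
        for kd in np.atleast_1d(np.asarray(K_D_grid, dtype=float)):
            for rf in np.atleast_1d(np.asarray(R_f_grid, dtype=float)):
                s = ScalingParams(K_D=kd, c0=c0, R_f=rf)
                rows.append({"c0": c0, "K_D": kd, "R_f": rf,
                             "df_max": delta_f_max(c0, s)})
    return pd.DataFrame(rows)
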