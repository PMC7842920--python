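"""Synthetic stand-ins for oocyte dose-response recordings.

The original fluorescence recordings behind the model are not publicly
deposited, so calibration and conversion code is exercised against
synthetic traces generated from the model itself: dose-response families
whose peak grows and latency shrinks with dose, and the small-dose
oscillatory regimes obtained by varying the SERCA half-activation K_s.
Every dataset records the ground-truth parameters and seed so it can be
regenerated bit-identically; the noiseless version satisfies the model
exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import ScalingParams, integrate, steady_state
from .fluorescence import SATURATION_MARGIN, FluorescenceTrace, calcium_to_fluorescence
from .model_core import DoseParams, InjectionProtocol

__all__ = ["SyntheticDataset", "generate_dose_response", "generate_oscillatory_trace"]

#: sampling cadence and duration of synthetic "recordings" (s)
DEFAULT_DT = 1.0
DEFAULT_T_END = 600.0


@dataclass(frozen=True)
class SyntheticDataset:
    """Per-dose synthetic traces plus the ground truth that generated them.

    ``traces`` maps dose -> (t, sed) scaled-Ca2+ arrays;
    ``fluorescence`` maps dose -> df/f0 traces when requested.
    """

    doses: tuple[float, ...]
    traces: dict[float, tuple[np.ndarray, np.ndarray]]
    truth_params: DoseParams
    truth_scaling: ScalingParams
    proto_template: InjectionProtocol
    noise_sd: float
    seed: int
    fluorescence: dict[float, FluorescenceTrace] | None = None

    def write(self, directory) -> None:
        """Per-dose CSV files plus a truth manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for a, (t, sed) in self.traces.items():
            pd.DataFrame({"t": t, "sed": sed}).to_csv(
                directory / f"dose_{a:g}.csv", index=False)
        manifest = {
            "doses": list(self.doses),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "params": self.truth_params.to_dict(),
            "scaling": asdict(self.truth_scaling),
            "protocol": asdict(self.proto_template),
        }
        (directory / "truth.json").write_text(json.dumps(manifest, indent=2))


def generate_dose_response(
    truth: DoseParams,
    proto_template: InjectionProtocol,
    doses: tuple[float, ...],
    scaling: ScalingParams,
    noise_sd: float,
    seed: int,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
    as_fluorescence: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SyntheticDataset:
    """Simulated dose-response family with optional noise.

    Each dose is run from the zero-dose steady state, scaled relative to its
    own resting Ca2+, optionally mapped to df/f0 through the inverse
    indicator relation, and perturbed with i.i.d. Gaussian noise.  By
    construction the peak grows and the latency shrinks as the dose
    increases (for the published large-dose regime).
    """
    if not doses:
        raise ValueError("doses must be nonempty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rest = steady_state(truth, 0.0)
    traces: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    fl: dict[float, FluorescenceTrace] = {}
    for a in doses:
        proto = InjectionProtocol(a=float(a), t1=proto_template.t1,
                                  r=proto_template.r)
        tr = integrate(truth, proto, t_end, dt_out=dt, initial=rest,
                       rtol=rtol, atol=atol)
        c_s = (tr.c - rest.c) / scaling.K_D
        if as_fluorescence:
            clean = calcium_to_fluorescence(tr.t, c_s, scaling)
            df = clean.df + noise_sd * rng.standard_normal(c_s.size)
            if np.any(df >= scaling.df_max - SATURATION_MARGIN):
                raise ValueError(
                    f"noise pushed df/f0 to indicator saturation at dose {a}"
                )
            fl[float(a)] = FluorescenceTrace(t=tr.t, df=df)
            traces[float(a)] = (tr.t, c_s)
        else:
            sed = c_s + noise_sd * rng.standard_normal(c_s.size)
            traces[float(a)] = (tr.t, sed)
    return SyntheticDataset(
        doses=tuple(float(a) for a in doses),
        traces=traces,
        truth_params=truth,
        truth_scaling=scaling,
        proto_template=proto_template,
        noise_sd=noise_sd,
        seed=seed,
        fluorescence=fl if as_fluorescence else None,
    )


def generate_oscillatory_trace(
    truth: DoseParams,
    K_s_override: float,
    proto: InjectionProtocol | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    t_end: float = DEFAULT_T_END,
    dt: float = 0.1,
) -> SyntheticDataset:
    """Small-dose run at one K_s value, for exercising regime classification.

    With the published small-dose constants and a 1 ug/ml injection the
    trace is a monotone rise to an elevated level at K_s = 0.15, a
    decaying-amplitude oscillation at 0.125, a growing oscillation at 0.12,
    and repetitive spiking at 0.118 or 0.11.
    """
    if K_s_override <= 0:
        raise ValueError("K_s_override must be positive")
    proto = proto or InjectionProtocol(a=1.0)
    params = truth.with_updates(K_s=K_s_override)
    scaling = ScalingParams()
    ds = generate_dose_response(
        params, proto, (proto.a,), scaling, noise_sd, seed,
        t_end=t_end, dt=dt,
    )
    return ds
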