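"""Synthetic noisy I-V experiments with the reference measurement design.

The generator reproduces the structure of the reference glucose-sensing
measurements — drain voltage swept over 0–0.7 V (71 points by default),
buffer at 1 mg/mL, glucose at {0, 2, 4, 6, 8, 10, 20, 50} mM — and perturbs
the model currents with independent zero-mean Gaussian noise:

    I_noisy = I * (1 + eps_m) + eps_a,

with eps_m ~ N(0, multiplicative_sd^2) and eps_a ~ N(0, additive_sd^2) in
amperes. Negative noisy currents are clipped to zero (physical readout
floor) and the number of clipped points is flagged on the dataset. Every
draw is governed by the NoiseModel seed, so a given seed always reproduces
the same dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import IVDataset, iv_sweep
from .device import DeviceGeometry, TransportParams
from .exceptions import InvalidParameterError
from .sensing import GlucoseResponseLaw, SensingCondition

__all__ = ["NoiseModel", "default_conditions", "default_vd_grid", "generate_experiment"]

#: Glucose concentrations (mM) of the reference experimental design.
DEFAULT_GLUCOSE_LEVELS_MM = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 20.0, 50.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive/multiplicative Gaussian current noise with a fixed seed."""

    multiplicative_sd: float = 0.0  # fraction of the current
    additive_sd: float = 0.0  # amperes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_sd < 0 or self.additive_sd < 0:
            raise InvalidParameterError("noise standard deviations must be nonnegative")


def default_vd_grid(n_points: int = 71, v_max: float = 0.7) -> np.ndarray:
    """The reference drain-voltage sweep: ``n_points`` from 0 to ``v_max`` V."""
    return np.linspace(0.0, v_max, n_points)


def default_conditions(
    glucose_levels: Sequence[float] = DEFAULT_GLUCOSE_LEVELS_MM,
    pbs_concentration: float = 1.0,
    pbs_voltage: float = 0.6,
    law: GlucoseResponseLaw | None = None,
) -> list[SensingCondition]:
    """The reference condition set: one sweep per glucose level, buffer fixed."""
    law = law or GlucoseResponseLaw()
    return [
        SensingCondition(
            pbs_concentration=pbs_concentration,
            pbs_voltage=pbs_voltage,
            glucose_concentration=float(f_g),
            law=law,
        )
        for f_g in glucose_levels
    ]


def generate_experiment(
    geometry: DeviceGeometry | None = None,
    transport: TransportParams | None = None,
    v_gs_bare: float = 1.5,
    conditions: Sequence[SensingCondition] | None = None,
    v_d_grid=None,
    noise: NoiseModel | None = None,
    label: str | None = None,
) -> IVDataset:
    """Generate one full noisy experiment as an :class:`IVDataset`.

    With zero noise the output currents are bit-identical to
    :func:`glucofet.calibration.iv_sweep`. The returned dataset carries an
    ``n_clipped`` attribute counting noisy currents floored at zero.
    """
    geometry = geometry or DeviceGeometry()
    transport = transport or TransportParams()
    conditions = list(conditions) if conditions is not None else default_conditions()
    grid = default_vd_grid() if v_d_grid is None else np.asarray(v_d_grid, dtype=float)
    noise = noise or NoiseModel()
    if label is None:
        label = f"synthetic seed={noise.seed}"

    rng = np.random.default_rng(noise.seed)
    frames = []
    n_clipped = 0
    for condition in conditions:
        clean = iv_sweep(grid, v_gs_bare, condition, geometry, transport, label=label)
        frame = clean.to_dataframe()
        i = frame["i_drain"].to_numpy()
        eps_m = rng.normal(0.0, noise.multiplicative_sd, size=i.size)
        eps_a = rng.normal(0.0, noise.additive_sd, size=i.size)
        noisy = i * (1.0 + eps_m) + eps_a
        n_clipped += int(np.sum(noisy < 0))
        frame["i_drain"] = np.maximum(noisy, 0.0)
        frames.append(frame)
    dataset = IVDataset(pd.concat(frames, ignore_index=True))
    dataset.n_clipped = n_clipped  # type: ignore[attr-defined]
    return dataset
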