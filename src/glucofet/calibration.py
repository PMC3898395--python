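"""I-V sweeps, calibration curves, sensitivity and model-vs-data RMS errors.

The experimental design being emulated: drain voltage swept 0–0.7 V, buffer
at 1 mg/mL, glucose stepped through {0, 2, 4, 6, 8, 10, 20, 50} mM. The
calibration curve is the readout current versus concentration at a fixed
drain bias; its least-squares slope over a stated linear range (2–10 mM at
V_D = 0.7 V in the reference design) is the sensor sensitivity. Agreement
between a simulated and a measured sweep is quantified per condition by the
absolute RMS current difference and by the normalized RMS — the absolute RMS
divided by the mean measured current of that condition, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import AMPERE_TO_MICROAMPERE
from .device import DeviceGeometry, TransportParams, derive_params
from .exceptions import (
    AlignmentError,
    InsufficientDataError,
    InvalidParameterError,
    NormalizationError,
)
from .sensing import GlucoseResponseLaw, SensingCondition, drain_current_biosensor

__all__ = [
    "IVDataset",
    "RmsReport",
    "SensitivityFit",
    "iv_sweep",
    "calibration_curve",
    "linear_sensitivity",
    "rms_comparison",
]

#: Required columns of the in-memory I-V table (SI units: volts, amperes).
IV_COLUMNS = ("v_drain", "i_drain", "f_pbs", "f_glucose", "label")

#: Columns identifying one solution condition.
CONDITION_KEYS = ("f_pbs", "f_glucose")


class IVDataset:
    """A labelled collection of drain-voltage sweeps, one group per condition.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``v_drain`` (V), ``i_drain`` (A), ``f_pbs`` (mg/mL), ``f_glucose`` (mM)
    and ``label`` (free-text provenance). Invariants enforced at
    construction: nonnegative drain voltages, strictly increasing drain
    voltage within each (f_pbs, f_glucose) condition group, and no duplicate
    (condition, drain-voltage) pairs.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in IV_COLUMNS if c not in frame.columns]
        if missing:
            raise InvalidParameterError(f"IVDataset frame missing columns: {missing}")
        frame = frame.loc[:, list(IV_COLUMNS)].reset_index(drop=True)
        if len(frame) == 0:
            raise InvalidParameterError("IVDataset must contain at least one record")
        if (frame["v_drain"] < 0).any():
            raise InvalidParameterError("drain voltages must be nonnegative")
        for cond, group in frame.groupby(list(CONDITION_KEYS), sort=False):
            v = group["v_drain"].to_numpy()
            if np.any(np.diff(v) <= 0):
                raise InvalidParameterError(
                    f"drain voltages must be strictly increasing within condition {cond}"
                )
        self._frame = frame

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "IVDataset":
        """Build from (v_drain, i_drain, f_pbs, f_glucose, label) tuples."""
        return cls(pd.DataFrame.from_records(list(records), columns=list(IV_COLUMNS)))

    def to_dataframe(self) -> pd.DataFrame:
        """Copy of the underlying table (SI units)."""
        return self._frame.copy()

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IVDataset):
            return NotImplemented
        return self._frame.equals(other._frame)

    def conditions(self) -> list[tuple[float, float]]:
        """Distinct (f_pbs, f_glucose) pairs in first-appearance order."""
        seen = self._frame.drop_duplicates(subset=list(CONDITION_KEYS))
        return [tuple(r) for r in seen[list(CONDITION_KEYS)].itertuples(index=False)]

    def condition_groups(self) -> Iterator[tuple[tuple[float, float], pd.DataFrame]]:
        for cond, group in self._frame.groupby(list(CONDITION_KEYS), sort=False):
            yield cond, group

    def currents(self) -> np.ndarray:
        return self._frame["i_drain"].to_numpy()


@dataclass(frozen=True)
class SensitivityFit:
    """OLS fit of readout current against concentration over a linear range."""

    slope: float  # A per mM
    intercept: float  # A
    r_squared: float
    n_points: int

    @property
    def slope_uA_per_mM(self) -> float:
        return self.slope * AMPERE_TO_MICROAMPERE


@dataclass(frozen=True)
class RmsReport:
    """Per-condition absolute and normalized RMS model-data current errors.

    ``per_condition`` has one row per (f_pbs, f_glucose) with columns
    ``absolute_rms`` (A) and ``normalized_rms_percent``; overall values are
    plain means across conditions.
    """

    per_condition: pd.DataFrame
    overall_absolute_rms: float
    overall_normalized_rms_percent: float

    def to_text(self) -> str:
        """Aligned text table with currents in microamperes."""
        lines = [
            f"{'Glucose (mM)':>14} {'F_PBS (mg/mL)':>14} {'Absolute RMS (uA)':>19} {'Normalized RMS (%)':>20}"
        ]
        for row in self.per_condition.itertuples(index=False):
            lines.append(
                f"{row.f_glucose:>14.6g} {row.f_pbs:>14.6g} "
                f"{row.absolute_rms * AMPERE_TO_MICROAMPERE:>19.6g} "
                f"{row.normalized_rms_percent:>20.4f}"
            )
        lines.append(
            f"{'mean':>14} {'':>14} "
            f"{self.overall_absolute_rms * AMPERE_TO_MICROAMPERE:>19.6g} "
            f"{self.overall_normalized_rms_percent:>20.4f}"
        )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        """CSV in report units: microamperes for the absolute RMS."""
        out = self.per_condition.copy()
        out["absolute_rms_uA"] = out.pop("absolute_rms") * AMPERE_TO_MICROAMPERE
        out.to_csv(path, index=False, float_format="%.12g")


def _validate_grid(v_d_grid) -> np.ndarray:
    grid = np.asarray(v_d_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise InvalidParameterError("drain-voltage grid must be a nonempty 1-D sequence")
    if np.any(grid < 0):
        raise InvalidParameterError("drain-voltage grid must be nonnegative")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("drain-voltage grid must be strictly increasing")
    return grid


def iv_sweep(
    v_d_grid,
    v_gs_bare: float,
    condition: SensingCondition,
    geometry: DeviceGeometry,
    transport: TransportParams,
    label: str = "model",
) -> IVDataset:
    """Deterministic noise-free model sweep over a drain-voltage grid."""
    grid = _validate_grid(v_d_grid)
    derived = derive_params(geometry, transport)
    currents = drain_current_biosensor(
        v_gs_bare, grid, condition, derived, transport.threshold_voltage
    )
    currents = np.atleast_1d(currents)
    return IVDataset(
        pd.DataFrame(
            {
                "v_drain": grid,
                "i_drain": currents,
                "f_pbs": condition.pbs_concentration,
                "f_glucose": condition.glucose_concentration,
                "label": label,
            }
        )
    )


def calibration_curve(
    f_g_list: Sequence[float],
    v_d_readout: float,
    v_gs_bare: float,
    geometry: DeviceGeometry,
    transport: TransportParams,
    pbs_concentration: float = 1.0,
    pbs_voltage: float = 0.6,
    law: GlucoseResponseLaw | None = None,
) -> pd.DataFrame:
    """Readout current versus glucose concentration at a fixed drain bias.

    Returns a frame with columns ``f_glucose`` (mM) and ``i_drain`` (A);
    strictly increasing in concentration while the device is on.
    """
    if v_d_readout < 0:
        raise InvalidParameterError("readout drain voltage must be nonnegative")
    law = law or GlucoseResponseLaw()
    derived = derive_params(geometry, transport)
    rows = []
    for f_g in f_g_list:
        condition = SensingCondition(
            pbs_concentration=pbs_concentration,
            pbs_voltage=pbs_voltage,
            glucose_concentration=float(f_g),
            law=law,
        )
        current = drain_current_biosensor(
            v_gs_bare, float(v_d_readout), condition, derived, transport.threshold_voltage
        )
        rows.append((float(f_g), float(current)))
    return pd.DataFrame(rows, columns=["f_glucose", "i_drain"])


def linear_sensitivity(curve, range_lo: float, range_hi: float) -> SensitivityFit:
    """Sensor sensitivity: OLS slope of current vs concentration in a range.

    ``curve`` is a calibration-curve frame or a sequence of (mM, A) pairs;
    points with range_lo <= f_g <= range_hi enter the regression. At least
    two in-range points are required.
    """
    if isinstance(curve, pd.DataFrame):
        f_g = curve["f_glucose"].to_numpy(dtype=float)
        i_d = curve["i_drain"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(curve), dtype=float)
        f_g, i_d = arr[:, 0], arr[:, 1]
    mask = (f_g >= range_lo) & (f_g <= range_hi)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"need at least 2 calibration points in [{range_lo}, {range_hi}] mM, "
            f"got {int(mask.sum())}"
        )
    x, y = f_g[mask], i_d[mask]
    if np.ptp(y) == 0.0:  # constant current: slope 0, linregress would warn
        return SensitivityFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, n_points=x.size)
    res = stats.linregress(x, y)
    return SensitivityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=int(x.size),
    )


def _aligned_currents(
    simulated: IVDataset, measured: IVDataset
) -> pd.DataFrame:
    keys = ["f_pbs", "f_glucose", "v_drain"]
    sim = simulated.frame[keys + ["i_drain"]].rename(columns={"i_drain": "i_sim"})
    meas = measured.frame[keys + ["i_drain"]].rename(columns={"i_drain": "i_meas"})
    merged = sim.merge(meas, on=keys, how="outer", indicator=True)
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        missing = [
            (row["f_pbs"], row["f_glucose"], row["v_drain"], str(row["_merge"]))
            for _, row in bad.head(10).iterrows()
        ]
        raise AlignmentError(
            "datasets are not aligned on identical (f_pbs, f_glucose, v_drain) keys; "
            f"{len(bad)} unmatched pairs, first: {missing}",
            missing_pairs=missing,
        )
    return merged.drop(columns="_merge")


def rms_comparison(simulated: IVDataset, measured: IVDataset) -> RmsReport:
    """Per-condition RMS comparison between a simulated and a measured sweep.

    Absolute RMS is the root of the mean squared current difference over the
    drain-voltage points of one condition; normalized RMS is 100 x absolute
    RMS / mean measured current of that condition. Requires exactly matching
    (condition, drain-voltage) keys — no interpolation is performed.
    """
    merged = _aligned_currents(simulated, measured)
    rows = []
    for (f_pbs, f_g), group in merged.groupby(["f_pbs", "f_glucose"], sort=False):
        diff = group["i_sim"].to_numpy() - group["i_meas"].to_numpy()
        abs_rms = float(np.sqrt(np.mean(diff * diff)))
        mean_meas = float(np.mean(group["i_meas"].to_numpy()))
        if mean_meas == 0.0:
            raise NormalizationError(
                f"mean measured current is zero for condition (f_pbs={f_pbs}, "
                f"f_glucose={f_g}); normalized RMS undefined"
            )
        rows.append((f_g, f_pbs, abs_rms, 100.0 * abs_rms / mean_meas))
    table = pd.DataFrame(
        rows, columns=["f_glucose", "f_pbs", "absolute_rms", "normalized_rms_percent"]
    )
    return RmsReport(
        per_condition=table,
        overall_absolute_rms=float(table["absolute_rms"].mean()),
        overall_normalized_rms_percent=float(table["normalized_rms_percent"].mean()),
    )
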