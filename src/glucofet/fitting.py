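"""Parameter estimation from measured I-V sweeps.

Free parameters of the biosensor model — the current prefactor ``beta``, the
threshold voltage ``v_t``, the critical voltage ``v_c``, the buffer-induced
gate shift ``v_pbs`` and the glucose-law constants ``law_asymptote`` (a) and
``law_rate`` (k) — are estimated by bounded trust-region nonlinear least
squares on the current residuals, with any subset held fixed at its
physics-derived value. The interface follows the Model/Results convention:

>>> model = BiosensorIVModel(data, geometry, transport)   # doctest: +SKIP
>>> res = model.fit(FitSpec(free_parameters=("v_pbs",)))  # doctest: +SKIP
>>> print(res.summary())                                  # doctest: +SKIP

Residuals are scaled to microamperes inside the optimizer for conditioning;
all reported quantities are SI. The optimizer itself (lmfit over scipy's
trust-region reflective solver) is deterministic: identical data, starts and
bounds give identical estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .calibration import IVDataset, RmsReport, rms_comparison
from .constants import AMPERE_TO_MICROAMPERE
from .device import DeviceGeometry, TransportParams, channel_current, derive_params
from .exceptions import (
    AlignmentError,
    IdentifiabilityError,
    InsufficientDataError,
    InvalidParameterError,
)
from .sensing import GlucoseResponseLaw, glucose_gate_voltage

__all__ = [
    "PARAM_NAMES",
    "FitSpec",
    "BiosensorIVModel",
    "BiosensorFitResults",
    "fit",
    "fit_glucose_law_two_stage",
    "TwoStageLawFit",
]

PARAM_NAMES = ("beta", "v_t", "v_c", "v_pbs", "law_asymptote", "law_rate")

#: Generous default bounds; beta's are in A/V^2 and rescale with the data.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "beta": (1e-15, 1e-2),
    "v_t": (-2.0, 2.0),
    "v_c": (1e-2, 1e4),
    "v_pbs": (0.0, 2.0),
    "law_asymptote": (0.5, 3.0),
    "law_rate": (1e-3, 1.0),
}

#: Default starting values where the physics gives no estimate.
DEFAULT_STARTS: dict[str, float] = {
    "v_t": 0.3,
    "v_c": 1.0,
    "v_pbs": 0.5,
    "law_asymptote": 1.4,
    "law_rate": 0.1,
}


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``free_parameters`` names the subset of :data:`PARAM_NAMES` to estimate;
    ``bounds`` and ``initial_values`` override the defaults per parameter;
    the optimizer stops when the relative objective change falls below
    ``tolerance`` or after ``max_iterations`` accepted iterations.
    """

    free_parameters: tuple[str, ...] = ("v_pbs", "law_asymptote", "law_rate")
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    initial_values: Mapping[str, float] = field(default_factory=dict)
    max_iterations: int = 200
    tolerance: float = 1e-12

    def __post_init__(self) -> None:
        if not self.free_parameters:
            raise InvalidParameterError("free_parameters must be nonempty")
        unknown = [p for p in self.free_parameters if p not in PARAM_NAMES]
        if unknown:
            raise InvalidParameterError(f"unknown free parameters: {unknown}")
        if not self.tolerance > 0:
            raise InvalidParameterError("tolerance must be strictly positive")
        if self.max_iterations < 1:
            raise InvalidParameterError("max_iterations must be at least 1")
        for name, (lo, hi) in self.bounds.items():
            if name not in PARAM_NAMES:
                raise InvalidParameterError(f"bounds given for unknown parameter {name!r}")
            if not lo < hi:
                raise InvalidParameterError(f"empty bound interval for {name!r}")
            start = self.initial_values.get(name)
            if start is not None and not (lo <= start <= hi):
                raise InvalidParameterError(
                    f"initial value {start} for {name!r} outside bounds [{lo}, {hi}]"
                )


class BiosensorIVModel:
    """Biosensor I-V model bound to a dataset, ready to fit or predict.

    Parameters
    ----------
    data : IVDataset
        Measured (or synthetic) sweeps; conditions are read from its
        ``f_pbs`` / ``f_glucose`` columns.
    geometry, transport :
        Device description; supplies the fixed values of beta, v_t and v_c
        (via the derived capacitances) for parameters not being fitted.
    v_gs_bare : float
        Applied gate voltage before any buffer/glucose shift (default 1.5 V).
    pbs_voltage : float
        Fixed buffer shift used when ``v_pbs`` is not free (default 0.6 V).
    law : GlucoseResponseLaw, optional
        Fixed glucose law used when its constants are not free.
    """

    def __init__(
        self,
        data: IVDataset,
        geometry: DeviceGeometry | None = None,
        transport: TransportParams | None = None,
        v_gs_bare: float = 1.5,
        pbs_voltage: float = 0.6,
        law: GlucoseResponseLaw | None = None,
    ):
        self.data = data
        self.geometry = geometry or DeviceGeometry()
        self.transport = transport or TransportParams()
        self.v_gs_bare = float(v_gs_bare)
        self.law = law or GlucoseResponseLaw()
        derived = derive_params(self.geometry, self.transport)
        self.fixed_values: dict[str, float] = {
            "beta": derived.beta,
            "v_t": self.transport.threshold_voltage,
            "v_c": derived.critical_voltage,
            "v_pbs": float(pbs_voltage),
            "law_asymptote": self.law.asymptote_voltage,
            "law_rate": self.law.rate_constant,
        }
        frame = data.frame
        self._v_d = frame["v_drain"].to_numpy(dtype=float)
        self._i_obs = frame["i_drain"].to_numpy(dtype=float)
        self._f_pbs = frame["f_pbs"].to_numpy(dtype=float)
        self._f_g = frame["f_glucose"].to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "BiosensorIVModel":
        """Build from a raw frame with the IVDataset columns (SI units)."""
        return cls(IVDataset(frame), **kwargs)

    # ------------------------------------------------------------------ #

    def predict(self, params: Mapping[str, float] | None = None) -> np.ndarray:
        """Model currents (A) at the dataset's rows for a parameter mapping.

        Missing entries fall back to the physics-derived fixed values.
        The buffer shift applies only to rows with ``f_pbs > 0`` (one
        calibration point, no buffer-concentration law).
        """
        p = dict(self.fixed_values)
        if params:
            p.update(params)
        law = GlucoseResponseLaw(p["law_asymptote"], p["law_rate"])
        out = np.empty_like(self._v_d)
        for i in range(self._v_d.size):
            v_eff = self.v_gs_bare
            if self._f_pbs[i] > 0:
                v_eff += p["v_pbs"]
            v_eff += float(glucose_gate_voltage(self._f_g[i], law))
            out[i] = channel_current(v_eff - p["v_t"], self._v_d[i], p["beta"], p["v_c"])
        return out

    def _predict_grouped(self, p: Mapping[str, float]) -> np.ndarray:
        # Vectorized per condition group; identical values to predict().
        law = GlucoseResponseLaw(p["law_asymptote"], p["law_rate"])
        out = np.empty_like(self._v_d)
        for (f_pbs, f_g), idx in self._group_indices:
            v_eff = self.v_gs_bare
            if f_pbs > 0:
                v_eff += p["v_pbs"]
            v_eff += float(glucose_gate_voltage(f_g, law))
            out[idx] = channel_current(v_eff - p["v_t"], self._v_d[idx], p["beta"], p["v_c"])
        return out

    @property
    def _group_indices(self):
        if not hasattr(self, "_group_indices_cache"):
            groups = []
            frame = self.data.frame
            for cond, sub in frame.groupby(["f_pbs", "f_glucose"], sort=False):
                groups.append((cond, sub.index.to_numpy()))
            self._group_indices_cache = groups
        return self._group_indices_cache

    def _check_identifiability(self, spec: FitSpec) -> None:
        free = set(spec.free_parameters)
        for (f_pbs, f_g), idx in self._group_indices:
            if idx.size < 2:
                raise InsufficientDataError(
                    f"condition (f_pbs={f_pbs}, f_glucose={f_g}) has fewer than "
                    "2 drain-voltage points"
                )
        positive_fg = sorted({f_g for (_, f_g), _ in self._group_indices if f_g > 0})
        if ("law_asymptote" in free or "law_rate" in free) and not positive_fg:
            raise IdentifiabilityError(
                "glucose-law constants cannot be fitted: no condition with f_glucose > 0"
            )
        if {"law_asymptote", "law_rate"} <= free and len(positive_fg) < 2:
            raise IdentifiabilityError(
                "fitting both glucose-law constants needs at least 2 distinct "
                "positive glucose concentrations"
            )
        if "v_pbs" in free and not any(f_pbs > 0 for (f_pbs, _), _ in self._group_indices):
            raise IdentifiabilityError(
                "v_pbs cannot be fitted: no condition with f_pbs > 0"
            )

    def _default_start(self, name: str) -> float:
        if name == "beta":
            # From the largest observed low-bias conductance: near V_D -> 0,
            # I ~ 2 beta V_GT V_D, so beta ~ G_max / (2 V_GT_guess).
            mask = self._v_d > 0
            if mask.any():
                g_max = float(np.max(self._i_obs[mask] / self._v_d[mask]))
                v_gt_guess = max(self.v_gs_bare - DEFAULT_STARTS["v_t"], 0.5)
                return max(g_max / (2.0 * v_gt_guess), DEFAULT_BOUNDS["beta"][0])
            return self.fixed_values["beta"]
        return DEFAULT_STARTS[name]

    def fit(self, spec: FitSpec | None = None) -> "BiosensorFitResults":
        """Bounded nonlinear least squares on the current residuals.

        Returns a :class:`BiosensorFitResults`; non-convergence is reported
        through its ``converged`` flag, never silently.
        """
        spec = spec or FitSpec()
        self._check_identifiability(spec)

        params = lmfit.Parameters()
        for name in PARAM_NAMES:
            if name in spec.free_parameters:
                lo, hi = spec.bounds.get(name, DEFAULT_BOUNDS[name])
                start = spec.initial_values.get(name, self._default_start(name))
                start = min(max(start, lo), hi)
                params.add(name, value=start, min=lo, max=hi, vary=True)
            else:
                params.add(name, value=self.fixed_values[name], vary=False)

        scale = AMPERE_TO_MICROAMPERE  # residuals in uA for conditioning
        trace: list[float] = []

        def residual(pars: lmfit.Parameters) -> np.ndarray:
            p = {name: pars[name].value for name in PARAM_NAMES}
            return (self._predict_grouped(p) - self._i_obs) * scale

        def iter_cb(pars, iteration, resid, *args, **kwargs):
            trace.append(float(np.sum(np.asarray(resid) ** 2)) / scale**2)

        minimizer = lmfit.Minimizer(residual, params, iter_cb=iter_cb)
        out = minimizer.minimize(
            method="least_squares",
            ftol=spec.tolerance,
            xtol=spec.tolerance,
            gtol=spec.tolerance,
            max_nfev=spec.max_iterations * (len(spec.free_parameters) + 1) * 5,
        )

        estimates = {name: float(out.params[name].value) for name in PARAM_NAMES}
        stderr = {
            name: (float(out.params[name].stderr) if out.params[name].stderr else None)
            for name in spec.free_parameters
        }
        final_resid = self._predict_grouped(estimates) - self._i_obs
        objective = float(np.sum(final_resid**2))
        # Accepted iterations: improving prefix minima of the evaluation trace.
        accepted: list[float] = []
        for value in trace:
            if not accepted or value < accepted[-1]:
                accepted.append(value)
        return BiosensorFitResults(
            model=self,
            spec=spec,
            estimates=estimates,
            stderr=stderr,
            objective=objective,
            converged=bool(out.success),
            iterations_used=int(out.nfev),
            objective_trace=trace,
            accepted_objective_trace=accepted,
            message=str(getattr(out, "message", "")),
        )


@dataclass
class BiosensorFitResults:
    """Estimates, uncertainties and diagnostics from a biosensor I-V fit.

    ``estimates`` holds all six model parameters (fitted or fixed);
    ``stderr`` the asymptotic standard errors of the free ones (None when the
    covariance is unavailable); ``objective`` the sum of squared current
    residuals in A^2. ``accepted_objective_trace`` is non-increasing by the
    optimizer wrapper's accepted-step contract.
    """

    model: BiosensorIVModel
    spec: FitSpec
    estimates: dict[str, float]
    stderr: dict[str, float | None]
    objective: float
    converged: bool
    iterations_used: int
    objective_trace: list[float]
    accepted_objective_trace: list[float]
    message: str = ""

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return self.spec.free_parameters

    def predict(self) -> np.ndarray:
        """Fitted model currents (A) at the data rows."""
        return self.model.predict(self.estimates)

    def residual_profile(self, data: IVDataset | None = None) -> pd.DataFrame:
        """Signed residuals (model - data, in A) per (condition, V_D) key.

        With an explicit ``data`` argument the fitted model is evaluated
        against that dataset instead, after exact key alignment.
        """
        if data is None:
            frame = self.model.data.frame.copy()
            frame["residual"] = self.predict() - frame["i_drain"].to_numpy()
            return frame[["f_pbs", "f_glucose", "v_drain", "residual"]]
        own = self.model.data.frame[["f_pbs", "f_glucose", "v_drain"]]
        other = data.frame[["f_pbs", "f_glucose", "v_drain"]]
        merged = own.merge(other, how="outer", indicator=True)
        bad = merged[merged["_merge"] != "both"]
        if len(bad):
            raise AlignmentError(
                f"dataset keys differ from the fitted data; {len(bad)} unmatched pairs",
                missing_pairs=[tuple(r)[:3] for r in bad.head(10).itertuples(index=False)],
            )
        other_model = BiosensorIVModel(
            data,
            self.model.geometry,
            self.model.transport,
            v_gs_bare=self.model.v_gs_bare,
        )
        frame = data.frame.copy()
        frame["residual"] = other_model.predict(self.estimates) - frame["i_drain"].to_numpy()
        return frame[["f_pbs", "f_glucose", "v_drain", "residual"]]

    @property
    def rms_report(self) -> RmsReport:
        """Per-condition RMS comparison of the fitted model against the data."""
        sim_frame = self.model.data.frame.copy()
        sim_frame["i_drain"] = self.predict()
        sim_frame["label"] = "fitted model"
        return rms_comparison(IVDataset(sim_frame), self.model.data)

    def parameters_at_bounds(self, rel_tol: float = 1e-3) -> list[str]:
        """Free parameters whose estimate sits at (or hugs) a bound."""
        flagged = []
        for name in self.spec.free_parameters:
            lo, hi = self.spec.bounds.get(name, DEFAULT_BOUNDS[name])
            value = self.estimates[name]
            span = hi - lo
            if value - lo <= rel_tol * span or hi - value <= rel_tol * span:
                flagged.append(name)
        return flagged

    def summary(self) -> str:
        """Human-readable fit report (statsmodels-style text table)."""
        lines = [
            "Biosensor I-V nonlinear least-squares fit",
            "=" * 57,
            f"Observations: {len(self.model.data):>6}    "
            f"Conditions: {len(self.model.data.conditions()):>3}",
            f"Objective (sum sq. residual, A^2): {self.objective:.6e}",
            f"Converged: {self.converged}    Function evals: {self.iterations_used}",
            "-" * 57,
            f"{'parameter':<15}{'estimate':>15}{'std err':>13}{'fitted':>9}",
            "-" * 57,
        ]
        for name in PARAM_NAMES:
            fitted = name in self.spec.free_parameters
            se = self.stderr.get(name)
            se_txt = f"{se:.3e}" if se is not None else ("--" if fitted else "")
            lines.append(
                f"{name:<15}{self.estimates[name]:>15.6e}{se_txt:>13}"
                f"{('yes' if fitted else 'no'):>9}"
            )
        at_bounds = self.parameters_at_bounds()
        if at_bounds:
            lines.append("-" * 57)
            lines.append(f"WARNING: parameter(s) at bounds: {', '.join(at_bounds)}")
        lines.append("=" * 57)
        return "\n".join(lines)

    def to_key_values(self) -> dict[str, object]:
        """Flat key-value serialisation (plain-text friendly)."""
        out: dict[str, object] = {}
        for name in PARAM_NAMES:
            out[f"estimate.{name}"] = self.estimates[name]
        for name, se in self.stderr.items():
            out[f"stderr.{name}"] = se if se is not None else "NA"
        out["objective_A2"] = self.objective
        out["converged"] = self.converged
        out["iterations_used"] = self.iterations_used
        out["free_parameters"] = ",".join(self.spec.free_parameters)
        at_bounds = self.parameters_at_bounds()
        out["parameters_at_bounds"] = ",".join(at_bounds) if at_bounds else "none"
        return out

    def plot_fit(self, ax=None):
        """Overlay data (points) and fitted model (lines), currents in uA."""
        from .plotting import plot_fit as _plot_fit

        return _plot_fit(self, ax=ax)


def fit(
    data: IVDataset,
    spec: FitSpec,
    geometry: DeviceGeometry | None = None,
    transport: TransportParams | None = None,
    **model_kwargs,
) -> BiosensorFitResults:
    """Functional wrapper: build a :class:`BiosensorIVModel` and fit it."""
    return BiosensorIVModel(data, geometry, transport, **model_kwargs).fit(spec)


@dataclass(frozen=True)
class TwoStageLawFit:
    """Result of the two-stage glucose-law regression.

    Stage 1 estimates one gate-voltage shift per positive-glucose condition;
    stage 2 regresses the piecewise-exponential law through those shifts.
    """

    per_condition_shifts: pd.DataFrame  # columns f_glucose, v_glucose
    law: GlucoseResponseLaw


def fit_glucose_law_two_stage(
    data: IVDataset,
    geometry: DeviceGeometry | None = None,
    transport: TransportParams | None = None,
    v_gs_bare: float = 1.5,
    pbs_voltage: float = 0.6,
) -> TwoStageLawFit:
    """Fit the glucose law by first extracting per-condition gate shifts.

    Mirrors the calibration route of regressing the rise in drain current
    with gate voltage against glucose concentration: stage 1 fits a single
    additional gate-voltage shift per condition with f_glucose > 0 (buffer
    shift held at ``pbs_voltage``); stage 2 fits (a, k) of
    ``v = a - exp(-k f_g)`` through the stage-1 shifts.
    """
    geometry = geometry or DeviceGeometry()
    transport = transport or TransportParams()
    derived = derive_params(geometry, transport)
    shifts = []
    for (f_pbs, f_g), group in data.condition_groups():
        if f_g <= 0:
            continue
        v_d = group["v_drain"].to_numpy(dtype=float)
        i_obs = group["i_drain"].to_numpy(dtype=float)
        base_v = v_gs_bare + (pbs_voltage if f_pbs > 0 else 0.0)

        def current_of_shift(v_d_arr, shift):
            return channel_current(
                base_v + shift - transport.threshold_voltage,
                v_d_arr,
                derived.beta,
                derived.critical_voltage,
            )

        popt, _ = curve_fit(current_of_shift, v_d, i_obs, p0=[0.5], maxfev=2000)
        shifts.append((float(f_g), float(popt[0])))
    if len(shifts) < 2:
        raise IdentifiabilityError(
            "two-stage law fit needs at least 2 distinct positive glucose conditions"
        )
    table = pd.DataFrame(sorted(shifts), columns=["f_glucose", "v_glucose"])

    def law_form(f_g, a, k):
        return a - np.exp(-k * f_g)

    popt, _ = curve_fit(
        law_form,
        table["f_glucose"].to_numpy(),
        table["v_glucose"].to_numpy(),
        p0=[1.4, 0.1],
        bounds=([0.5, 1e-3], [3.0, 1.0]),
        maxfev=5000,
    )
    return TwoStageLawFit(
        per_condition_shifts=table,
        law=GlucoseResponseLaw(asymptote_voltage=float(popt[0]), rate_constant=float(popt[1])),
    )
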