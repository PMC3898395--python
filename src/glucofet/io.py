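"""File formats: the I-V CSV interchange format and the YAML run config.

CSV contract (strict): header exactly
``v_drain_V,i_drain_uA,f_pbs_mg_per_mL,f_glucose_mM,label`` — currents live
in microamperes on disk and amperes in memory. Values are written with 12
significant digits so a write/read round trip is lossless at that precision
and row order is preserved.

The run configuration is a YAML file with fixed sections (``device``,
``transport``, ``sensing``, ``sweep``, ``noise``, ``fit``); unknown keys are
rejected with the line number where they appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import IVDataset
from .constants import AMPERE_TO_MICROAMPERE
from .device import DeviceGeometry, TransportParams
from .exceptions import ConfigError, InvalidParameterError, ParseError
from .fitting import PARAM_NAMES, FitSpec
from .sensing import GlucoseResponseLaw
from .synthetic import DEFAULT_GLUCOSE_LEVELS_MM, NoiseModel

__all__ = ["read_iv_csv", "write_iv_csv", "RunConfig", "load_config"]

CSV_COLUMNS = ["v_drain_V", "i_drain_uA", "f_pbs_mg_per_mL", "f_glucose_mM", "label"]
_NUMERIC_CSV = CSV_COLUMNS[:4]


def write_iv_csv(dataset: IVDataset, path) -> None:
    """Write an :class:`IVDataset` to the strict CSV format (uA on disk)."""
    frame = dataset.to_dataframe()
    out = pd.DataFrame(
        {
            "v_drain_V": frame["v_drain"],
            "i_drain_uA": frame["i_drain"] * AMPERE_TO_MICROAMPERE,
            "f_pbs_mg_per_mL": frame["f_pbs"],
            "f_glucose_mM": frame["f_glucose"],
            "label": frame["label"],
        }
    )
    out.to_csv(path, index=False, float_format="%.12g")


def read_iv_csv(path) -> IVDataset:
    """Read the strict I-V CSV format back into an :class:`IVDataset`.

    Raises :class:`ParseError` (with row numbers, header = row 1) for
    missing or extra columns, non-numeric cells, or duplicate
    (condition, drain-voltage) keys.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"cannot parse CSV: {exc}", path=path) from exc
    got = list(raw.columns)
    missing = [c for c in CSV_COLUMNS if c not in got]
    extra = [c for c in got if c not in CSV_COLUMNS]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing column(s) {missing}")
        if extra:
            parts.append(f"unexpected column(s) {extra}")
        raise ParseError("; ".join(parts), path=path, line=1)
    data = {}
    for col in _NUMERIC_CSV:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & ~raw[col].str.strip().str.lower().isin(["nan"])
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(
                f"non-numeric value {raw[col][bad.idxmax()]!r} in column {col!r}",
                path=path,
                row=row,
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax()) + 2
            raise ParseError(f"missing value in column {col!r}", path=path, row=row)
        data[col] = converted.to_numpy(dtype=float)
    keys = pd.DataFrame(
        {
            "f_pbs": data["f_pbs_mg_per_mL"],
            "f_glucose": data["f_glucose_mM"],
            "v_drain": data["v_drain_V"],
        }
    )
    dup = keys.duplicated()
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise ParseError(
            "duplicate (f_pbs, f_glucose, v_drain) key", path=path, row=row
        )
    frame = pd.DataFrame(
        {
            "v_drain": data["v_drain_V"],
            "i_drain": data["i_drain_uA"] / AMPERE_TO_MICROAMPERE,
            "f_pbs": data["f_pbs_mg_per_mL"],
            "f_glucose": data["f_glucose_mM"],
            "label": raw["label"],
        }
    )
    try:
        return IVDataset(frame)
    except InvalidParameterError as exc:
        raise ParseError(str(exc), path=path) from exc


# --------------------------------------------------------------------- #
# Run configuration
# --------------------------------------------------------------------- #

_SCHEMA: dict[str, set[str]] = {
    "device": {
        "cnt_diameter_nm",
        "channel_length_um",
        "substrate_thickness_um",
        "relative_permittivity",
    },
    "transport": {
        "mobility_m2_per_Vs",
        "saturation_velocity_m_per_s",
        "fermi_velocity_m_per_s",
        "threshold_voltage_V",
    },
    "sensing": {
        "v_gs_bare_V",
        "pbs_concentration_mg_per_mL",
        "pbs_voltage_V",
        "glucose_concentrations_mM",
        "law_asymptote_V",
        "law_rate_per_mM",
    },
    "sweep": {"v_d_start_V", "v_d_stop_V", "n_points"},
    "noise": {"multiplicative_sd", "additive_sd_uA", "seed"},
    "fit": {"free_parameters", "max_iterations", "tolerance", "bounds", "initial_values"},
}


@dataclass(frozen=True)
class RunConfig:
    """Typed run configuration: device, conditions, sweep, noise and fit."""

    geometry: DeviceGeometry = field(default_factory=DeviceGeometry)
    transport: TransportParams = field(default_factory=TransportParams)
    v_gs_bare: float = 1.5
    pbs_concentration: float = 1.0
    pbs_voltage: float = 0.6
    glucose_levels: tuple[float, ...] = DEFAULT_GLUCOSE_LEVELS_MM
    law: GlucoseResponseLaw = field(default_factory=GlucoseResponseLaw)
    v_d_start: float = 0.0
    v_d_stop: float = 0.7
    n_points: int = 71
    noise: NoiseModel = field(default_factory=NoiseModel)
    fit_spec: FitSpec = field(default_factory=FitSpec)

    def vd_grid(self) -> np.ndarray:
        return np.linspace(self.v_d_start, self.v_d_stop, self.n_points)


def _check_unknown_keys(path: Path, text: str) -> None:
    """Walk the YAML node tree and reject unknown keys with line numbers."""
    root = yaml.compose(text)
    if root is None:
        return
    if not isinstance(root, yaml.MappingNode):
        raise ConfigError("top level must be a mapping of sections", path=path, line=1)
    for key_node, value_node in root.value:
        section = key_node.value
        line = key_node.start_mark.line + 1
        if section not in _SCHEMA:
            raise ConfigError(f"unknown section {section!r}", path=path, line=line)
        if not isinstance(value_node, yaml.MappingNode):
            raise ConfigError(f"section {section!r} must be a mapping", path=path, line=line)
        for sub_key, _sub_val in value_node.value:
            if sub_key.value not in _SCHEMA[section]:
                raise ConfigError(
                    f"unknown key {section}.{sub_key.value!r}",
                    path=path,
                    line=sub_key.start_mark.line + 1,
                )


def _number(section: dict, key: str, default: float) -> float:
    # YAML 1.1 reads exponent forms like 8.0e5 (no sign) as strings; accept
    # any string that parses cleanly as a float.
    value = section.get(key, default)
    if isinstance(value, bool):
        raise ConfigError(f"{key} must be a number, got {value!r}")
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            raise ConfigError(f"{key} must be a number, got {value!r}") from None
    if not isinstance(value, (int, float)):
        raise ConfigError(f"{key} must be a number, got {value!r}")
    return float(value)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration into a :class:`RunConfig`."""
    path = Path(path)
    text = path.read_text()
    try:
        _check_unknown_keys(path, text)
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        raise ConfigError(
            f"invalid YAML: {exc}", path=path, line=(mark.line + 1 if mark else None)
        ) from exc

    dev = raw.get("device", {}) or {}
    tra = raw.get("transport", {}) or {}
    sen = raw.get("sensing", {}) or {}
    swe = raw.get("sweep", {}) or {}
    noi = raw.get("noise", {}) or {}
    fit = raw.get("fit", {}) or {}
    try:
        geometry = DeviceGeometry(
            cnt_diameter=_number(dev, "cnt_diameter_nm", 1.5) * 1e-9,
            channel_length=_number(dev, "channel_length_um", 50.0) * 1e-6,
            substrate_thickness=_number(dev, "substrate_thickness_um", 100.0) * 1e-6,
            relative_permittivity=_number(dev, "relative_permittivity", 3.3),
        )
        transport = TransportParams(
            mobility=_number(tra, "mobility_m2_per_Vs", 0.1),
            saturation_velocity=_number(tra, "saturation_velocity_m_per_s", 8.0e5),
            fermi_velocity=_number(tra, "fermi_velocity_m_per_s", 1.0e6),
            threshold_voltage=_number(tra, "threshold_voltage_V", 0.3),
        )
        law = GlucoseResponseLaw(
            asymptote_voltage=_number(sen, "law_asymptote_V", 1.42),
            rate_constant=_number(sen, "law_rate_per_mM", 0.1),
        )
        levels = sen.get("glucose_concentrations_mM", list(DEFAULT_GLUCOSE_LEVELS_MM))
        if not isinstance(levels, (list, tuple)) or not levels:
            raise ConfigError("glucose_concentrations_mM must be a nonempty list")
        noise = NoiseModel(
            multiplicative_sd=_number(noi, "multiplicative_sd", 0.0),
            additive_sd=_number(noi, "additive_sd_uA", 0.0) / AMPERE_TO_MICROAMPERE,
            seed=int(noi.get("seed", 0)),
        )
        free = tuple(fit.get("free_parameters", ("v_pbs", "law_asymptote", "law_rate")))
        bad = [p for p in free if p not in PARAM_NAMES]
        if bad:
            raise ConfigError(f"fit.free_parameters contains unknown names {bad}")
        bounds = {
            str(k): (float(v[0]), float(v[1])) for k, v in (fit.get("bounds") or {}).items()
        }
        starts = {str(k): float(v) for k, v in (fit.get("initial_values") or {}).items()}
        fit_spec = FitSpec(
            free_parameters=free,
            bounds=bounds,
            initial_values=starts,
            max_iterations=int(fit.get("max_iterations", 200)),
            tolerance=_number(fit, "tolerance", 1e-12),
        )
        n_points = int(swe.get("n_points", 71))
        if n_points < 1:
            raise ConfigError("sweep.n_points must be at least 1")
        return RunConfig(
            geometry=geometry,
            transport=transport,
            v_gs_bare=_number(sen, "v_gs_bare_V", 1.5),
            pbs_concentration=_number(sen, "pbs_concentration_mg_per_mL", 1.0),
            pbs_voltage=_number(sen, "pbs_voltage_V", 0.6),
            glucose_levels=tuple(float(x) for x in levels),
            law=law,
            v_d_start=_number(swe, "v_d_start_V", 0.0),
            v_d_stop=_number(swe, "v_d_stop_V", 0.7),
            n_points=n_points,
            noise=noise,
            fit_spec=fit_spec,
        )
    except ConfigError:
        raise
    except (InvalidParameterError, TypeError, ValueError) as exc:
        raise ConfigError(str(exc), path=path) from exc
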