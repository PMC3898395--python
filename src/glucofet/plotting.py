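"""Non-normative plots: I-V families and fit overlays (currents in uA)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .calibration import IVDataset
from .constants import AMPERE_TO_MICROAMPERE

__all__ = ["plot_iv_families", "plot_fit"]


def plot_iv_families(dataset: IVDataset, ax=None):
    """One curve per solution condition, labelled by glucose concentration."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for (f_pbs, f_g), group in dataset.condition_groups():
        ax.plot(
            group["v_drain"],
            group["i_drain"] * AMPERE_TO_MICROAMPERE,
            marker=".",
            markersize=3,
            label=f"F_g = {f_g:g} mM" + ("" if f_pbs > 0 else " (no PBS)"),
        )
    ax.set_xlabel("Drain voltage $V_D$ (V)")
    ax.set_ylabel(r"Drain current $I_D$ ($\mu$A)")
    ax.legend(fontsize=7)
    return ax


def plot_fit(results, ax=None):
    """Data points with the fitted model overlaid, per condition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    frame = results.model.data.frame.copy()
    frame["i_fit"] = results.predict()
    for (f_pbs, f_g), group in frame.groupby(["f_pbs", "f_glucose"], sort=False):
        pts = ax.plot(
            group["v_drain"],
            group["i_drain"] * AMPERE_TO_MICROAMPERE,
            ".",
            markersize=3,
            label=f"data, F_g = {f_g:g} mM",
        )
        ax.plot(
            group["v_drain"],
            group["i_fit"] * AMPERE_TO_MICROAMPERE,
            "-",
            color=pts[0].get_color(),
        )
    ax.set_xlabel("Drain voltage $V_D$ (V)")
    ax.set_ylabel(r"Drain current $I_D$ ($\mu$A)")
    ax.legend(fontsize=6)
    return ax
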