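"""Per-cell directional and magnitude tuning.

Two metrics summarize how a vestibulospinal neuron encodes roll tilts:

* **Directionality index (DI)** — the difference between the mean peak ΔF/F
  responses to ipsilateral and contralateral 30° steps, normalized by their
  sum: DI = (R_ipsi - R_contra) / (R_ipsi + R_contra).  +1 is purely
  ipsilateral-preferring, 0 is nondirectional.  DI is undefined (flagged, not
  clamped) when the denominator is not positive.

* **Roll sensitivity** — the slope, in ΔF/F per degree, of an ordinary
  least-squares line (two free parameters) fit to the individual per-trial
  peak responses pooled over all step magnitudes in one direction.  The free
  intercept absorbs magnitude-independent response components (e.g. the
  phasic transient evoked by the return step itself).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traces import cv_table, responsiveness_table, trial_cv

__all__ = ["DirectionalityIndex", "SlopeFit", "directionality_index",
           "sensitivity_slope", "tune_cells"]


@dataclass(frozen=True)
class DirectionalityIndex:
    value: float
    defined: bool


@dataclass(frozen=True)
class SlopeFit:
    """OLS line fit of peak ΔF/F vs step magnitude for one cell/direction."""

    slope: float          # ΔF/F per degree
    intercept: float      # ΔF/F
    stderr: float         # standard error of the slope
    intercept_stderr: float
    n: int


def directionality_index(r_ipsi: float, r_contra: float) -> DirectionalityIndex:
    """DI = (R_ipsi - R_contra) / (R_ipsi + R_contra) for 30° steps.

    Negative mean peaks are allowed in the numerator; only a non-positive
    denominator makes the index undefined (``defined=False``, value NaN).
    """
    denom = r_ipsi + r_contra
    if not np.isfinite(denom) or denom <= 0:
        return DirectionalityIndex(float("nan"), False)
    return DirectionalityIndex(float((r_ipsi - r_contra) / denom), True)


def sensitivity_slope(magnitudes_deg: np.ndarray, peaks: np.ndarray) -> SlopeFit:
    """OLS fit of individual trial peaks against step magnitude (degrees).

    All trial peaks are pooled (not per-magnitude means); 0° baseline points
    are not part of the fit.  Raises ``ValueError`` if fewer than two distinct
    magnitudes or fewer than two points are supplied (slope unidentifiable).
    """
    x = np.asarray(magnitudes_deg, float)
    y = np.asarray(peaks, float)
    if len(x) != len(y):
        raise ValueError("magnitudes and peaks must have equal length")
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise ValueError(
            "sensitivity slope needs trial peaks at >= 2 distinct step magnitudes"
        )
    fit = stats.linregress(x, y)
    return SlopeFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        stderr=float(fit.stderr),
        intercept_stderr=float(fit.intercept_stderr),
        n=len(x),
    )


def tune_cells(
    peak_table: pd.DataFrame,
    *,
    di_magnitude_deg: float = 30.0,
    paired: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cell tuning summary from a step peak-response table.

    Columns: mean 30° peaks per direction, DI (+ ``di_defined``), slope and
    intercept ± SE per direction, per-direction responsiveness at the DI
    magnitude, and the CV of ipsilateral 30° step peaks.
    """
    steps = peak_table[peak_table["stim_kind"] == "step"]
    resp = responsiveness_table(steps, paired=paired, alpha=alpha)
    rows = []
    for cell, g in steps.groupby("cell_id", sort=False, observed=True):
        row: dict = {"cell_id": cell}
        means = {}
        for d in ("ipsi", "contra"):
            gd = g[g["stim_direction"] == d]
            at_mag = gd[gd["stim_magnitude_deg"] == di_magnitude_deg]
            means[d] = at_mag["peak_response"].mean() if len(at_mag) else float("nan")
            row[f"mean_peak_{d}_{di_magnitude_deg:g}"] = means[d]
            if len(gd) >= 2 and gd["stim_magnitude_deg"].nunique() >= 2:
                fit = sensitivity_slope(
                    gd["stim_magnitude_deg"].to_numpy(), gd["peak_response"].to_numpy()
                )
                row[f"slope_{d}"] = fit.slope
                row[f"slope_{d}_se"] = fit.stderr
                row[f"intercept_{d}"] = fit.intercept
            else:
                row[f"slope_{d}"] = row[f"slope_{d}_se"] = float("nan")
                row[f"intercept_{d}"] = float("nan")
            r = resp[
                (resp["cell_id"] == cell)
                & (resp["stim_direction"] == d)
                & (resp["stim_magnitude_deg"] == di_magnitude_deg)
            ]
            row[f"responsive_{d}"] = bool(r["responsive"].iloc[0]) if len(r) else False
        di = directionality_index(means["ipsi"], means["contra"])
        row["di"] = di.value
        row["di_defined"] = di.defined
        ipsi_top = g[
            (g["stim_direction"] == "ipsi")
            & (g["stim_magnitude_deg"] == di_magnitude_deg)
        ]
        row["cv_ipsi"] = trial_cv(ipsi_top["peak_response"].to_numpy())
        rows.append(row)
    return pd.DataFrame(rows)
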