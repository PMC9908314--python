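"""ΔF/F normalization, response windows, and per-trial scalar responses.

Raw fluorescence is normalized to ΔF/F = (F - F0)/F0 under one of two schemes:

``trial_baseline``
    F0 is the mean fluorescence over the last 5 s of the trial's horizontal
    baseline period.  Used when every measurement is made at horizontal.
``anesthetized_baseline``
    F0 is supplied externally, from an anesthetized recording of the same cell
    at the same imaging angle.  Used when comparing activity measured at
    different angles, since the light path (and hence raw intensity) changes
    with eccentricity while anesthetized fluorescence reflects only expression
    level and imaging conditions.

Scalar responses are means of ΔF/F over 1-s windows located from the stimulus
log (never from trace features): the "peak response" is the mean over the
first second after the platform returns to horizontal (or, for eccentric-angle
imaging, the last second before the return), and the reference baseline is the
mean over the first second of the baseline period.  Windows are half-open
``[start, start + 1 s)`` on sample timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SWEEP_KEY",
    "normalize",
    "extract_peaks",
    "window_mean",
    "responsiveness_test",
    "responsiveness_table",
    "trial_cv",
    "cv_table",
    "eccentric_dynamics",
    "eccentric_dynamics_table",
    "ResponsivenessResult",
    "EccentricDynamics",
]

#: Columns identifying one stimulus-response sweep (a trial repeat).
SWEEP_KEY = ["fish_id", "cell_id", "session_id", "age_dpf", "trial_id", "repeat_id"]

_STIM_COLS = [
    "stim_kind", "stim_direction", "stim_magnitude_deg",
    "baseline_s", "hold_s", "response_s", "transition_ms",
]


def _transition_s(df: pd.DataFrame) -> pd.Series:
    return df["transition_ms"] * 1e-3


def _t_return(df: pd.DataFrame) -> pd.Series:
    """Return-to-horizontal time from the stimulus log."""
    return df["baseline_s"] + 2 * _transition_s(df) + df["hold_s"]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(
    traces: pd.DataFrame,
    scheme: str = "trial_baseline",
    f0_source: dict | pd.Series | None = None,
) -> pd.DataFrame:
    """Add ``dff``, ``F0`` and ``normalization_scheme`` columns to a trace table.

    Parameters
    ----------
    traces : tidy trace table (one row per recorded volume).
    scheme : {"trial_baseline", "anesthetized_baseline"}
    f0_source : mapping cell_id -> F0, required for ``anesthetized_baseline``.
        Typically the per-cell mean fluorescence of a matched anesthetized
        recording at the same angle.

    Raises
    ------
    ValueError
        If a trial's baseline period is shorter than 5 s (trial named in the
        message), if any F0 <= 0, or if ``f0_source`` is missing a cell.
    """
    df = traces.copy()
    if scheme == "trial_baseline":
        short = df.loc[df["baseline_s"] < 5.0, "trial_id"].unique()
        if len(short):
            raise ValueError(
                f"trial_baseline normalization needs >= 5 s of baseline; "
                f"too short in trial(s) {sorted(map(str, short))}"
            )
        in_win = (df["time_s"] >= df["baseline_s"] - 5.0) & (
            df["time_s"] < df["baseline_s"]
        )
        f0 = (
            df[in_win]
            .groupby(SWEEP_KEY, sort=False, observed=True)["F"]
            .mean()
            .rename("F0")
        )
        df = df.merge(f0, on=SWEEP_KEY, how="left")
    elif scheme == "anesthetized_baseline":
        if f0_source is None:
            raise ValueError("anesthetized_baseline requires an f0_source")
        f0_map = pd.Series(f0_source, name="F0")
        missing = set(df["cell_id"].unique()) - set(f0_map.index)
        if missing:
            raise ValueError(f"f0_source missing cells: {sorted(missing)}")
        df["F0"] = df["cell_id"].map(f0_map).astype(float)
    else:
        raise ValueError(f"unknown normalization scheme {scheme!r}")

    if df["F0"].isna().any() or (df["F0"] <= 0).any():
        bad = df.loc[df["F0"].isna() | (df["F0"] <= 0), "trial_id"].unique()
        raise ValueError(f"non-positive or missing F0 in trial(s) {sorted(map(str, bad))}")
    df["dff"] = (df["F"] - df["F0"]) / df["F0"]
    df["normalization_scheme"] = scheme
    return df


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------

def window_mean(
    time_s: np.ndarray, values: np.ndarray, start: float, stop: float
) -> float:
    """Mean of ``values`` at samples with ``start <= t < stop``; NaN if empty."""
    time_s = np.asarray(time_s, float)
    values = np.asarray(values, float)
    m = (time_s >= start) & (time_s < stop)
    return float(values[m].mean()) if m.any() else float("nan")


def extract_peaks(
    ntraces: pd.DataFrame, window: str = "post_return_first_1s"
) -> pd.DataFrame:
    """One scalar response per sweep: mean ΔF/F in the stated 1-s window.

    ``window`` is ``post_return_first_1s`` (mean ΔF/F over the first second
    after the return to horizontal) or ``eccentric_last_1s`` (mean over the
    last second at the eccentric angle).  Each row also carries
    ``baseline_first_1s_mean``, the mean ΔF/F over the first second of the
    baseline period, used by the responsiveness test.

    Raises ``ValueError`` (reporting the effective sample rate) if a sweep has
    no samples inside the window.
    """
    df = ntraces
    if "dff" not in df.columns:
        raise ValueError("traces must be normalized first (missing 'dff' column)")
    if window == "post_return_first_1s":
        start = _t_return(df)
    elif window == "eccentric_last_1s":
        start = df["baseline_s"] + _transition_s(df) + df["hold_s"] - 1.0
    else:
        raise ValueError(f"unknown response window {window!r}")
    stop = start + 1.0

    keys = SWEEP_KEY + _STIM_COLS
    grouped = df.groupby(keys, sort=False, observed=True)
    in_resp = (df["time_s"] >= start) & (df["time_s"] < stop)
    in_base = df["time_s"] < 1.0

    def _agg(mask: pd.Series, name: str) -> pd.DataFrame:
        g = df[mask].groupby(keys, sort=False, observed=True)["dff"]
        return g.mean().rename(name).reset_index()

    peaks = _agg(in_resp, "peak_response")
    base = _agg(in_base, "baseline_first_1s_mean")
    out = grouped.size().rename("n_samples").reset_index()
    out = out.merge(peaks, on=keys, how="left").merge(base, on=keys, how="left")
    if out["peak_response"].isna().any():
        n_per_s = len(df) / max(df["time_s"].max(), 1e-9) / max(len(out), 1)
        bad = out.loc[out["peak_response"].isna(), "trial_id"].unique()
        raise ValueError(
            f"no samples inside the {window} window for trial(s) "
            f"{sorted(map(str, bad))}; effective sample rate ~{n_per_s:.2f}/s"
        )
    out["window"] = window
    return out.drop(columns="n_samples")


# ---------------------------------------------------------------------------
# responsiveness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponsivenessResult:
    responsive: bool
    p: float
    n: int
    testable: bool = True


def responsiveness_test(
    peaks: np.ndarray,
    baselines: np.ndarray,
    *,
    paired: bool = True,
    alpha: float = 0.05,
) -> ResponsivenessResult:
    """One-tailed t test: are per-trial peaks higher than per-trial baselines?

    Paired by trial by default (each sweep's peak against the first-second
    baseline mean of that same sweep); ``paired=False`` uses a two-sample
    (Welch) variant.  A cell with fewer than two sweeps is flagged not
    testable.  Identically zero differences yield p = 1.
    """
    peaks = np.asarray(peaks, float)
    baselines = np.asarray(baselines, float)
    n = len(peaks)
    if n < 2 or (paired and len(baselines) != n):
        return ResponsivenessResult(False, float("nan"), n, testable=False)
    if paired:
        diffs = peaks - baselines
        if np.allclose(diffs, diffs[0]) and np.isclose(diffs.std(), 0.0):
            p = 1.0 if diffs[0] <= 0 else 0.0
        else:
            p = float(stats.ttest_rel(peaks, baselines, alternative="greater").pvalue)
    else:
        p = float(
            stats.ttest_ind(
                peaks, baselines, equal_var=False, alternative="greater"
            ).pvalue
        )
    return ResponsivenessResult(bool(p < alpha), p, n)


def responsiveness_table(
    peak_table: pd.DataFrame, *, paired: bool = True, alpha: float = 0.05
) -> pd.DataFrame:
    """Per (cell, stimulus) responsiveness from a peak-response table."""
    rows = []
    keys = ["cell_id", "stim_kind", "stim_direction", "stim_magnitude_deg"]
    for key, g in peak_table.groupby(keys, sort=False, observed=True):
        res = responsiveness_test(
            g["peak_response"].to_numpy(),
            g["baseline_first_1s_mean"].to_numpy(),
            paired=paired,
            alpha=alpha,
        )
        rows.append(dict(zip(keys, key)) | {
            "responsive": res.responsive, "p": res.p,
            "n_trials": res.n, "testable": res.testable,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trial-to-trial variability
# ---------------------------------------------------------------------------

def trial_cv(peaks: np.ndarray) -> float:
    """Coefficient of variation (sample SD / mean) of per-trial peaks.

    Returns NaN (undefined) for fewer than two trials or a mean near zero.
    """
    peaks = np.asarray(peaks, float)
    if len(peaks) < 2:
        return float("nan")
    mean = peaks.mean()
    if np.isclose(mean, 0.0, atol=1e-12):
        return float("nan")
    return float(peaks.std(ddof=1) / mean)


def cv_table(
    peak_table: pd.DataFrame,
    *,
    stim_kind: str = "step",
    stim_direction: str = "ipsi",
    magnitude_deg: float = 30.0,
) -> pd.DataFrame:
    """Per-cell CV of peak responses for one stimulus (default 30° ipsi step)."""
    sel = peak_table[
        (peak_table["stim_kind"] == stim_kind)
        & (peak_table["stim_direction"] == stim_direction)
        & (peak_table["stim_magnitude_deg"] == magnitude_deg)
    ]
    cv = (
        sel.groupby("cell_id", sort=False, observed=True)["peak_response"]
        .apply(lambda p: trial_cv(p.to_numpy()))
        .rename("cv")
    )
    return cv.reset_index()


# ---------------------------------------------------------------------------
# eccentric-hold dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EccentricDynamics:
    """Per-cell dynamics measured while held at the eccentric angle."""

    time_to_peak_s: float
    decay_slope: float  # ΔF/F per second, fit from the peak to hold end


def eccentric_dynamics(
    time_s: np.ndarray,
    dff: np.ndarray,
    hold_start_s: float,
    hold_end_s: float,
) -> EccentricDynamics:
    """Time-to-peak and post-peak decay slope during the eccentric hold.

    ``time_to_peak_s`` is the time from hold onset to the ΔF/F maximum within
    the hold; ``decay_slope`` is the least-squares slope of ΔF/F vs time from
    that peak to the end of the hold.  Requires a hold of at least 10 s.
    """
    if hold_end_s - hold_start_s < 10.0:
        raise ValueError(
            f"eccentric hold of {hold_end_s - hold_start_s:.1f} s is too short "
            "(need >= 10 s) to characterize hold dynamics"
        )
    time_s = np.asarray(time_s, float)
    dff = np.asarray(dff, float)
    m = (time_s >= hold_start_s) & (time_s <= hold_end_s)
    if m.sum() < 3:
        raise ValueError("too few samples inside the eccentric hold")
    th, xh = time_s[m], dff[m]
    i_peak = int(np.argmax(xh))
    t_fit, x_fit = th[i_peak:], xh[i_peak:]
    if len(t_fit) >= 2 and np.ptp(t_fit) > 0:
        slope = float(stats.linregress(t_fit, x_fit).slope)
    else:
        slope = float("nan")
    return EccentricDynamics(float(th[i_peak] - hold_start_s), slope)


def eccentric_dynamics_table(
    ntraces: pd.DataFrame,
    *,
    stim_kind: str = "step",
    stim_direction: str = "ipsi",
    magnitude_deg: float | None = None,
) -> pd.DataFrame:
    """Per-cell eccentric-hold dynamics from trial-averaged ΔF/F traces.

    Selects one stimulus (defaults to the largest ipsilateral step present),
    averages ΔF/F across that stimulus's sweeps at each time point, and
    measures time-to-peak and decay slope per cell.  Should be applied to
    anesthetized-baseline-normalized traces recorded at the eccentric angle.
    """
    df = ntraces[
        (ntraces["stim_kind"] == stim_kind)
        & (ntraces["stim_direction"] == stim_direction)
    ]
    if magnitude_deg is None:
        magnitude_deg = df["stim_magnitude_deg"].max()
    df = df[df["stim_magnitude_deg"] == magnitude_deg]
    rows = []
    for cell, g in df.groupby("cell_id", sort=False, observed=True):
        mean_trace = (
            g.groupby("time_s", sort=True, observed=True)["dff"].mean().reset_index()
        )
        hold_start = float(g["baseline_s"].iloc[0] + g["transition_ms"].iloc[0] * 1e-3)
        hold_end = hold_start + float(g["hold_s"].iloc[0])
        dyn = eccentric_dynamics(
            mean_trace["time_s"].to_numpy(), mean_trace["dff"].to_numpy(),
            hold_start, hold_end,
        )
        rows.append(
            {"cell_id": cell, "time_to_peak_s": dyn.time_to_peak_s,
             "decay_slope": dyn.decay_slope}
        )
    return pd.DataFrame(rows)
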