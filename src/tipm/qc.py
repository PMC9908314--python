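"""Imaging-stability and mounting-geometry quality control.

Field-of-view stability across the rapid tilt step is quantified by 2-D
normalized cross-correlation between the frame recorded just before the
stimulus and the frame just after it: each integer (x, y) lag is scored by the
Pearson correlation of the overlapping pixels (zero-mean, unit-variance per
overlap region), the shift is the lag of highest correlation, and the
correlation at zero lag summarizes how well the frames match without any
shift.

Mounting roll is estimated from the bilateral Mauthner lateral-dendrite
landmarks: the roll angle is the arctangent of the left-right depth (z)
difference over the mediolateral reference distance between the two dendrite
tips (171.8 µm on average).  Cell positions are expressed relative to the
Mauthner lateral-dendrite tip of the cell's own hemisphere, with +x lateral,
+y rostral and +z dorsal (ventral cells have negative z).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FrameShiftQC",
    "frame_shift",
    "roll_angle",
    "position_group_compare",
    "read_frame_pair",
    "read_positions",
    "MAUTHNER_X_REF_UM",
]

logger = logging.getLogger(__name__)

#: Average mediolateral distance between the Mauthner lateral dendrites (µm).
MAUTHNER_X_REF_UM = 171.8

_LOW_CONFIDENCE_R = 0.3


@dataclass(frozen=True)
class FrameShiftQC:
    """Result of pre/post-stimulus frame registration by integer-lag NCC."""

    dx_px: int
    dy_px: int
    dx_um: float
    dy_um: float
    r_zero_shift: float   # correlation with no shift applied
    peak_r: float         # correlation at the best lag
    peak_location: tuple[int, int]  # (dx, dy) in pixels
    low_confidence: bool  # peak correlation too weak to trust the shift
    valid: bool           # False if a frame had zero variance

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peak_location"] = list(self.peak_location)
        return d


def _overlap_corr(pre: np.ndarray, post: np.ndarray, ly: int, lx: int) -> float:
    """Pearson correlation of pre[y, x] against post[y + ly, x + lx]."""
    h, w = pre.shape
    y0, y1 = max(0, -ly), min(h, h - ly)
    x0, x1 = max(0, -lx), min(w, w - lx)
    a = pre[y0:y1, x0:x1].ravel()
    b = post[y0 + ly : y1 + ly, x0 + lx : x1 + lx].ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return float("nan")
    return float((a @ b) / denom)


def frame_shift(
    frame_pre: np.ndarray,
    frame_post: np.ndarray,
    pixel_size_um: float = 1.0,
    *,
    max_lag: int | None = None,
) -> FrameShiftQC:
    """Estimate the integer-pixel shift between two frames by NCC.

    The correlation is evaluated at every integer lag up to ``max_lag``
    (default: half the smaller image dimension, i.e. at least 50% overlap);
    the reported shift is the argmax lag, with ties broken toward the
    smallest |lag|.  Shifts are also returned in microns using
    ``pixel_size_um``.  A constant (zero-variance) frame makes the
    correlation undefined: the result is flagged ``valid=False``.
    """
    pre = np.asarray(frame_pre, float)
    post = np.asarray(frame_post, float)
    if pre.shape != post.shape or pre.ndim != 2:
        raise ValueError("frames must be two equal-sized 2-D images")
    if min(pre.shape) < 16:
        raise ValueError("frames must be at least 16 x 16 pixels")
    if pre.std() == 0 or post.std() == 0:
        logger.warning("constant frame: correlation undefined")
        return FrameShiftQC(0, 0, 0.0, 0.0, float("nan"), float("nan"),
                            (0, 0), True, False)
    if max_lag is None:
        max_lag = min(pre.shape) // 2
    lags = range(-max_lag, max_lag + 1)
    r = np.full((2 * max_lag + 1, 2 * max_lag + 1), -np.inf)
    for iy, ly in enumerate(lags):
        for ix, lx in enumerate(lags):
            r[iy, ix] = _overlap_corr(pre, post, ly, lx)
    finite = np.isfinite(r)
    r_best = r[finite].max()
    ties = np.argwhere(finite & (r == r_best))
    # prefer the smallest lag magnitude among exact ties
    norms = [((iy - max_lag) ** 2 + (ix - max_lag) ** 2, abs(iy - max_lag),
              abs(ix - max_lag), iy, ix) for iy, ix in ties]
    _, _, _, iy, ix = min(norms)
    dy, dx = iy - max_lag, ix - max_lag
    r0 = _overlap_corr(pre, post, 0, 0)
    return FrameShiftQC(
        dx_px=int(dx),
        dy_px=int(dy),
        dx_um=float(dx * pixel_size_um),
        dy_um=float(dy * pixel_size_um),
        r_zero_shift=float(r0),
        peak_r=float(r_best),
        peak_location=(int(dx), int(dy)),
        low_confidence=bool(r_best < _LOW_CONFIDENCE_R),
        valid=True,
    )


def roll_angle(dz_um: float, x_ref_um: float = MAUTHNER_X_REF_UM) -> float:
    """Mounting roll angle in degrees from the bilateral landmark depth offset.

    ``roll = degrees(arctan(dz / x_ref))``, signed by the sign of ``dz``.
    """
    if x_ref_um <= 0:
        raise ValueError("x_ref_um must be positive")
    return float(np.degrees(np.arctan2(dz_um, x_ref_um)))


def position_group_compare(
    positions: pd.DataFrame, responsive: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Compare responsive vs nonresponsive soma positions along each axis.

    ``positions`` must carry ``x_um``, ``y_um``, ``z_um`` (relative to the
    Mauthner lateral-dendrite tip).  Returns one row per axis with group
    means ± SD, group sizes, and an unpaired two-sample t test.  If either
    group has fewer than 2 cells the comparison is skipped (logged,
    ``tested=False``).
    """
    resp = np.asarray(responsive, bool)
    if len(resp) != len(positions):
        raise ValueError("one responsive label per cell required")
    rows = []
    for axis in ("x_um", "y_um", "z_um"):
        a = positions.loc[resp, axis].to_numpy(float)
        b = positions.loc[~resp, axis].to_numpy(float)
        row = {
            "axis": axis,
            "mean_responsive": float(a.mean()) if len(a) else float("nan"),
            "sd_responsive": float(a.std(ddof=1)) if len(a) > 1 else float("nan"),
            "n_responsive": len(a),
            "mean_nonresponsive": float(b.mean()) if len(b) else float("nan"),
            "sd_nonresponsive": float(b.std(ddof=1)) if len(b) > 1 else float("nan"),
            "n_nonresponsive": len(b),
        }
        if len(a) >= 2 and len(b) >= 2:
            t = stats.ttest_ind(a, b)
            row |= {"t": float(t.statistic), "p": float(t.pvalue), "tested": True}
        else:
            logger.info("axis %s: a group has < 2 cells; comparison skipped", axis)
            row |= {"t": float("nan"), "p": float("nan"), "tested": False}
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_frame_pair(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 2-page TIFF frame pair (pre, post)."""
    import tifffile

    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-page TIFF frame pair")
    return stack[0], stack[1]


def read_positions(
    path: str | Path, *, reference_prefix: str = "mauthner"
) -> tuple[pd.DataFrame, float]:
    """Read a landmark/cell-position CSV and convert to relative coordinates.

    The CSV has columns ``cell_id, hemisphere, x_um, y_um, z_um`` in absolute
    stack coordinates, including one reference row per hemisphere whose
    ``cell_id`` starts with ``reference_prefix`` (the Mauthner lateral-dendrite
    tips).  Each cell's position is returned relative to the reference of its
    own hemisphere; the second return value is the mounting roll angle in
    degrees estimated from the bilateral reference depth difference
    (left z - right z over the mediolateral reference distance).
    """
    df = pd.read_csv(path)
    required = {"cell_id", "hemisphere", "x_um", "y_um", "z_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: positions CSV needs columns {sorted(required)}")
    is_ref = df["cell_id"].str.lower().str.startswith(reference_prefix)
    refs = df[is_ref].set_index("hemisphere")
    if not {"left", "right"}.issubset(refs.index):
        raise ValueError("need one Mauthner reference row per hemisphere")
    cells = df[~is_ref].copy()
    for axis in ("x_um", "y_um", "z_um"):
        cells[axis] = cells[axis] - cells["hemisphere"].map(refs[axis])
    dz = float(refs.loc["left", "z_um"] - refs.loc["right", "z_um"])
    x_ref = float(abs(refs.loc["left", "x_um"] - refs.loc["right", "x_um"]))
    return cells.reset_index(drop=True), roll_angle(dz, x_ref or MAUTHNER_X_REF_UM)
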