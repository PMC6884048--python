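"""Hyperoxemia exposure from irregular arterial blood-gas series.

Arterial PaO2 is observed as a point process (one value per blood-gas draw).
The exposure metric is the area between the linearly-interpolated PaO2 curve
and a supraphysiologic boundary (default 13.3 kPa = 100 mm Hg), accumulated
over a fixed potential-exposure window and divided by the window length:

    dose (kPa) = AUC_{PaO2 > threshold} / window_h

so a dose of 1 kPa means the patient's average PaO2 sat 1 kPa above the
boundary for the whole window.  Interpolation is only trusted across gaps of
at most ``gap_limit_h`` (default 12 h); longer gaps contribute no area, and
unobserved time counts as zero exposure (the denominator is always the full
window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD_KPA = 13.3
DEFAULT_GAP_LIMIT_H = 12.0
DEFAULT_WINDOWS_H = (24, 72, 120, 168)

#: display conversion; the conventional 100 mm Hg boundary is 13.3 kPa
KPA_TO_MMHG = 7.50062


class Segment(NamedTuple):
    """A linear piece of the interpolated PaO2 curve.

    ``t0 < t1`` in hours since ICU admission; ``p0``/``p1`` in kPa.
    """

    t0: float
    p0: float
    t1: float
    p1: float


@dataclass(frozen=True)
class BloodGasSeries:
    """Ordered (time, PaO2) samples for one ICU episode.

    Times are hours since ICU admission and must be strictly increasing;
    samples before admission (t < 0) are rejected at construction.
    """

    episode_id: str
    times_h: np.ndarray
    pao2_kpa: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        p = np.asarray(self.pao2_kpa, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("times_h and pao2_kpa must be 1-D and equal length")
        if t.size and t.min() < 0:
            raise ValueError("samples before ICU admission (t < 0) are not allowed")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(~np.isfinite(p)) or np.any(p <= 0):
            raise ValueError("PaO2 values must be finite and positive")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "pao2_kpa", p)

    def __len__(self) -> int:
        return int(self.times_h.size)


@dataclass(frozen=True)
class ExposureSummary:
    """Window-specific hyperoxemia exposure for one episode."""

    episode_id: str
    window_h: float
    auc_kpa_h: float
    dose_kpa: float
    any_exposure: bool
    threshold_kpa: float = DEFAULT_THRESHOLD_KPA


def build_segments(
    series: BloodGasSeries,
    window_h: float,
    gap_limit_h: float = DEFAULT_GAP_LIMIT_H,
) -> list[Segment]:
    """Linear interpolation segments inside the exposure window.

    One segment per consecutive sample pair whose gap is <= ``gap_limit_h``
    (strictly longer gaps are untrusted and yield no segment).  Segments
    crossing ``window_h`` are truncated there by linear interpolation; pairs
    lying wholly beyond the window are dropped.  Empty or single-sample
    series yield an empty list.
    """
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    t, p = series.times_h, series.pao2_kpa
    out: list[Segment] = []
    for i in range(len(t) - 1):
        t0, t1 = float(t[i]), float(t[i + 1])
        if t1 - t0 > gap_limit_h or t0 >= window_h:
            continue
        p0, p1 = float(p[i]), float(p[i + 1])
        if t1 > window_h:
            p1 = p0 + (p1 - p0) * (window_h - t0) / (t1 - t0)
            t1 = window_h
        out.append(Segment(t0, p0, t1, p1))
    return out


def segment_area_above_threshold(
    segment: Segment, threshold_kpa: float = DEFAULT_THRESHOLD_KPA
) -> float:
    """Exact area (kPa*h) of max(0, line(t) - threshold) over one segment.

    Trapezoid when both endpoints exceed the boundary, triangle from the
    crossing point when only one does, zero otherwise (a value exactly at
    the boundary is not hyperoxemic).  Zero-duration segments contribute 0.
    """
    d = segment.t1 - segment.t0
    if d <= 0:
        return 0.0
    e0 = segment.p0 - threshold_kpa
    e1 = segment.p1 - threshold_kpa
    if e0 <= 0 and e1 <= 0:
        return 0.0
    if e0 >= 0 and e1 >= 0:
        return 0.5 * (e0 + e1) * d
    # one endpoint above: triangle between the crossing point and that endpoint
    hi = max(e0, e1)
    return 0.5 * hi * hi * d / (abs(e0) + abs(e1))


def compute_exposure(
    series: BloodGasSeries,
    window_h: float,
    threshold_kpa: float = DEFAULT_THRESHOLD_KPA,
    gap_limit_h: float = DEFAULT_GAP_LIMIT_H,
) -> ExposureSummary:
    """Window-specific dose, cumulative exposure and any-exposure flag.

    Unobserved time (before the first sample, inside long gaps, after the
    last sample) is assumed unexposed: the AUC sums only over trusted
    segments while the dose denominator is the full window.  An empty
    series is a valid zero-exposure episode, not an error.
    """
    segments = build_segments(series, window_h, gap_limit_h)
    auc = float(
        sum(segment_area_above_threshold(s, threshold_kpa) for s in segments)
    )
    return ExposureSummary(
        episode_id=series.episode_id,
        window_h=window_h,
        auc_kpa_h=auc,
        dose_kpa=auc / window_h,
        any_exposure=auc > 0.0,
        threshold_kpa=threshold_kpa,
    )


def _pair_arrays(
    episode_idx: np.ndarray, t: np.ndarray, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Consecutive same-episode sample pairs from sorted flat arrays."""
    same = episode_idx[1:] == episode_idx[:-1]
    return episode_idx[:-1][same], t[:-1][same], t[1:][same], p[:-1][same], p[1:][same]


def _segment_area_vec(
    t0: np.ndarray,
    p0: np.ndarray,
    t1: np.ndarray,
    p1: np.ndarray,
    threshold: float,
) -> np.ndarray:
    d = t1 - t0
    e0 = p0 - threshold
    e1 = p1 - threshold
    both_above = (e0 >= 0) & (e1 >= 0)
    any_above = (e0 > 0) | (e1 > 0)
    hi = np.maximum(e0, e1)
    denom = np.abs(e0) + np.abs(e1)
    denom = np.where(denom == 0, 1.0, denom)
    tri = 0.5 * hi * hi * d / denom
    trap = 0.5 * (e0 + e1) * d
    area = np.where(both_above, trap, np.where(any_above, tri, 0.0))
    return np.where(d > 0, area, 0.0)


def compute_exposure_table(
    blood_gas: pd.DataFrame,
    episode_ids: Sequence[str],
    window_h: float,
    threshold_kpa: float = DEFAULT_THRESHOLD_KPA,
    gap_limit_h: float = DEFAULT_GAP_LIMIT_H,
) -> pd.DataFrame:
    """Vectorized :func:`compute_exposure` over a whole blood-gas table.

    Parameters
    ----------
    blood_gas
        Long table with columns ``episode_id``, ``t_h``, ``pao2_kpa``.
    episode_ids
        Episodes to report (episodes without samples get zero exposure).

    Returns one row per requested episode with columns ``episode_id``,
    ``window_h``, ``auc_kpa_h``, ``dose_kpa``, ``any_exposure``,
    ``threshold_kpa``.
    """
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    episode_ids = list(episode_ids)
    bg = blood_gas[blood_gas["t_h"] >= 0]
    bg = bg.sort_values(["episode_id", "t_h"], kind="mergesort")
    codes, uniques = pd.factorize(bg["episode_id"].to_numpy())
    t = bg["t_h"].to_numpy(dtype=float)
    p = bg["pao2_kpa"].to_numpy(dtype=float)

    eidx, t0, t1, p0, p1 = _pair_arrays(codes, t, p)
    keep = ((t1 - t0) <= gap_limit_h) & (t0 < window_h) & (t1 > t0)
    eidx, t0, t1, p0, p1 = eidx[keep], t0[keep], t1[keep], p0[keep], p1[keep]
    over = t1 > window_h
    if np.any(over):
        frac = (window_h - t0[over]) / (t1[over] - t0[over])
        p1 = p1.copy()
        t1 = t1.copy()
        p1[over] = p0[over] + (p1[over] - p0[over]) * frac
        t1[over] = window_h
    areas = _segment_area_vec(t0, p0, t1, p1, threshold_kpa)
    auc_per_code = np.bincount(eidx, weights=areas, minlength=len(uniques))

    auc = pd.Series(auc_per_code, index=uniques).reindex(episode_ids).fillna(0.0)
    out = pd.DataFrame(
        {
            "episode_id": pd.Series(episode_ids, dtype=object),
            "window_h": float(window_h),
            "auc_kpa_h": auc.to_numpy(),
            "dose_kpa": auc.to_numpy() / window_h,
            "any_exposure": auc.to_numpy() > 0.0,
            "threshold_kpa": threshold_kpa,
        }
    )
    return out


def series_from_frame(episode_id: str, frame: pd.DataFrame) -> BloodGasSeries:
    """Build a :class:`BloodGasSeries` from the rows of one episode."""
    sub = frame[frame["episode_id"] == episode_id].sort_values("t_h")
    return BloodGasSeries(
        episode_id=episode_id,
        times_h=sub["t_h"].to_numpy(dtype=float),
        pao2_kpa=sub["pao2_kpa"].to_numpy(dtype=float),
    )
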