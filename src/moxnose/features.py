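"""Curve-shape features of normalized sensor responses.

Every acquisition is first normalized to its first resistance value R0; all
five features are then computed on the dimensionless ratio r = R/R0 and are
therefore invariant to the channel's absolute resistance scale:

* ``delta_r`` — magnitude of the response excursion during the exposure
  (analysis) window: ``1 - min(r)`` for n-type, ``max(r) - 1`` for p-type.
* ``deriv_extremum`` — the exposure spike of the first derivative (minimum
  for n-type, maximum for p-type), estimated by central differences on a
  lightly smoothed curve; the recovery spike is excluded.
* ``area_to_extremum`` — trapezoidal area under r from the start of the
  acquisition to the first global extremum.
* ``total_area`` — trapezoidal area under r over the whole acquisition.
* ``transition_time`` — 10-90 % fall time (n-type) or rise time (p-type),
  reference levels measured from the baseline toward the extremum as
  fractions of the realized amplitude, crossings linearly interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import FEATURE_NAMES, DesignManifest
from .simulate import ResponseCurve, SensorDataset

__all__ = [
    "NormalizedCurve",
    "normalize",
    "delta_r",
    "deriv_extremum",
    "area_to_extremum",
    "total_area",
    "transition_time",
    "feature_vector",
    "extract_table",
    "FeatureError",
]

logger = logging.getLogger(__name__)

#: Default moving-average smoothing window for the derivative, in seconds.
#: At the default 1 Hz sampling this is the classic 5-sample window; keeping
#: it in seconds makes the feature robust to the sampling rate.
DEFAULT_SMOOTH_S = 5.0


class FeatureError(ValueError):
    """A feature is undefined on the given curve."""


@dataclass
class NormalizedCurve:
    """Dimensionless response r = R/R0 with exposure-window markers."""

    t: np.ndarray
    r: np.ndarray
    polarity: str
    exposure_onset_s: float
    exposure_end_s: float

    def exposure_mask(self) -> np.ndarray:
        return (self.t >= self.exposure_onset_s) & (self.t <= self.exposure_end_s)


def normalize(curve: ResponseCurve) -> NormalizedCurve:
    """Normalize a resistance acquisition to its first value R0."""
    r0 = float(curve.R[0])
    if not r0 > 0:
        raise ValueError(f"first resistance value must be positive, got {r0}")
    return NormalizedCurve(
        t=np.asarray(curve.t, dtype=float),
        r=np.asarray(curve.R, dtype=float) / r0,
        polarity=curve.polarity,
        exposure_onset_s=curve.exposure_onset_s,
        exposure_end_s=curve.exposure_end_s,
    )


def _boxcar_smooth(y: np.ndarray, dt: float, width_s: float) -> np.ndarray:
    """Centered moving average of width ``width_s`` seconds, computed as the
    exact average of the linear interpolant of ``y`` over [t-w/2, t+w/2].

    Fractional trapezoid end-weights make the operator consistent across
    sampling rates (a plain k-sample window is not); edges are padded with
    the boundary values.
    """
    half = width_s / 2.0
    m = int(half / dt)
    alpha = half / dt - m
    # integral weights of the linear interpolant over the window
    w = np.ones(2 * m + 3)
    w[0] = w[-1] = alpha**2 / 2.0
    w[1] = w[-2] = 0.5 + alpha - alpha**2 / 2.0
    if m == 0:  # window narrower than one sample interval
        w = np.array([alpha**2 / 2.0, 1.0 + 2 * alpha - alpha**2, alpha**2 / 2.0])
        w /= w.sum()
    else:
        w /= 2.0 * half / dt
    pad = len(w) // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, w, mode="valid")


def _extremum_index(nc: NormalizedCurve) -> int:
    """Index of the first sample attaining the global extremum (min for
    n-type, max for p-type) over the full acquisition."""
    return int(np.argmin(nc.r) if nc.polarity == "n" else np.argmax(nc.r))


def delta_r(nc: NormalizedCurve) -> float:
    """Normalized response magnitude over the exposure window (>= 0 on
    well-formed responses)."""
    win = nc.exposure_mask()
    if not win.any():
        raise FeatureError("exposure window contains no samples")
    if nc.polarity == "n":
        return float(1.0 - np.min(nc.r[win]))
    return float(np.max(nc.r[win]) - 1.0)


def deriv_extremum(nc: NormalizedCurve, smooth_s: float = DEFAULT_SMOOTH_S) -> float:
    """Exposure spike of the first derivative of r (1/s).

    The derivative is estimated by central finite differences on a moving-
    average-smoothed curve (continuous boxcar of ``smooth_s`` seconds — the
    classic 5-sample window at the default 1 Hz sampling; ``smooth_s=0``
    disables smoothing) and the extremum is taken over the exposure window
    only, which excludes the recovery spike.
    """
    win = nc.exposure_mask()
    if int(win.sum()) < 3:
        raise FeatureError("exposure window too short for a derivative estimate")
    dt = float(np.median(np.diff(nc.t)))
    r_s = _boxcar_smooth(nc.r, dt, smooth_s) if smooth_s > 0 else nc.r
    dr = np.gradient(r_s, nc.t)
    return float(np.min(dr[win]) if nc.polarity == "n" else np.max(dr[win]))


def area_to_extremum(nc: NormalizedCurve) -> float:
    """Trapezoidal area (s) under r from the acquisition start to the first
    global extremum."""
    i = _extremum_index(nc)
    if i == 0:
        return 0.0
    return float(np.trapezoid(nc.r[: i + 1], nc.t[: i + 1]))


def total_area(nc: NormalizedCurve) -> float:
    """Trapezoidal area (s) under r over the full acquisition."""
    return float(np.trapezoid(nc.r, nc.t))


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """Time of the first crossing of ``y`` through ``level`` (y starts below),
    linearly interpolated between samples."""
    above = y >= level
    if not above.any():
        raise FeatureError(f"signal never reaches level {level:g}")
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def transition_time(nc: NormalizedCurve) -> float:
    """10-90 % fall time (n-type) / rise time (p-type), in seconds.

    Reference levels are 10 % and 90 % of the realized amplitude
    ``|r_extremum - 1|``, measured from the baseline toward the extremum;
    crossing times are linearly interpolated and the first crossings are used.
    """
    i_ext = _extremum_index(nc)
    amp = abs(float(nc.r[i_ext]) - 1.0)
    if amp == 0:
        raise FeatureError("zero response amplitude: transition time undefined")
    # Signed excursion from baseline grows from 0 to amp regardless of polarity.
    exc = (1.0 - nc.r) if nc.polarity == "n" else (nc.r - 1.0)
    t10 = _first_crossing(nc.t, exc, 0.1 * amp)
    t90 = _first_crossing(nc.t, exc, 0.9 * amp)
    return max(0.0, t90 - t10)


def feature_vector(nc: NormalizedCurve, smooth_s: float = DEFAULT_SMOOTH_S) -> dict[str, float]:
    """All five features of one normalized curve, keyed by canonical name."""
    return {
        "delta_r": delta_r(nc),
        "deriv_extremum": deriv_extremum(nc, smooth_s=smooth_s),
        "area_to_extremum": area_to_extremum(nc),
        "total_area": total_area(nc),
        "transition_time": transition_time(nc),
    }


def extract_table(
    dataset: SensorDataset,
    smooth_s: float = DEFAULT_SMOOTH_S,
    n_channels: int | None = None,
) -> pd.DataFrame:
    """Feature table: one row per replica, ``{sensor_id}.{feature}`` columns
    in canonical (sorted-sensor) order, plus the label columns.

    Replicas with a missing channel or an undefined feature are excluded and
    logged rather than propagated as NaNs.
    """
    sensor_ids = sorted({c.sensor_id for c in dataset.curves})
    expected = n_channels if n_channels is not None else len(sensor_ids)
    by_replica: dict[str, dict[str, float]] = {}
    bad: set[str] = set()
    for curve in dataset.curves:
        try:
            feats = feature_vector(normalize(curve), smooth_s=smooth_s)
        except (FeatureError, ValueError) as err:
            logger.warning("replica %s sensor %s: %s", curve.replica_id, curve.sensor_id, err)
            bad.add(curve.replica_id)
            continue
        row = by_replica.setdefault(curve.replica_id, {})
        for name, value in feats.items():
            row[f"{curve.sensor_id}.{name}"] = value

    columns = [f"{sid}.{feat}" for sid in sensor_ids for feat in FEATURE_NAMES]
    labels = dataset.manifest.labels()
    records = []
    for rid, _ in dataset.manifest.rows:
        row = by_replica.get(rid)
        if rid in bad or row is None or len(row) != expected * len(FEATURE_NAMES):
            if row is not None or rid in bad:
                logger.warning("replica %s excluded: incomplete channels", rid)
            continue
        lab = labels[rid]
        rec = {"replica_id": rid, **{c: row[c] for c in columns}}
        rec.update(
            seasoning=lab.seasoning.value,
            process=lab.process.value,
            rind_pct=lab.rind_pct,
            rind_class=lab.rind_class.value,
        )
        records.append(rec)
    out_cols = ["replica_id", *columns, "seasoning", "process", "rind_pct", "rind_class"]
    return pd.DataFrame(records, columns=out_cols)


def write_feature_csv(table: pd.DataFrame, path) -> None:
    """Write a feature table with full float precision (round-trip exact for
    the chosen string representation)."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
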