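"""Raw channel intensities -> free Ca2+ concentrations.

Implements the standard ratiometric workflow: background subtraction,
linear bleed-through unmixing, ratio formation, and the ratiometric
calibration  c = beta_kd * (R - R_min) / (R_max - R)  with its forward
counterpart fitted to titration data by nonlinear least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import (D1ER_CHANNELS, D1ER_SENSOR, FURA2_CHANNELS,
                       FURA2_SENSOR, SensorParams, TimeCourse)

MAX_BLEED_CONDITION = 1e6


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted (or known) ratiometric calibration of one sensor."""

    sensor: str
    r_min: float
    r_max: float
    beta_kd: float
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.r_max > self.r_min:
            raise ValueError("need r_max > r_min")
        if self.beta_kd <= 0:
            raise ValueError("beta_kd must be > 0")

    def forward(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return (self.r_min * self.beta_kd + self.r_max * c) / (self.beta_kd + c)


def model_from_sensor(sensor: SensorParams) -> CalibrationModel:
    """Calibration with the sensor's true parameters (known-calibration mode)."""
    return CalibrationModel(sensor=sensor.name, r_min=sensor.r_min,
                            r_max=sensor.r_max, beta_kd=sensor.beta_kd,
                            fit_diagnostics={"mode": "known"})


@dataclass
class ConcentrationTrace:
    """Per-cell free Ca2+ time series for one compartment.

    ``mask`` is True for valid frames; masked frames are excluded from all
    downstream fits.  ``clamped`` marks frames where the ratio fell at or
    below R_min and the concentration was clamped to zero.
    """

    cell_id: str
    times: np.ndarray
    c: np.ndarray
    compartment: str
    mask: np.ndarray
    clamped: Optional[np.ndarray] = None
    events: Dict[str, float] = field(default_factory=dict)

    def valid(self) -> Tuple[np.ndarray, np.ndarray]:
        """(times, c) restricted to unmasked frames."""
        return self.times[self.mask], self.c[self.mask]


def correct_bleedthrough(raw: np.ndarray, bleed: Sequence[Sequence[float]]
                         ) -> np.ndarray:
    """Linear unmixing of two background-subtracted channel series.

    ``raw`` is (2, n): rows are the observed numerator and denominator
    channels; ``bleed`` the 2x2 forward mixing matrix (observed = bleed @
    true).  Returns the unmixed (2, n) array.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != 2:
        raise ValueError("raw must be a (2, n) channel array")
    m = np.asarray(bleed, dtype=float)
    if m.shape != (2, 2):
        raise ValueError("bleed must be 2x2")
    if np.linalg.cond(m) > MAX_BLEED_CONDITION:
        raise ValueError("bleed matrix is singular or near-singular")
    return np.linalg.solve(m, raw)


def compute_ratio(numerator: np.ndarray, denominator: np.ndarray,
                  background: Tuple[float, float] = (0.0, 0.0)
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Background-subtracted ratio with a validity mask.

    Frames whose background-subtracted denominator is <= 0 are masked
    (ratio set to NaN), not dropped, so the time grid is preserved.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError("channel length mismatch")
    num = num - background[0]
    den = den - background[1]
    mask = den > 0
    ratio = np.full(num.shape, np.nan)
    ratio[mask] = num[mask] / den[mask]
    return ratio, mask


def ratio_to_concentration(ratio: np.ndarray, cal: CalibrationModel,
                           mask: Optional[np.ndarray] = None,
                           cell_id: str = "", compartment: str = "",
                           times: Optional[np.ndarray] = None,
                           events: Optional[Dict[str, float]] = None,
                           ) -> ConcentrationTrace:
    """Invert the ratiometric equation: c = beta_kd (R - Rmin) / (Rmax - R).

    R <= R_min clamps to c = 0 (flagged); R >= R_max masks the frame --
    near-saturation ratios have no stable inverse.
    """
    r = np.asarray(ratio, dtype=float)
    valid = np.isfinite(r) if mask is None else (np.asarray(mask, bool) & np.isfinite(r))
    c = np.full(r.shape, np.nan)
    clamped = np.zeros(r.shape, dtype=bool)
    out_mask = valid.copy()

    low = valid & (r <= cal.r_min)
    c[low] = 0.0
    clamped[low] = True
    high = valid & (r >= cal.r_max)
    out_mask[high] = False
    ok = valid & ~low & ~high
    c[ok] = cal.beta_kd * (r[ok] - cal.r_min) / (cal.r_max - r[ok])
    if times is None:
        times = np.arange(r.size, dtype=float)
    return ConcentrationTrace(cell_id=cell_id, times=np.asarray(times, float),
                              c=c, compartment=compartment, mask=out_mask,
                              clamped=clamped, events=dict(events or {}))


def fit_calibration(titration: pd.DataFrame, sensor: str = "D1ER",
                    r_min: Optional[float] = None,
                    r_max: Optional[float] = None) -> CalibrationModel:
    """Nonlinear least squares of the forward ratiometric curve.

    ``titration`` needs columns ``c_uM`` and ``ratio``.  By default all
    three parameters are free (initialised from the data, see module
    docs); passing ``r_min``/``r_max`` fixes the endpoints (the
    saturation-protocol mode) and fits beta_kd alone.
    """
    c = titration["c_uM"].to_numpy(dtype=float)
    r = titration["ratio"].to_numpy(dtype=float)
    if c.size < 4 or np.unique(c).size < 4:
        raise ValueError("need >= 4 distinct titration concentrations")
    span = np.log10(np.max(c) / np.max([np.min(c[c > 0]), 1e-12]))
    if span < 2.0:
        raise ValueError("titration must span >= 2 decades for identifiability")

    kd0 = math.exp(np.mean(np.log(c[c > 0])))
    fixed = r_min is not None and r_max is not None
    try:
        if fixed:
            def f(cc, kd):
                return (r_min * kd + r_max * cc) / (kd + cc)
            popt, _ = curve_fit(f, c, r, p0=[kd0], bounds=(1e-12, np.inf),
                                maxfev=20000)
            pars = (r_min, r_max, float(popt[0]))
        else:
            def f(cc, lo, hi, kd):
                return (lo * kd + hi * cc) / (kd + cc)
            p0 = [float(np.min(r)), 1.05 * float(np.max(r)), kd0]
            popt, _ = curve_fit(f, c, r, p0=p0,
                                bounds=([1e-12, 1e-12, 1e-12],
                                        [np.inf, np.inf, np.inf]),
                                maxfev=20000)
            pars = (float(popt[0]), float(popt[1]), float(popt[2]))
    except RuntimeError as err:
        raise ValueError(f"calibration fit did not converge: {err}") from err
    if not pars[1] > pars[0]:
        raise ValueError("degenerate calibration fit: r_max <= r_min")

    resid = r - (pars[0] * pars[2] + pars[1] * c) / (pars[2] + c)
    diagnostics = {
        "mode": "fixed-endpoint" if fixed else "free",
        "rss": float(np.sum(resid ** 2)),
        "rmse": float(np.sqrt(np.mean(resid ** 2))),
        "n_points": int(c.size),
    }
    return CalibrationModel(sensor=sensor, r_min=pars[0], r_max=pars[1],
                            beta_kd=pars[2], fit_diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Raw time course -> compartment concentration traces
# ---------------------------------------------------------------------------


def timecourse_to_concentrations(
    tc: TimeCourse,
    cal_er: CalibrationModel,
    cal_cyt: CalibrationModel,
    er_sensor: SensorParams = D1ER_SENSOR,
    cyt_sensor: SensorParams = FURA2_SENSOR,
) -> Dict[str, ConcentrationTrace]:
    """Full conversion of one cell's four channels to [Ca2+]_ER and
    [Ca2+]_cyt traces (background subtraction, unmixing, ratio, inversion).

    Background and bleed-through coefficients are taken from the sensor
    configuration (they are acquisition settings, known to the analyst).
    """
    out = {}
    for compartment, (num_name, den_name), sensor, cal in (
            ("ER", D1ER_CHANNELS, er_sensor, cal_er),
            ("cyt", FURA2_CHANNELS, cyt_sensor, cal_cyt)):
        num = tc.channels[num_name] - sensor.background[0]
        den = tc.channels[den_name] - sensor.background[1]
        unmixed = correct_bleedthrough(np.vstack([num, den]), sensor.bleed)
        ratio, mask = compute_ratio(unmixed[0], unmixed[1])
        out[compartment] = ratio_to_concentration(
            ratio, cal, mask=mask, cell_id=tc.cell_id,
            compartment=compartment, times=tc.times, events=tc.events)
    return out


def traces_to_concentration_frame(traces: Sequence[ConcentrationTrace]
                                  ) -> pd.DataFrame:
    """Long-format concentration table (cell_id, time_s, compartment,
    ca_uM, masked)."""
    rows = []
    for tr in traces:
        rows.append(pd.DataFrame({
            "cell_id": tr.cell_id, "time_s": tr.times,
            "compartment": tr.compartment, "ca_uM": tr.c,
            "masked": ~tr.mask}))
    return pd.concat(rows, ignore_index=True)
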