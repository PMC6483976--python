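"""Per-cell kinetic metrics of ER Ca2+ leak experiments.

Extracts, from calibrated concentration traces, the quantities used to
characterise leak: the slow pre-TG store loss rate, the pre-TG decay
half-time after compound application (threshold crossing), the post-TG
exponential decay (leak constant k and t_half = ln2/k), the leakage flux
k*[Ca2+]_ER, the post-TG cytosolic AUC, and the TG-response amplitude.

Two half-time conventions coexist deliberately: the pre-TG half-time is an
interpolated 50%-crossing of the trace, while the post-TG half-time is
derived from the fitted exponential rate.  Both are reported per cell and
then averaged across the population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .calibration import ConcentrationTrace

LN2 = math.log(2.0)
NO_DECAY_K = 1e-5   # fitted rates below this are flagged as no-decay


@dataclass(frozen=True)
class DecayFit:
    """Single-exponential decay of a [Ca2+]_ER segment:
    c(t) = plateau + (c_start - plateau) * exp(-k (t - t0))."""

    k: float
    t_half: float
    c_start: float
    plateau: float
    window: Tuple[float, float]
    rss: float
    no_decay: bool = False

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not self.no_decay and abs(self.t_half * self.k - LN2) > 1e-9:
            raise ValueError("t_half and k are inconsistent")


@dataclass(frozen=True)
class CytosolMetrics:
    """Cytosolic TG-response summary for one cell."""

    auc: Optional[float]          # uM*s, baseline-subtracted
    delta: float                  # uM, post-TG peak minus pre-TG baseline
    baseline: float               # uM
    delta_relative: Optional[float] = None   # percent of a control mean


def pre_tg_loss_rate(trace: ConcentrationTrace,
                     window: Tuple[float, float]) -> float:
    """Store loss rate over ``window`` in percent of the starting level
    per minute (positive = losing Ca2+).

    Least-squares slope of c(t) over the valid frames in the window,
    normalised by the regression value at the window start (robust to
    single-frame noise in c(t_start)).
    """
    t, c = trace.valid()
    sel = (t >= window[0]) & (t <= window[1])
    if sel.sum() < 5:
        raise ValueError("need >= 5 valid frames in the loss-rate window")
    slope, intercept = np.polyfit(t[sel], c[sel], 1)
    c_start = slope * window[0] + intercept
    if c_start <= 0:
        raise ValueError("non-positive starting level in loss-rate window")
    return float(-slope * 60.0 / c_start * 100.0)


def pre_tg_halftime(trace: ConcentrationTrace,
                    t_compound: float) -> Optional[float]:
    """Seconds from compound application until c first falls to 50% of the
    level at application, linearly interpolated; None when never reached
    (censored)."""
    t, c = trace.valid()
    if t.size == 0 or t[-1] <= t_compound:
        raise ValueError("trace does not extend beyond t_compound")
    c0 = float(np.interp(t_compound, t, c))
    target = 0.5 * c0
    after = t >= t_compound
    ta, ca = t[after], c[after]
    below = np.where(ca <= target)[0]
    if below.size == 0:
        return None
    i = below[0]
    if i == 0:
        return 0.0
    # linear interpolation between the bracketing frames
    t_cross = ta[i - 1] + (ta[i] - ta[i - 1]) * \
        (ca[i - 1] - target) / (ca[i - 1] - ca[i])
    return float(t_cross - t_compound)


def _exp_decay(t, c_start, plateau, k):
    return plateau + (c_start - plateau) * np.exp(-k * t)


def fit_post_tg_decay(trace: ConcentrationTrace, t_tg: float) -> DecayFit:
    """Exponential-plus-plateau fit of the TG-induced [Ca2+]_ER decay.

    Fitted on valid frames at t >= t_tg.  The decaying component defines
    t_half = ln2 / k.  A fitted rate below ``NO_DECAY_K`` is returned
    flagged (``no_decay=True``, t_half = inf, censored downstream).
    """
    t, c = trace.valid()
    sel = t >= t_tg
    if sel.sum() < 10:
        raise ValueError("need >= 10 valid frames after t_tg")
    ts = t[sel] - t_tg
    cs = c[sel]

    c0 = float(cs[0])
    n_tail = max(1, cs.size // 10)
    plateau0 = float(np.mean(cs[-n_tail:]))
    halfway = plateau0 + 0.5 * (c0 - plateau0)
    below = np.where(cs <= halfway)[0]
    t_half0 = ts[below[0]] if below.size and ts[below[0]] > 0 else \
        max(ts[-1] / 2.0, 1.0)
    k0 = min(max(LN2 / t_half0, 1e-6), 1.0)
    p0 = [max(c0, 1e-6), max(plateau0, 0.0), k0]
    try:
        popt, _ = curve_fit(_exp_decay, ts, cs, p0=p0,
                            bounds=([0.0, 0.0, 0.0],
                                    [np.inf, np.inf, 10.0]),
                            maxfev=20000)
    except RuntimeError as err:
        raise ValueError(f"post-TG decay fit did not converge: {err}") from err
    c_start, plateau, k = (float(v) for v in popt)
    rss = float(np.sum((cs - _exp_decay(ts, *popt)) ** 2))
    # a vanishing decaying component makes k unidentifiable: also no-decay
    amplitude = c_start - plateau
    if amplitude <= 1e-6 * max(abs(c_start), 1.0):
        k = 0.0
    if k < NO_DECAY_K:
        return DecayFit(k=k, t_half=math.inf, c_start=c_start,
                        plateau=plateau, window=(t_tg, float(t[sel][-1])),
                        rss=rss, no_decay=True)
    return DecayFit(k=k, t_half=LN2 / k, c_start=c_start, plateau=plateau,
                    window=(t_tg, float(t[sel][-1])), rss=rss)


def leakage(c_er: float, k: float) -> float:
    """Ca2+ leakage flux: the leak constant times the ER free Ca2+ level."""
    if c_er < 0 or k < 0:
        raise ValueError("inputs must be >= 0")
    return k * c_er


def post_tg_auc(trace: ConcentrationTrace,
                window: Tuple[float, float] = (1200.0, 1800.0),
                baseline_window: Optional[Tuple[float, float]] = None
                ) -> float:
    """Trapezoidal integral of (c - baseline) over ``window`` (uM*s).

    ``baseline_window`` defaults to the 60 s before compound application
    (or before the window when no compound event is annotated).  Negative
    increments are retained.  The trace must cover the whole window.
    """
    t, c = trace.valid()
    if t.size == 0 or t[0] > window[0] or t[-1] < window[1]:
        raise ValueError("trace does not cover the AUC window")
    if baseline_window is None:
        anchor = trace.events.get("compound", window[0])
        baseline_window = (anchor - 60.0, anchor)
    bsel = (t >= baseline_window[0]) & (t <= baseline_window[1])
    if not bsel.any():
        raise ValueError("no valid frames in the baseline window")
    baseline = float(np.mean(c[bsel]))
    wsel = (t >= window[0]) & (t <= window[1])
    return float(np.trapezoid(c[wsel] - baseline, t[wsel]))


def post_tg_amplitude(trace: ConcentrationTrace, t_tg: float,
                      control_mean: Optional[float] = None,
                      search_window: float = 300.0,
                      baseline_window: float = 60.0) -> CytosolMetrics:
    """Amplitude of the cytosolic TG response.

    delta = (maximum of c over (t_tg, t_tg + search_window)) minus the
    pre-TG baseline (mean over the ``baseline_window`` seconds before TG),
    floored at zero.  ``delta_relative`` is delta as a percentage of
    ``control_mean`` when one is supplied.
    """
    t, c = trace.valid()
    if t.size == 0 or t[-1] < t_tg + search_window:
        raise ValueError("trace does not cover the post-TG search window")
    bsel = (t >= t_tg - baseline_window) & (t < t_tg)
    if not bsel.any():
        raise ValueError("no valid frames in the pre-TG baseline window")
    baseline = float(np.mean(c[bsel]))
    psel = (t > t_tg) & (t <= t_tg + search_window)
    delta = max(float(np.max(c[psel])) - baseline, 0.0)
    rel = None if control_mean is None else 100.0 * delta / control_mean
    return CytosolMetrics(auc=None, delta=delta, baseline=baseline,
                          delta_relative=rel)


# ---------------------------------------------------------------------------
# Per-cell metric table
# ---------------------------------------------------------------------------


def cell_metrics(er_trace: ConcentrationTrace,
                 cyt_trace: ConcentrationTrace,
                 scenario: str = "",
                 auc_window: Tuple[float, float] = (1200.0, 1800.0)) -> dict:
    """All per-cell metrics for one (ER, cytosol) trace pair.

    Event annotations (compound, TG) drive the analysis windows.  Metrics
    whose windows the recording does not cover are reported as NaN.
    """
    events = er_trace.events or cyt_trace.events
    t_compound = events.get("compound")
    t_tg = events.get("TG")
    row = {"cell_id": er_trace.cell_id, "scenario": scenario,
           "pre_tg_loss_pct_min": np.nan, "pre_tg_t_half_s": np.nan,
           "pre_tg_censored": False, "post_tg_t_half_s": np.nan,
           "k_per_s": np.nan, "no_decay": False,
           "pre_tg_ca_er_uM": np.nan, "auc_uM_s": np.nan,
           "delta_uM": np.nan, "baseline_uM": np.nan}
    t, c = er_trace.valid()

    if t_tg is not None:
        loss_end = t_tg
    else:
        loss_end = t[-1] if t.size else 0.0
    try:
        row["pre_tg_loss_pct_min"] = pre_tg_loss_rate(er_trace, (0.0, loss_end))
    except ValueError:
        pass

    if t_compound is not None:
        try:
            th = pre_tg_halftime(er_trace, t_compound)
            row["pre_tg_t_half_s"] = np.nan if th is None else th
            row["pre_tg_censored"] = th is None
        except ValueError:
            pass

    if t_tg is not None:
        sel = (t >= t_tg - 60.0) & (t < t_tg)
        if sel.any():
            row["pre_tg_ca_er_uM"] = float(np.mean(c[sel]))
        try:
            fit = fit_post_tg_decay(er_trace, t_tg)
            row["k_per_s"] = fit.k
            row["no_decay"] = fit.no_decay
            row["post_tg_t_half_s"] = np.nan if fit.no_decay else fit.t_half
        except ValueError:
            pass
        try:
            amp = post_tg_amplitude(cyt_trace, t_tg)
            row["delta_uM"] = amp.delta
            row["baseline_uM"] = amp.baseline
        except ValueError:
            pass
        try:
            row["auc_uM_s"] = post_tg_auc(cyt_trace, auc_window)
        except ValueError:
            pass
    return row


def population_metrics(pairs: Sequence[Tuple[ConcentrationTrace,
                                             ConcentrationTrace]],
                       scenario: str = "") -> pd.DataFrame:
    """Per-cell metric table for a population of (ER, cyt) trace pairs."""
    return pd.DataFrame([cell_metrics(er, cyt, scenario=scenario)
                         for er, cyt in pairs])
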