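"""Four-parameter logistic (4PL) dose-response fitting on log dose.

The model is  y(d) = bottom + (top - bottom) / (1 + (d / ec50)^hill)  for a
decreasing response (top at low dose); the direction is inferred from the
data unless a hint is given.  A zero-dose (vehicle) anchor is mapped to a
pseudo-dose two decades below the lowest positive dose, the standard
log-dose convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

HILL_BOUNDS = (0.3, 5.0)


@dataclass(frozen=True)
class DoseResponseFit:
    ec50: float
    hill: float
    bottom: float
    top: float
    direction: str                       # "increasing" | "decreasing"
    ci: Optional[Tuple[float, float]] = None   # bootstrap CI for ec50
    low_confidence: bool = False
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.bottom == self.top:
            raise ValueError("degenerate fit: bottom == top")

    def predict(self, dose: np.ndarray) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (d / self.ec50) ** self.hill)


def _map_zero_doses(doses: np.ndarray) -> np.ndarray:
    positive = doses[doses > 0]
    if positive.size == 0:
        raise ValueError("need at least one positive dose")
    pseudo = positive.min() / 100.0
    out = doses.copy()
    out[out <= 0] = pseudo
    return out


def _fit_4pl(logd: np.ndarray, y: np.ndarray, decreasing: bool):
    def f(ld, log_ec50, hill, bottom, top):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (ld - log_ec50)))

    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    span = y_hi - y_lo
    top0, bottom0 = (y_hi, y_lo) if decreasing else (y_lo, y_hi)
    p0 = [float(np.median(logd)), 1.0, bottom0, top0]
    bounds = ([logd.min() - 2.0, HILL_BOUNDS[0], y_lo - 2 * span - 1e-9,
               y_lo - 2 * span - 1e-9],
              [logd.max() + 2.0, HILL_BOUNDS[1], y_hi + 2 * span + 1e-9,
               y_hi + 2 * span + 1e-9])
    with warnings.catch_warnings():
        # near-degenerate covariance is expected when fitting 4 points
        # with 4 parameters; only the point estimate is used
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(f, logd, y, p0=p0, bounds=bounds, maxfev=20000)
    resid = y - f(logd, *popt)
    return popt, float(np.sum(resid ** 2))


def fit_ec50(doses: Sequence[float], responses: Sequence[float],
             direction: Optional[str] = None,
             cell_values: Optional[Sequence[Sequence[float]]] = None,
             n_boot: int = 200, seed: int = 0) -> DoseResponseFit:
    """Fit the 4PL on log dose and return the EC50.

    ``doses`` may include zero (vehicle), mapped to a pseudo-dose two
    decades below the lowest tested dose.  When ``cell_values`` (per-dose
    lists of per-cell metric values) is given, a bootstrap CI for the EC50
    is computed by resampling cells within each dose.  With only three
    positive doses the fit is flagged low-confidence.
    """
    d = np.asarray(list(doses), dtype=float)
    y = np.asarray(list(responses), dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and responses must have equal length")
    n_pos = np.unique(d[d > 0]).size
    if n_pos < 3:
        raise ValueError("need >= 3 distinct positive doses")
    if np.ptp(y) == 0:
        raise ValueError("flat responses: dose-response fit is undefined")

    d_eff = _map_zero_doses(d)
    logd = np.log10(d_eff)
    if direction is None:
        # direction from the dose-ordered trend
        order = np.argsort(d_eff)
        decreasing = y[order][-1] < y[order][0]
    else:
        decreasing = direction == "decreasing"

    popt, rss = _fit_4pl(logd, y, decreasing)
    log_ec50, hill, bottom, top = popt
    span = abs(top - bottom)
    if span < 1e-12 * max(1.0, abs(top)):
        raise ValueError("dose-response fit collapsed to a flat curve")

    ci = None
    if cell_values is not None:
        rng = np.random.default_rng(seed)
        boots = []
        groups = [np.asarray(list(g), dtype=float) for g in cell_values]
        for _ in range(n_boot):
            yb = np.array([np.mean(rng.choice(g, size=g.size, replace=True))
                           for g in groups])
            try:
                pb, _ = _fit_4pl(logd, yb, decreasing)
                boots.append(10.0 ** pb[0])
            except RuntimeError:
                continue
        if len(boots) >= max(20, n_boot // 4):
            ci = (float(np.percentile(boots, 2.5)),
                  float(np.percentile(boots, 97.5)))

    return DoseResponseFit(
        ec50=float(10.0 ** log_ec50), hill=float(hill),
        bottom=float(bottom), top=float(top),
        direction="decreasing" if decreasing else "increasing",
        ci=ci, low_confidence=n_pos <= 3,
        diagnostics={"rss": rss, "n_points": int(d.size)})
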