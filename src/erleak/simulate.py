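"""Synthetic dual-sensor Ca2+ imaging data.

Generates single-cell fluorescence time courses from a two-compartment
(ER / cytosol) Ca2+ model in a Ca2+-free (EGTA) bath.  The ER loses Ca2+
through a first-order leak, J_leak = k(t) * c_er, and regains it through
SERCA pumps; the cytosol additionally loses Ca2+ to the bath through a
saturable extrusion pathway.  Compounds and thapsigargin (TG) act through a
piecewise-constant leak schedule and a SERCA multiplier (TG = instantaneous
SERCA shutdown).

Hidden concentrations are read out by forward models of two ratiometric
sensors -- an ER FRET sensor reported as F536/F469 and a cytosolic dye
reported as F340/F380 -- then mixed (bleed-through), offset (background)
and noised to produce four raw channel series per cell.

A named scenario library encodes the eeyarestatin experimental
conditions: effective leak constants are anchored to published half-times
via k = ln2 / t_half, with unpublished dose/exposure combinations filled
from four-parameter-logistic dose families (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

LN2 = math.log(2.0)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellModelParams:
    """Biophysical parameters of the two-compartment cell model.

    Concentrations in uM, rates in per-second, fluxes cytosol-referenced
    in uM/s.  ``rho`` is the effective ER:cytosol volume/buffering ratio:
    one uM lost from the ER raises the cytosol by ``rho`` uM.
    """

    c_er0: float = 400.0          # initial free ER Ca2+ (uM)
    c_cyt0: float = 0.05          # initial free cytosolic Ca2+ (uM)
    rho: float = 0.05             # ER:cytosol volume/buffering ratio
    k_base: float = LN2 / 150.0   # basal ER leak constant (1/s)
    v_serca: float = 0.11690      # max SERCA flux (uM/s, cytosol-referenced)
    km_serca: float = 0.0273861   # SERCA half-activation (uM)
    h_serca: float = 2.0          # SERCA Hill coefficient
    v_ex: float = 0.0175          # max extrusion flux to bath (uM/s)
    km_ex: float = 0.3            # extrusion half-activation (uM)
    cv_cell: float = 0.10         # log-normal cell-to-cell scatter (c_er0, leak)
    sec61_fraction: float = 0.6   # share of basal leak carried by Sec61

    def __post_init__(self) -> None:
        for name in ("c_er0", "c_cyt0", "k_base", "v_serca", "km_serca",
                     "h_serca", "v_ex", "km_ex"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must be in (0, 1)")
        if not 0.0 <= self.cv_cell <= 0.5:
            raise ValueError("cv_cell must be in [0, 0.5]")
        if not 0.0 <= self.sec61_fraction <= 1.0:
            raise ValueError("sec61_fraction must be in [0, 1]")


def calibrated_params(
    mock_t_half: float = 150.0,
    loss_rate_pct_per_min: float = 0.75,
    c_er0: float = 400.0,
    c_cyt0: float = 0.05,
    rho: float = 0.05,
    serca_headroom: float = 1.3,
    km_ex: float = 0.3,
    h_serca: float = 2.0,
    cv_cell: float = 0.10,
    sec61_fraction: float = 0.6,
) -> CellModelParams:
    """Solve the flux parameters so the mock condition matches its anchors.

    Closed-form calibration from three conditions:

    1. the basal leak constant equals the mock post-TG decay rate,
       ``k_base = ln2 / mock_t_half`` (TG removes SERCA but leaves the leak);
    2. the basal ER loss in the EGTA bath equals ``loss_rate_pct_per_min``
       of the initial store, which fixes the extrusion flux at baseline
       (at cytosolic steady state the net ER loss is J_ex / rho);
    3. the cytosol is stationary at ``c_cyt0``, which fixes the basal SERCA
       flux; ``serca_headroom`` (v_serca over the basal SERCA flux) then
       sets km_serca through the Hill curve.
    """
    k_base = LN2 / mock_t_half
    loss = loss_rate_pct_per_min / 100.0 * c_er0 / 60.0   # uM/s, ER-referenced
    j_ex0 = loss * rho
    v_ex = j_ex0 * (km_ex + c_cyt0) / c_cyt0
    j_serca0 = rho * k_base * c_er0 - j_ex0
    if j_serca0 <= 0:
        raise ValueError("basal loss rate exceeds basal leak; no steady state")
    v_serca = serca_headroom * j_serca0
    # j_serca0 / v_serca = c0^h / (km^h + c0^h)  =>  km = c0 (H-1)^(1/h)
    km_serca = c_cyt0 * (serca_headroom - 1.0) ** (1.0 / h_serca)
    return CellModelParams(
        c_er0=c_er0, c_cyt0=c_cyt0, rho=rho, k_base=k_base,
        v_serca=v_serca, km_serca=km_serca, h_serca=h_serca,
        v_ex=v_ex, km_ex=km_ex, cv_cell=cv_cell,
        sec61_fraction=sec61_fraction,
    )


HEK_PARAMS = calibrated_params(mock_t_half=150.0)
# HeLa cells (siRNA protocol) are simulated with a slower basal leak; the
# paper does not print their mock decay half-time.
HELA_PARAMS = calibrated_params(mock_t_half=250.0)


@dataclass(frozen=True)
class LeakSchedule:
    """Piecewise-constant effective leak constants and pump multipliers.

    ``k_pre`` applies from compound application until TG, ``k_post`` after
    TG; before the compound the basal constant of the cell model applies.
    ``serca_scale`` multiplies the SERCA flux before TG (0.6 emulates
    SERCA2 knockdown); after TG the pump is off.  ``leak_scale`` multiplies
    the Sec61-carried component of the leak (0.2 emulates Sec61 knockdown).
    """

    t_compound: float = 180.0
    t_tg: Optional[float] = None
    k_pre: float = LN2 / 150.0
    k_post: float = LN2 / 150.0
    serca_scale: float = 1.0
    leak_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.t_tg is not None and self.t_tg < self.t_compound:
            raise ValueError("t_tg must be >= t_compound")
        if self.k_pre < 0 or self.k_post < 0:
            raise ValueError("leak constants must be >= 0")
        if not 0.0 <= self.serca_scale <= 1.0:
            raise ValueError("serca_scale must be in [0, 1]")
        if not 0.0 <= self.leak_scale <= 1.0:
            raise ValueError("leak_scale must be in [0, 1]")


@dataclass(frozen=True)
class SensorParams:
    """Forward model of a ratiometric Ca2+ sensor and its two channels.

    The ratio responds to free Ca2+ as
    ``R(c) = (r_min * beta_kd + r_max * c) / (beta_kd + c)``,
    the exact inverse of the standard ratiometric equation
    ``c = beta_kd * (R - r_min) / (r_max - R)``.
    """

    name: str = "D1ER"
    r_min: float = 1.0
    r_max: float = 4.0
    beta_kd: float = 165.25       # apparent Kd (uM)
    f_denominator: float = 1000.0  # baseline denominator intensity (a.u.)
    background: Tuple[float, float] = (50.0, 50.0)  # (numerator, denominator)
    noise_cv: float = 0.02        # per-frame multiplicative channel noise
    bleed: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (1.0, 0.05), (0.05, 1.0))

    def __post_init__(self) -> None:
        if not self.r_max > self.r_min > 0:
            raise ValueError("need r_max > r_min > 0")
        if self.beta_kd <= 0:
            raise ValueError("beta_kd must be > 0")
        if not 0.0 <= self.noise_cv <= 0.2:
            raise ValueError("noise_cv must be in [0, 0.2]")
        if abs(np.linalg.det(np.asarray(self.bleed))) < 1e-12:
            raise ValueError("bleed matrix must be invertible")

    def forward_ratio(self, c: np.ndarray) -> np.ndarray:
        """Ratio produced by free Ca2+ concentration ``c`` (uM)."""
        c = np.asarray(c, dtype=float)
        return (self.r_min * self.beta_kd + self.r_max * c) / (self.beta_kd + c)


D1ER_SENSOR = SensorParams(name="D1ER", r_min=1.0, r_max=4.0, beta_kd=165.25)
FURA2_SENSOR = SensorParams(name="FURA2", r_min=0.3, r_max=6.0, beta_kd=5.26)

# channel naming: (numerator, denominator) per sensor
D1ER_CHANNELS = ("F536", "F469")
FURA2_CHANNELS = ("F340", "F380")


@dataclass(frozen=True)
class Scenario:
    """Named simulation recipe: schedule, population size and timing grid."""

    name: str
    leak_schedule: LeakSchedule
    n_cells: int = 30
    frame_interval: float = 10.0
    duration: float = 1800.0
    params: CellModelParams = HEK_PARAMS

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.frame_interval <= 0 or self.duration <= 0:
            raise ValueError("frame_interval and duration must be > 0")
        t_tg = self.leak_schedule.t_tg
        if t_tg is not None and t_tg >= self.duration:
            raise ValueError("t_tg must fall within the recording")


@dataclass
class TimeCourse:
    """Per-cell raw four-channel trace with event annotations.

    ``truth`` (optional) retains the hidden states and the effective leak
    constants actually applied to this cell, for round-trip testing.
    """

    cell_id: str
    times: np.ndarray
    channels: Dict[str, np.ndarray]
    events: Dict[str, float]
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, series in self.channels.items():
            if series.shape != self.times.shape:
                raise ValueError(f"channel {name} not on the shared time grid")


# ---------------------------------------------------------------------------
# Hidden-state dynamics
# ---------------------------------------------------------------------------


def _effective_leak(k_scheduled: float, params: CellModelParams,
                    leak_scale: float) -> float:
    """Scale the Sec61-carried leak component for knockdown scenarios.

    The basal leak splits into a Sec61 part (fraction ``sec61_fraction``)
    and a residual part; compound-induced gains are Sec61-mediated, so the
    knockdown multiplier applies to everything above the residual.
    """
    k_resid = (1.0 - params.sec61_fraction) * params.k_base
    return k_resid + leak_scale * max(k_scheduled - k_resid, 0.0)


def _rhs(params: CellModelParams, k: float, serca_scale: float):
    rho = params.rho
    vs, kms, h = params.v_serca * serca_scale, params.km_serca, params.h_serca
    vx, kmx = params.v_ex, params.km_ex

    def rhs(t, y):
        c_er, c_cyt, _ = y
        c_cyt = max(c_cyt, 0.0)
        j_leak = k * max(c_er, 0.0)           # ER-referenced (uM/s)
        j_serca = vs * c_cyt ** h / (kms ** h + c_cyt ** h) if vs > 0 else 0.0
        j_ex = vx * c_cyt / (kmx + c_cyt)
        d_er = -j_leak + j_serca / rho
        d_cyt = rho * j_leak - j_serca - j_ex
        return (d_er, d_cyt, j_ex)

    return rhs


def simulate_hidden(
    scenario: Scenario,
    params: CellModelParams,
    k_pre: Optional[float] = None,
    k_post: Optional[float] = None,
    leak_multiplier: float = 1.0,
    c_er0: Optional[float] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict:
    """Integrate the hidden two-compartment states on the frame grid.

    Returns a dict with times, c_er, c_cyt, cumulative extruded Ca2+
    (cytosol-referenced) and the effective per-segment leak constants.
    ``leak_multiplier`` and ``c_er0`` override per-cell scattered values.
    """
    sched = scenario.leak_schedule
    dt = scenario.frame_interval
    times = np.arange(0.0, scenario.duration + dt / 2.0, dt)

    k_pre = sched.k_pre if k_pre is None else k_pre
    k_post = sched.k_post if k_post is None else k_post
    k_pre_eff = _effective_leak(k_pre, params, sched.leak_scale) * leak_multiplier
    k_post_eff = _effective_leak(k_post, params, sched.leak_scale) * leak_multiplier
    k_base_eff = _effective_leak(params.k_base, params, sched.leak_scale) \
        * leak_multiplier

    t_tg = sched.t_tg if sched.t_tg is not None else np.inf
    segments = []  # (t_start, t_end, k, serca_scale)
    bounds = [0.0, min(sched.t_compound, scenario.duration),
              min(t_tg, scenario.duration), scenario.duration]
    seg_k = [k_base_eff, k_pre_eff, k_post_eff]
    # before TG the pump runs at serca_scale (1 normally, 0.6 for SERCA2
    # knockdown); after TG it is off (instantaneous, irreversible block)
    seg_serca = [sched.serca_scale, sched.serca_scale, 0.0]
    for i in range(3):
        if bounds[i + 1] > bounds[i]:
            segments.append((bounds[i], bounds[i + 1], seg_k[i], seg_serca[i]))

    y = [params.c_er0 if c_er0 is None else c_er0, params.c_cyt0, 0.0]
    c_er = np.empty_like(times)
    c_cyt = np.empty_like(times)
    extruded = np.empty_like(times)
    filled = np.zeros(times.shape, dtype=bool)

    def store(idx, ys):
        c_er[idx], c_cyt[idx], extruded[idx] = ys[0], ys[1], ys[2]
        filled[idx] = True

    store(0, y)
    for (t0, t1, k, serca) in segments:
        mask = (times > t0 + 1e-9) & (times <= t1 + 1e-9)
        t_eval = times[mask]
        sol = solve_ivp(_rhs(params, k, serca), (t0, t1), y,
                        t_eval=t_eval if t_eval.size else None,
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        if t_eval.size:
            idx = np.where(mask)[0]
            c_er[idx], c_cyt[idx], extruded[idx] = sol.y
            filled[idx] = True
            y = [sol.y[0][-1], sol.y[1][-1], sol.y[2][-1]]
        else:
            # still advance state through an output-free segment
            y = [sol.y[0][-1], sol.y[1][-1], sol.y[2][-1]] if sol.y.size else y
    if not filled.all():   # pragma: no cover - guards grid/segment mismatch
        raise RuntimeError("frame grid not fully covered by ODE segments")

    return {
        "times": times, "c_er": c_er, "c_cyt": np.maximum(c_cyt, 0.0),
        "extruded": extruded,
        "k_pre_eff": k_pre_eff, "k_post_eff": k_post_eff,
        "k_base_eff": k_base_eff,
    }


# ---------------------------------------------------------------------------
# Sensor forward model and channel synthesis
# ---------------------------------------------------------------------------


def _channels_from_concentration(
    c: np.ndarray, sensor: SensorParams, rng: Optional[np.random.Generator],
) -> Tuple[np.ndarray, np.ndarray]:
    """Numerator/denominator intensities: ratio -> mix -> background -> noise."""
    ratio = sensor.forward_ratio(c)
    den = np.full_like(ratio, sensor.f_denominator)
    num = ratio * den
    mixed = np.asarray(sensor.bleed) @ np.vstack([num, den])
    num_obs = mixed[0] + sensor.background[0]
    den_obs = mixed[1] + sensor.background[1]
    if rng is not None and sensor.noise_cv > 0:
        num_obs = num_obs * (1.0 + sensor.noise_cv * rng.standard_normal(num_obs.shape))
        den_obs = den_obs * (1.0 + sensor.noise_cv * rng.standard_normal(den_obs.shape))
    return np.maximum(num_obs, 0.0), np.maximum(den_obs, 0.0)


def _cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    """Independent, reproducible per-cell stream from (root seed, index)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(cell_index),)))


def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal multiplier with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def simulate_cell(
    scenario: Scenario,
    params: Optional[CellModelParams] = None,
    sensors: Tuple[SensorParams, SensorParams] = (D1ER_SENSOR, FURA2_SENSOR),
    seed: int = 0,
    cell_index: int = 0,
    keep_truth: bool = True,
) -> TimeCourse:
    """Simulate one cell: hidden ODE states plus four noisy raw channels.

    ``sensors`` is the (ER sensor, cytosolic sensor) pair.  Cell-to-cell
    scatter (log-normal, ``cv_cell``) applies to the initial ER load and,
    as a common multiplier, to the whole leak schedule of the cell.
    """
    params = scenario.params if params is None else params
    rng = _cell_rng(seed, cell_index)
    er_mult = _lognormal_multiplier(rng, params.cv_cell)
    leak_mult = _lognormal_multiplier(rng, params.cv_cell)

    hidden = simulate_hidden(scenario, params,
                             leak_multiplier=leak_mult,
                             c_er0=params.c_er0 * er_mult)

    er_sensor, cyt_sensor = sensors
    f_num_er, f_den_er = _channels_from_concentration(
        hidden["c_er"], er_sensor, rng if er_sensor.noise_cv > 0 else None)
    f_num_cyt, f_den_cyt = _channels_from_concentration(
        hidden["c_cyt"], cyt_sensor, rng if cyt_sensor.noise_cv > 0 else None)

    events = {"compound": scenario.leak_schedule.t_compound}
    if scenario.leak_schedule.t_tg is not None:
        events["TG"] = scenario.leak_schedule.t_tg

    truth = None
    if keep_truth:
        truth = {
            "c_er": hidden["c_er"], "c_cyt": hidden["c_cyt"],
            "extruded": hidden["extruded"],
            "k_pre_eff": hidden["k_pre_eff"],
            "k_post_eff": hidden["k_post_eff"],
            "k_base_eff": hidden["k_base_eff"],
            "c_er0": params.c_er0 * er_mult,
            "leak_multiplier": leak_mult,
        }
    return TimeCourse(
        cell_id=f"{scenario.name}_c{cell_index:03d}",
        times=hidden["times"],
        channels={
            D1ER_CHANNELS[0]: f_num_er, D1ER_CHANNELS[1]: f_den_er,
            FURA2_CHANNELS[0]: f_num_cyt, FURA2_CHANNELS[1]: f_den_cyt,
        },
        events=events,
        truth=truth,
    )


def simulate_population(
    scenario: Scenario,
    params: Optional[CellModelParams] = None,
    sensors: Tuple[SensorParams, SensorParams] = (D1ER_SENSOR, FURA2_SENSOR),
    seed: int = 0,
    n_cells: Optional[int] = None,
    keep_truth: bool = True,
) -> List[TimeCourse]:
    """Simulate ``n_cells`` independent cells (default: the scenario's)."""
    n = scenario.n_cells if n_cells is None else n_cells
    if n < 1:
        raise ValueError("n_cells must be >= 1")
    return [simulate_cell(scenario, params, sensors, seed=seed, cell_index=i,
                          keep_truth=keep_truth) for i in range(n)]


def simulate_titration(
    sensor: SensorParams,
    c_grid: Sequence[float],
    replicates: int = 3,
    seed: int = 0,
    noise_cv: Optional[float] = None,
) -> pd.DataFrame:
    """In-vitro style calibration titration: (c, R) pairs with noise.

    Returns a DataFrame with columns ``c_uM``, ``replicate``, ``ratio``.
    """
    c = np.asarray(list(c_grid), dtype=float)
    if c.size == 0:
        raise ValueError("empty titration grid")
    if np.any(c < 0):
        raise ValueError("titration concentrations must be >= 0")
    cv = sensor.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        r = sensor.forward_ratio(c)
        if cv > 0:
            r = r * (1.0 + cv * rng.standard_normal(r.shape))
        rows.append(pd.DataFrame({"c_uM": c, "replicate": rep, "ratio": r}))
    return pd.concat(rows, ignore_index=True)


DEFAULT_D1ER_GRID = tuple(np.geomspace(1.0, 10_000.0, 8))
DEFAULT_FURA2_GRID = tuple(np.geomspace(0.05, 100.0, 8))


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------

MOCK_T_HALF = 150.0      # mock post-TG half-time (s); design anchor
ES1_EC50_UM = 1.0        # published effective concentration (17-min series)
ES1_HILL = 1.5           # dose-family slope (design choice)
# bottom forced by the printed 94.20 s at (1 uM, 17 min) sitting at the
# midpoint of the 17-min family: B = 2 * 94.20 - T
ES1_T_HALF_FLOOR = 2.0 * 94.20 - MOCK_T_HALF
# 4-min family EC50 solved from the printed 106.61 s at (1 uM, 4 min)
_f4 = (MOCK_T_HALF - 106.61) / (106.61 - ES1_T_HALF_FLOOR)
ES1_EC50_4MIN = _f4 ** (-1.0 / ES1_HILL)
ES1_EC50_1MIN = 1.6      # short-exposure family (design, continues the trend)

# printed post-TG half-times override the family fill
_PRINTED_T_HALF = {
    (1.0, 4.0): 106.61,
    (10.0, 4.0): 43.83,
    (1.0, 17.0): 94.20,
}


def es1_t_half(dose_um: float, exposure_min: float) -> float:
    """Effective post-TG half-time (s) for an ES1 dose/exposure condition."""
    key = (float(dose_um), float(exposure_min))
    if key in _PRINTED_T_HALF:
        return _PRINTED_T_HALF[key]
    ec50 = {1.0: ES1_EC50_1MIN, 4.0: ES1_EC50_4MIN, 17.0: ES1_EC50_UM}[
        float(exposure_min)]
    span = MOCK_T_HALF - ES1_T_HALF_FLOOR
    return ES1_T_HALF_FLOOR + span / (1.0 + (dose_um / ec50) ** ES1_HILL)


def _schedule(t_half_post: float, t_half_pre: Optional[float] = None,
              exposure_min: float = 17.0, **kw) -> LeakSchedule:
    k_post = LN2 / t_half_post
    k_pre = k_post if t_half_pre is None else LN2 / t_half_pre
    return LeakSchedule(t_compound=180.0, t_tg=180.0 + 60.0 * exposure_min,
                        k_pre=k_pre, k_post=k_post, **kw)


def _noise_free_delta(k: float, base: Scenario) -> float:
    """Noise-free post-TG cytosolic amplitude for leak constant ``k``."""
    sched = replace(base.leak_schedule, k_pre=k, k_post=k)
    scen = replace(base, leak_schedule=sched)
    hidden = simulate_hidden(scen, scen.params)
    t, c = hidden["times"], hidden["c_cyt"]
    t_tg = sched.t_tg
    baseline = float(np.mean(c[(t >= t_tg - 60.0) & (t < t_tg)]))
    peak = float(np.max(c[(t > t_tg) & (t <= t_tg + 300.0)]))
    return max(peak - baseline, 0.0)


def _hela_mock_scenario() -> Scenario:
    return Scenario(name="scr-mock",
                    leak_schedule=_schedule(250.0, exposure_min=1.0),
                    n_cells=60, params=HELA_PARAMS)


def solve_noise_free_amplitude_k(target_gain_pct: float,
                                 k_hi: float = 0.011) -> float:
    """Leak constant whose noise-free cytosolic TG amplitude exceeds the
    HeLa mock amplitude by ``target_gain_pct`` percent.

    The gain is non-monotonic in k (a very fast leak partially empties the
    store during the pre-TG exposure and raises the pre-TG baseline), so
    the root is taken on the ascending branch; ``k_hi`` must stay at or
    below the gain maximum (~0.011 1/s for the default HeLa parameters,
    gain ~+78%).  The frozen scenario anchors use the pipeline-measured
    variant in :func:`erleak.io_cli.solve_measured_amplitude_k`, which
    accounts for the (noise-dependent) bias of the peak estimator; this
    noise-free version is its cheap lower-bound cross-check.
    """
    mock = _hela_mock_scenario()
    delta0 = _noise_free_delta(mock.params.k_base, mock)
    target = (1.0 + target_gain_pct / 100.0) * delta0

    def objective(k):
        return _noise_free_delta(k, mock) - target

    return brentq(objective, mock.params.k_base * 1.0001, k_hi, xtol=1e-8)


# HeLa compound leak constants anchored to the published relative TG
# amplitude gains (+32% for 10 uM ES1, +62% for 1 uM ES24), mirroring the
# k = ln2/t_half anchoring used where half-times are printed.  Frozen
# output of erleak.io_cli.solve_measured_amplitude_k (anchoring seed 101);
# tests recompute the realised gains at independent seeds.
SCR_ES1_K_POST = 0.003700747   # +32% measured amplitude gain, 10 uM ES1
SCR_ES24_K_POST = 0.004882044  # +62% measured amplitude gain, 1 uM ES24


def scenario_library() -> Dict[str, Scenario]:
    """Named map of simulation scenarios anchored to the study conditions."""
    lib: Dict[str, Scenario] = {}

    def add(name: str, sched: LeakSchedule, n_cells: int = 30,
            params: CellModelParams = HEK_PARAMS) -> None:
        lib[name] = Scenario(name=name, leak_schedule=sched, n_cells=n_cells,
                             params=params)

    k_base = HEK_PARAMS.k_base
    mock_sched = _schedule(MOCK_T_HALF, exposure_min=17.0)
    add("mock", mock_sched)

    for dose in (0.1, 1.0, 10.0):
        for expo in (1.0, 4.0, 17.0):
            t_half = es1_t_half(dose, expo)
            dose_tag = f"{dose:g}uM"
            add(f"ES1-{dose_tag}-{expo:g}min",
                _schedule(t_half, exposure_min=expo))

    k_pre_es1_10 = LN2 / es1_t_half(10.0, 17.0)
    # ES2: about half the ES1 effect; pre-TG decay about twice as slow
    k_post_es2 = k_base + 0.5 * (LN2 / es1_t_half(10.0, 17.0) - k_base)
    add("ES2-10uM", _schedule(LN2 / k_post_es2,
                              t_half_pre=LN2 / (0.5 * k_pre_es1_10)))
    # ES24: pre-TG decay about twice as fast as ES1 at 10 uM; post-TG
    # anchored to the 5-fold reduction seen with simultaneous TG+ES24
    add("ES24-10uM", _schedule(MOCK_T_HALF / 5.0,
                               t_half_pre=LN2 / (2.0 * k_pre_es1_10)))
    add("ES24-1uM", _schedule(35.0))
    add("ESR35-10uM", _schedule(MOCK_T_HALF, t_half_pre=MOCK_T_HALF))
    add("ES47-10uM", _schedule(MOCK_T_HALF * 1.16, t_half_pre=MOCK_T_HALF))
    # simultaneous TG + ES24 application: no pre-TG window
    add("TG+ES24", LeakSchedule(t_compound=180.0, t_tg=180.0,
                                k_pre=5.0 * k_base, k_post=5.0 * k_base))

    # HeLa siRNA protocol: 1-min exposure, FURA-2 readout
    hela_kb = HELA_PARAMS.k_base
    scr_mock = _schedule(LN2 / hela_kb, exposure_min=1.0)
    add("scr-mock", scr_mock, n_cells=60, params=HELA_PARAMS)
    add("scr-ES1-10uM",
        _schedule(LN2 / SCR_ES1_K_POST, exposure_min=1.0),
        n_cells=60, params=HELA_PARAMS)
    add("scr-ES24-1uM",
        _schedule(LN2 / SCR_ES24_K_POST, exposure_min=1.0),
        n_cells=60, params=HELA_PARAMS)
    for tag, t_half_post in (("mock", LN2 / hela_kb),
                             ("ES1-10uM", LN2 / SCR_ES1_K_POST),
                             ("ES24-1uM", LN2 / SCR_ES24_K_POST)):
        add(f"SEC61KD-{tag}",
            _schedule(t_half_post, exposure_min=1.0, leak_scale=0.2),
            n_cells=60, params=HELA_PARAMS)
        add(f"SERCA2KD-{tag}",
            _schedule(t_half_post, exposure_min=1.0, serca_scale=0.6),
            n_cells=60, params=HELA_PARAMS)
    return lib


# ---------------------------------------------------------------------------
# Long-format CSV export / import
# ---------------------------------------------------------------------------


def traces_to_frame(traces: Sequence[TimeCourse]) -> pd.DataFrame:
    """Long-format intensity table: cell_id, time_s, channel, intensity."""
    rows = []
    for tc in traces:
        for channel, series in tc.channels.items():
            rows.append(pd.DataFrame({
                "cell_id": tc.cell_id, "time_s": tc.times,
                "channel": channel, "intensity": series}))
    return pd.concat(rows, ignore_index=True)


def events_to_frame(traces: Sequence[TimeCourse]) -> pd.DataFrame:
    rows = [{"cell_id": tc.cell_id, "event": name, "time_s": t}
            for tc in traces for name, t in tc.events.items()]
    return pd.DataFrame(rows, columns=["cell_id", "event", "time_s"])


def truth_to_frame(traces: Sequence[TimeCourse]) -> pd.DataFrame:
    rows = []
    for tc in traces:
        if tc.truth is None:
            continue
        rows.append(pd.DataFrame({
            "cell_id": tc.cell_id, "time_s": tc.times,
            "c_er_uM": tc.truth["c_er"], "c_cyt_uM": tc.truth["c_cyt"]}))
    if not rows:
        return pd.DataFrame(columns=["cell_id", "time_s", "c_er_uM", "c_cyt_uM"])
    return pd.concat(rows, ignore_index=True)


def frame_to_traces(traces_df: pd.DataFrame,
                    events_df: Optional[pd.DataFrame] = None
                    ) -> List[TimeCourse]:
    """Rebuild TimeCourse objects from the long-format CSV schema."""
    required = {"cell_id", "time_s", "channel", "intensity"}
    missing = required - set(traces_df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    out = []
    for cell_id, group in traces_df.groupby("cell_id", sort=True):
        channels = {}
        times = None
        for channel, sub in group.groupby("channel", sort=True):
            sub = sub.sort_values("time_s")
            t = sub["time_s"].to_numpy(dtype=float)
            if times is None:
                times = t
            elif t.shape != times.shape or not np.allclose(t, times):
                raise ValueError(
                    f"cell {cell_id}: channels not on a shared time grid")
            channels[channel] = sub["intensity"].to_numpy(dtype=float)
        events = {}
        if events_df is not None and len(events_df):
            sel = events_df[events_df["cell_id"] == cell_id]
            events = dict(zip(sel["event"], sel["time_s"].astype(float)))
        out.append(TimeCourse(cell_id=str(cell_id), times=times,
                              channels=channels, events=events))
    return out
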