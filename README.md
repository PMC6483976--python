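# erleak

Simulation and analysis of **ER Ca²⁺ leak kinetics** from ratiometric
live-cell imaging.

Eeyarestatin compounds (ES1 and its analogs ES2, ES24, ESR35, ES47)
modulate the passive Ca²⁺ leak from the endoplasmic reticulum, in large
part through Sec61 translocon complexes.  Experimentally this leak is
characterised with an "online" protocol: a compound is applied during
continuous dual-sensor imaging (an ER-targeted FRET sensor read out as
F536/F469 and a cytosolic ratiometric dye read out as F340/F380), and the
leak is then unmasked by blocking SERCA pumps with thapsigargin (TG).
Because direct leak measurements on live cells cannot be re-run from
published figures alone, `erleak` re-creates the whole measurement chain
*in silico* so that every published kinetic quantity becomes a parameter
recovery exercise on synthetic data:

* **synthetic data** (`erleak.simulate`) — a two-compartment ODE of
  ER/cytosol Ca²⁺ handling in a Ca²⁺-free (EGTA) bath.  The ER leak flux is
  first-order, `J_leak = k(t)·[Ca²⁺]_ER`, opposed by a Hill-type SERCA flux
  and a saturable extrusion pathway; TG is an instantaneous, irreversible
  SERCA shutdown.  Hidden states are read out through sensor forward models
  `R(c) = (R_min·βK_d + R_max·c)/(βK_d + c)`, then bleed-through mixed,
  background offset and noised into four raw channels per cell.  A scenario
  library anchors effective leak constants to published half-times via
  `k = ln2 / t½` (e.g. 106.61 s for 1 µM ES1 after 4 min exposure).
* **calibration** (`erleak.calibration`) — background subtraction, linear
  unmixing, ratio formation and the standard ratiometric inversion
  `[Ca²⁺] = βK_d·(R − R_min)/(R_max − R)`, plus nonlinear least-squares
  fitting of calibration titrations (free or fixed-endpoint).
* **kinetics** (`erleak.kinetics`) — pre-TG store loss rate (%/min),
  interpolated pre-TG decay half-times, exponential-plus-plateau fits of
  the post-TG decay (leak constant `k`, `t½ = ln2/k`), leakage flux
  `k·[Ca²⁺]_ER`, post-TG AUC and cytosolic TG-response amplitudes.
* **dose_response** (`erleak.dose_response`) — four-parameter logistic
  EC₅₀ fits on log dose with bootstrap confidence intervals.
* **group_stats** (`erleak.group_stats`) — mean ± SEM condition summaries,
  two-sample Kolmogorov–Smirnov tests (exact enumeration for small
  samples), percent changes, normalised densitometry ratios and the
  viability correlation.
* **io_cli** (`erleak.io_cli`) — CSV schemas, YAML run configuration and
  the `erleak` command-line pipeline.

## Worked example

Simulate 30 cells under 1 µM ES1 applied 4 min before TG, analyse the raw
channels back into concentrations and kinetic metrics, and summarise:

```sh
$ erleak simulate --scenario ES1-1uM-4min --seed 42 --n-cells 30 --out run
INFO erleak: wrote 30 cells to run
$ erleak analyze --traces run/traces.csv --events run/events.csv \
    --scenario ES1-1uM-4min --out run
INFO erleak: analyzed 30 cells
$ erleak report --metrics run/metrics.csv --out report.txt
$ cat report.txt
condition summary
=================
ES1-1uM-4min: n=30 post-TG t1/2=108.30s (SEM 2.65) delta=12.017uM censored-preTG=0 no-decay=0
```

The population-mean fitted post-TG half-time, 108.30 ± 2.65 s, recovers
the configured value (`k_post = ln2 / 106.61 s⁻¹`) within 2%: the decay of
ER Ca²⁺ after SERCA blockade is exponential with rate `k`, and the small
upward offset reflects cell-to-cell scatter of the leak constant.  `delta`
is the mean cytosolic TG-response amplitude (µM above the pre-TG
baseline).  The same objects are available from Python:

```python
from erleak import run_scenario
df = run_scenario("ES1-1uM-4min", seed=42, n_cells=30)
print(df["post_tg_t_half_s"].mean())   # 108.298...
```

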