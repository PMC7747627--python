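# heattent

Toolkit for field-scale **high night temperature (HNT) stress phenotyping**
with paired heat tents. A stress tent's bang-bang thermostat targets a fixed
temperature differential (default +4.0 °C) above its dedicated unheated
control tent, using a six-sensor array, per-minute wireless control-tent
messages and a fault-tolerant logging loop. The package provides:

- `heattent.controller` — the thermostat: sensor-array averaging, the
  single-threshold heater rule (differential exactly at the setpoint ⇒ off),
  stale-message fail-safe, and a reboot/degraded fault state machine that
  never crashes on sensor read failures.
- `heattent.microclimate` — a closed-loop paired-tent microclimate simulator
  (lumped single-node thermal model, moisture and CO₂ dynamics, diurnal
  sinusoid + AR(1) ambient driver, read-level sensor fault injection) that
  runs the controller in the loop through the nightly schedule (tents close
  18:30, power 19:00, stress window 20:00–06:00, open 06:00).
- `heattent.env_analysis` — log reduction: stress-window differentials,
  per-clock-hour profiles, inter-sensor uniformity metrics, Magnus-form
  vapor pressure deficit, CO₂/RH summaries and a heater-rule audit.
- `heattent.traits` — agronomic/grain-quality statistics: percent
  differences and per-°C normalization, protein from nitrogen (×5.7),
  non-infected-seed extrapolation, emergence metrics, split-plot ANOVA
  (temperature = main plot, genotype = sub plot) with Tukey HSD letters,
  check-line positional uniformity tests, and a calibrated synthetic
  replicate-level trait generator.
- `heattent.io` — the controller CSV log schema (NA-token failed reads,
  strict header/monotone-time validation), trait tables, and checksummed
  packaged fixtures of the published starch/protein table and main-effect
  means.

## CLI

```sh
# 10 simulated nights, paired logs + ground truth + config echo
heattent simulate --seed 1 --nights 10 --out runs/demo

# differential / profile / uniformity summaries from a pair of logs
heattent analyze-env --stress runs/demo/stress.csv --control runs/demo/control.csv --out runs/env

# treatment summaries, split-plot ANOVA, check-line test (synthetic data when
# no --traits CSV is given)
heattent analyze-traits --seed 1 --delta-t 3.8 --out runs/traits

# recompute the packaged starch/protein table and compare with printed values
heattent reproduce-tables
```

`simulate` accepts a YAML config overriding `ambient`, `thermal`,
`thermal_stress` and `thermal_control` dataclass fields, e.g.

```yaml
ambient:
  mean_C: 18.0
  amplitude_C: 6.0
thermal:
  q_heat: 0.45
```

## Notes

- All timestamps are timezone-naive local clock times; the controller
  reasons in local schedule hours.
- Reported percentages round half away from zero to 2 decimals; overall
  percent differences use the mean of per-genotype treatment means, with the
  mean of per-genotype percent differences available as a secondary
  statistic.
- The simulator targets the control law's closed-loop behavior (stress-window
  mean differential ≈ +3.8 to +4.0 °C at default calibration); it does not
  replay any particular season's weather.
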