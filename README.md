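# lasersprint

Kinematic analysis of linear sprints from 100 Hz laser distance-measurement
(LDM) traces.

A rangefinder behind the start line tracks the runner's lower back and logs
distance at a nominal 100 Hz. From that single raw trace the package
computes:

- calibrated displacement past the start line (`x = d − L1`, the
  laser-to-start-line calibration distance),
- artifact detection/repair (beam dropouts, spikes) and start/end cropping
  (2-SD threshold start rule; end = 50 samples after 60 m, configurable),
- speed and acceleration via central differences, with per-variable
  moving-average smoothing,
- three speed zones (ascending / maintenance of the maximum / descending,
  maintenance bounded by a 2% tolerance below peak smoothed speed),
- 10 m section splits with interpolated boundary crossings,
- per-step gait events (touchdown = local speed minimum, toe-off = local
  speed maximum), support/flight/step times, step length and frequency,
- left/right side assignment and symmetry indices,
- descriptive statistics, Pearson correlation and a JSON/CSV report bundle.

A first-class synthetic-trace simulator (`lasersprint.simulate`) generates
100 m sprints with a mono-exponential speed rise, per-step velocity
oscillation, terminal deceleration, Gaussian sensor noise and injected
dropouts/spikes — together with the exact ground-truth event table, so
every stage of the pipeline is testable without recorded data.

## CLI

```bash
# synthesize a trace + metadata + ground truth
lasersprint simulate --seed 1 --out sim_out

# analyze a trace (row-wise or column-wise text; '.' or ',' decimals)
lasersprint analyze sim_out/trace.txt --meta sim_out/meta.yaml \
    --end-distance 100 --out analysis_out
```

`analyze` writes `report.json`, `splits.csv`, `steps.csv`, `zones.json`,
`symmetry.json` and `mask.csv`. All thresholds (start rule, end rule,
smoothing windows, gait detection) are exposed via a YAML config
(`--config`) mirroring the `AnalysisConfig` dataclass, plus common CLI
flags (`--k-sd`, `--end-distance`, `--window-n`).

For noisy field traces, enable the periodicity-validated step detector:

```python
from lasersprint import AnalysisConfig, GaitConfig
cfg = AnalysisConfig(gait=GaitConfig(
    detection_smoothing=9, detection_passes=3,
    periodic_prune=True, refine_halfwidth=5,
))
```

## Library example

```python
import lasersprint as ls

sim = ls.SimConfig(noise_sd=0.02, seed=1)
trace, truth = ls.synthesize_trace(sim)

meta = ls.MeasurementMeta(calibration_distance_L1=sim.L1,
                          first_leg_on_start="L")
result = ls.analyze_trace(trace, meta)
print(result.zones.v_max, len(result.steps))
print(result.symmetry["step_time"].symmetry_index)
```

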