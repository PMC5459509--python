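# tubeheart

Quantitative analysis of tubular-heart recordings: optical heartbeat
analysis (M-mode wall tracking, beat segmentation, arrhythmia index,
diameters, fractional shortening, contraction-phase parsing under load),
intracellular action-potential analysis (resting potential, amplitude,
burst metrics, APD10/50/90), TTL-based optical/electrical synchronization,
and dCt/ddCt expression math — together with a synthetic-recording
generator whose ground truth is analytic, used as the test oracle
throughout.

## Modules

| module | what it does |
| --- | --- |
| `tubeheart.synthgen` | synthetic movies, diameter traces, voltage traces and TTL-synchronized pairs with exact programmed ground truth (presets: `wt_young`, `sei_like`, `kcnq_like`, `wt_old`, `load`) |
| `tubeheart.mmode` | kymograph extraction from multi-frame TIFF movies and sub-pixel wall-edge tracking to a calibrated diameter trace |
| `tubeheart.beats` | hysteresis beat segmentation; DI/SI/heart period, arrhythmia index (SD/median of heart periods), diastolic/systolic diameters, fractional shortening, binned DI histograms, paired pre/post drug comparisons |
| `tubeheart.phases` | movement-speed thresholding into shortening / isometric / lengthening phases; shortening velocity; Pre/Load/Post protocol reports |
| `tubeheart.aps` | resting potential, event detection and grouping, single/EAD-double/burst classification, event duration, APD10/50/90 |
| `tubeheart.sync` | TTL pulse location, optical-to-electrical clock alignment, greedy 1:1 AP-to-beat matching |
| `tubeheart.qpcr` | per-sample dCt and two-step ddCt with 2^-ddCt fold change |
| `tubeheart.cli` | `tubeheart` command-line entry point and full-pipeline runner |

## CLI

```sh
tubeheart synth --preset wt_young --seed 1 --out demo/          # synthetic recording + ground truth
tubeheart mmode movie.tif --line 20,0,20,127 --fps 150 --scale 1.0 --out trace.csv
tubeheart beats trace.csv --bin 0.1 --summary summary.json
tubeheart phases trace.csv --threshold rel:0.15
tubeheart aps voltage.csv --prominence 5 --group-ms 300
tubeheart sync voltage.csv trace.csv --tolerance 0.15
tubeheart qpcr ct.csv --mode ddct --reference actin
tubeheart demo --seed 7 --out demo_out/                          # full pipeline, two cohorts
```

Exit codes: 0 ok, 1 usage error, 2 data error.  `tubeheart demo` also
accepts an INI config (`--config run.ini`, section `[run]`) and is
deterministic for a fixed seed.

Traces are plain CSV (`time_s,value` for diameters; `time_s,mv[,ttl]` for
voltage), movies are multi-frame grayscale TIFF, tables/summaries are
CSV/JSON.

## Conventions

- 0-based pixel-centre coordinates; half-open `[start, end)` intervals.
- Systolic interval runs from contraction onset (departure from the
  diastolic plateau) to relaxation end (return to it); the diastolic
  interval is the plateau span to the next onset.
- Arrhythmia index uses the sample SD (n-1) of heart periods over their
  median.
- APDs are referenced to the 10%-amplitude upstroke crossing by default
  (`apd_reference="peak"` for peak-referenced values).
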