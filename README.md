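# zeitfly

Video-tracking circadian ethomics for flies, end to end and fully testable on
synthetic data with known ground truth:

- **`synthetic_data`** — parameterized fly behavior generator (bimodal daily
  activity, pre-dawn anticipation ramp, lights-on startle, siesta, two-state
  wake/sleep bouts) producing 1 Hz trajectories in an 80×8×8 mm chamber,
  rendered grayscale frame sequences, and confocal-like intensity stacks with
  a known-intensity blob.
- **`tracking`** — background-model segmentation of frame sequences to 1 Hz
  trajectories in millimetres (temporal-median background, Otsu or fixed
  threshold, largest-component rule, linear interpolation of gaps ≤ 5 s).
- **`metrics`** — displacement activity series, sleep scoring (≥ 5 min below
  one body length/s), daytime/nighttime sleep summaries, binned average
  activity profiles, and the morning anticipation index
  (MAI = activity in ZT21–24 / activity in ZT18–24, averaged over the first
  three complete days).
- **`dam_emulation`** — virtual single-infrared-beam monitor: per-minute beam
  crossing counts, monitor-convention sleep from zero-count runs, and a
  paired video-vs-beam comparison that reproduces the beam monitor's
  sleep-overestimation bias.
- **`stats`** — formula-level test battery: D'Agostino–Pearson normality
  gate with log-retest, Kruskal–Wallis (tie-corrected) with Dunn's post hoc,
  one-/two-way ANOVA (Type-II SS) with Tukey HSD, Scheirer–Ray–Hare,
  Wilcoxon rank tests with Benjamini–Hochberg correction, star-tier output.
- **`pdf_quant`** — fluorescence quantification: maximum-intensity
  z-projection → threshold ROI → mean immunoreactivity, with batch dispatch
  to the two-way ANOVA.
- **`io_cli`** — trajectory CSV and Trikinetics-style monitor text formats
  (lossless round trips), flat key=value run configs with content hashes,
  and the `zeitfly` CLI.

## CLI

```sh
zeitfly simulate --preset male --n 30 --days 3 --seed 7 --out runs/males
zeitfly score    --traj runs/males --days 3 --out runs/males_metrics.tsv
zeitfly stats    --metrics runs/males_metrics.tsv --test kw --out runs/kw.txt
zeitfly dam      --traj runs/males --out runs/monitor.txt --compare runs/dam_vs_video.tsv
zeitfly track    --frames frames.tif --calib calib.txt --out tracked.csv
zeitfly pdfquant --stacks stacks/ --metadata meta.tsv --out quant.tsv
zeitfly report   --traj runs/males --out runs/report
```

Presets: `male`, `virgin_female`, `mated_female`, `mated_female_declining`,
`flat`, `anticipating`, `confined` (half-chamber micro-foraging, the
beam-monitor blind spot).

## Conventions

Zeitgeber time: ZT0 = lights-on, 12:12 LD. All positional math is in
millimetres (pixels only inside `tracking`). Times are integer seconds from
experiment start; ZT is always computed, never stored. All randomness flows
from one master seed; per-fly seeds are `master + fly_index`.
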