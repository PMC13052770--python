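# motisyn

Analysis of 2D cell-migration tracks and immune-synapse imaging read-outs:

- **track_io** — TrackMate-XML / tidy-CSV track ingestion, QC filtering
  (flag exclusion, speed and length cuts, gap interpolation/splitting).
- **track_stats** — per-track one-lag and directionality statistics
  (median step size/speed, confinement ratio, linearity of forward
  progression).
- **msd_models** — overlapping-interval MSD estimation; constrained /
  Brownian / persistent-random-walk model fitting (bounded least squares,
  deterministic multi-start) on the leading 40% of each lag curve;
  small-sample AICc model selection; descriptive power-law fit; persistence
  speed/time and random-motility-coefficient extraction.
- **population** — condition-level walk-type fractions, motility
  distributions, windrose (origin-aligned) coordinates, and the full
  pipeline orchestrator.
- **synapse_metrics** — calcium F/F0 normalization and 30-min AUC, synapse
  area as the intersection of independently segmented mask movies,
  first-minute response-speed regression, MTOC docking time from the first
  derivative peak, and center-of-mass distance to the synapse interface.
- **synthetic_data** — seeded generators with ground truth: Brownian,
  exactly-discretized OU-velocity persistent walks, reflected-disc confined
  walks, imaging artifacts (localization noise, 1-2 frame gaps), calcium
  transients, and two-disc mask movies with analytic overlap.

## CLI

```sh
motisyn simulate walk --model prw --v 5 --p 10 --n-tracks 500 \
    --n-frames 100 --dt 2 --seed 7 --out tracks.csv
motisyn tracks validate tracks.csv
motisyn tracks filter tracks.csv --out filtered.csv \
    --min-frames 20 --max-speed 25 --max-gap 2
motisyn stats --in filtered.csv --out stats.csv
motisyn msd --in filtered.csv --out msd.csv --max-lag-fraction 0.4
motisyn classify --in filtered.csv --out classes.csv
motisyn summarize --in filtered.csv --out summary.json --by condition
motisyn pipeline --config run.toml
motisyn synapse calcium --in traces.csv --out ca.csv --t-zero 0
motisyn synapse area --t-cell tcell.tif --tumor tumor.tif \
    --pixel-size 0.5 --out area.csv
motisyn synapse docking --in mtoc.csv --out docking.csv
motisyn synapse comdist --image label.tif --interface y=0 --pixel-size 0.2
```

A pipeline TOML names the input, output directory, and optional overrides:

```toml
input = "tracks.csv"
outdir = "out"
fit_fraction = 0.4

[filters]
min_frames = 20
max_speed = 25.0
max_gap_frames = 2
```

## Conventions

Positions in µm, times in minutes, 2D only. Tracks are uniformly sampled
after filtering (gaps ≤ 2 frames are linearly interpolated and flagged;
longer gaps split the track). MSD fitting is unweighted, in linear MSD
space, over the leading `max(4, floor(0.4 K))` lags of each K-lag curve.
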