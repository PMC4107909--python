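# dffpipe

Calcium-imaging response profiling for slice preparations: from time-lapse
GCaMP movies to per-cell ΔF/F responder calls, cross-stimulus overlap (Venn)
statistics, normalized tuning panels, dose–response curves, and nonparametric
behavior statistics. A synthetic-data forward model with recorded ground truth
makes every stage testable by recovery.

## Pipeline

1. **preprocess** — rigid registration of every frame to frame 0
   (integer-pixel FFT cross-correlation, search bounded to ±10% of the image).
2. **roi** — per-stimulus ROI candidates from a per-pixel SNR score
   (event-window mean minus pre-event mean, over a robust SD of detrended
   pre-event residuals), area/circularity gates, and IoU-based integration of
   local ROIs into one global list.
3. **traces** — per-ROI raw traces, photobleaching baseline fit
   (exponential → linear → constant fallbacks, response windows excluded),
   3-frame smoothed peak detection, and ΔF/F responder calls at the inclusive
   30% threshold.
4. **profiling** — responder overlap summaries, percent responding (optionally
   gated on a second-channel co-label image), per-cell max-normalized tuning
   panels, and dose–response curves with threshold concentration and an
   optional Hill fit.
5. **behavior** — mount scoring (count/duration/latency) and Mann–Whitney /
   Kruskal–Wallis tests (exact enumeration for small tie-free samples, normal
   approximation with tie and continuity corrections otherwise).
6. **synthetic** — the forward model: disk-shaped somata, single-exponential
   photobleaching, difference-of-exponentials transients, tuning-class
   population structure with configurable co-response probabilities, rigid
   drift, Gaussian noise, co-label images and Poisson/exponential behavior
   event tables.

## CLI

```bash
dffpipe simulate --config config.yaml --seed 1 --out sim/       # movie + truth
dffpipe register --movie sim/movie.tif --out reg/
dffpipe detect   --movie sim/movie.tif --schedule sim/schedule.json --out det/
dffpipe analyze  --movie sim/movie.tif --schedule sim/schedule.json --out ana/
dffpipe profile  --calls ana/calls.csv --a SE --b EU --out summary.json
dffpipe behavior --events events.csv --out beh/
dffpipe run      --config config.yaml --seed 1 --out run/       # all-in-one
```

Movies are read/written as multi-page TIFF or HDF5 (uint16); schedules, ROI
lists (run-length encoded) and summaries as JSON; calls, shifts, ROI tables
and behavior tables as CSV. Runs are fully deterministic given (config, seed):
the same seed reproduces byte-identical outputs, and every run writes its
resolved config and a log beside the outputs.

## Library use

```python
import dffpipe as dp

cfg = dp.SimulationConfig(seed=1)
schedule = dp.generate_stimulus_schedule(cfg, [("SE", 1e-7), ("EU", None)])
movie, truth = dp.generate_slice_movie(cfg, schedule)
rois, matrix, shifts = dp.analyze_movie(movie, schedule)
venn = dp.overlap_summary(matrix, "SE", "EU")
print(venn.pct_b_given_a)
```
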