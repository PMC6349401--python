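# punctaloc

Object-based 3D colocalization of cytosolic foci in two-channel confocal
z-stacks, with significance judged against a randomized-placement null
model, plus FRAP (fluorescence recovery after photobleaching) correction,
normalization and mobile-fraction fitting.

The package is written for quantitative cell biologists imaging micron-scale
cytoplasmic assemblies — e.g. the dynein-assembly foci of multiciliated
cells, stress granules, or other liquid-like organelles — who need to answer
two questions from a pair of fluorescence channels:

1. **Do foci in the two channels occupy the same structures?**  Pixel
   correlation alone cannot say: two diffuse channels correlate without any
   shared organelle.  The object-based approach segments each channel's foci
   as 3D objects and measures, per focus, the fraction of its volume lying
   inside any focus of the other channel.
2. **Is the observed overlap more than chance would give?**  The same foci
   are rigidly re-placed at uniformly random in-cell positions (rejection
   sampling keeps them inside the cell and non-overlapping within a
   channel), independently per channel, and the overlap metric is recomputed
   over several synthetic replicates, yielding a per-cell background overlap
   rate.

## The algorithm

For each two-channel z-stack (channels `green` — the segmentation channel —
and `red`):

1. **Cell segmentation.**  A per-layer Otsu threshold on the green channel;
   binary layers are sum-projected and the projected island with the largest
   pixel sum (a volume proxy) is taken as the cell; per-layer masks are
   restricted to it, cleaned by morphological closing/opening, and a second
   Otsu round removes dark intracellular vacuoles.
2. **Fluorescent foreground.**  Per channel, the in-cell local median
   (disk radius 15 px) is subtracted and the result clipped at zero; signal
   near the cell edge is attenuated by a factor rising linearly with the
   2D distance *d* to the cell boundary, `f(d) = min(d/40, 1)` — 0 at the
   edge, 0.5 at 20 px, 1 at 40 px — suppressing bright-membrane artifacts.
3. **Detection.**  Per-layer multiscale Laplacian-of-Gaussian (σ = 2–8 px)
   maxima above a relative response threshold seed the foci.
4. **Segmentation.**  A marker-seeded watershed on the negated foreground,
   restricted to the support `{foreground > 0}`, delineates each focus body.
5. **Measurement.**  Focus intensity is the summed foreground over its basin.
6. **3D collation.**  Basins sharing at least one (y, x) pixel in adjacent
   z-layers are chained into 3D objects (connected components).
7. **Overlap metric.**  Per 3D focus: voxels inside any other-channel focus,
   divided by its total voxels.
8. **Null model.**  Both channels' foci are independently randomized within
   the cell (10 replicates by default) and the metric recomputed.

A pixel-based Pearson correlation over in-cell voxels is reported alongside
as the conventional global readout.

FRAP traces (CSV of bleach/reference/background ROI means) are
double-normalized — background-subtracted, divided by the reference ROI to
correct acquisition bleaching, and scaled so the pre-bleach mean is 1 — then
fit with a single-exponential recovery
`F(t) = f0 + (f_inf − f0)(1 − e^{−t/τ})`; the mobile fraction is
`100·(f_inf − f0)/(1 − f0)` and the half-time is `τ·ln 2`.

A synthetic-data generator renders full scenes with known ground truth
(irregular cell, dark vacuoles, bright rim, 1–3 µm irregular foci with a
controllable cross-channel coincidence fraction, Poisson + read noise) and
FRAP traces with known mobile fraction, so the whole pipeline is testable
without any microscopy data.

## Worked example

Simulate a scene (half of the red foci planted coincident with green foci)
and run the full pipeline:

```bash
punctaloc simulate stack --out sim --seed 7
punctaloc coloc sim/synthetic_stack.tif --out results --seed 7
```

`results/synthetic_stack_summary.csv` then contains:

```
channel  n_puncta  observed_mean_overlap  randomized_mean_overlap  randomized_sd_overlap  exceedance_count  pearson_r
  green         8                  0.416                    0.001                  0.002                 0      0.571
    red         8                  0.449                    0.004                  0.010                 0      0.571
```

Eight foci are found per channel (eight were planted).  The observed mean
overlap fraction (~0.42–0.45, half the foci being truly coincident) is two
orders of magnitude above the randomized background rate (~0.001–0.004); no
randomized replicate reaches the observed value (`exceedance_count` 0), so
the colocalization is far beyond chance.  Per-focus records are in
`*_overlaps.csv`, focus geometry in `*_puncta.csv`, and label masks in
`*_labels_{green,red}.tif`.

FRAP, on three simulated traces with a true mobile fraction of 60 %:

```bash
punctaloc simulate frap --out frap0 --seed 0   # likewise seeds 1, 2
punctaloc frap frap0/synthetic_frap.csv frap1/... frap2/... --out frapres
```

`frapres/frap_summary.csv`:

```
       mode  mobile_fraction_mean_pct  mobile_fraction_sd_pct  tau_mean_s  n
full_bleach                      60.0                    0.61        2.95  3
```

recovering the planted 60 % mobile fraction and τ = 3 s.

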