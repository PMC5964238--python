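# casig

Quantitative analysis of ratiometric calcium imaging for rare cell–cell
communication events — specifically, T cells forming conjugates with
antigen-presenting cells (e.g. monocyte-derived macrophages) under
superantigen stimulation.

In this assay, Fura-2-loaded T cells are perfused over macrophages and
imaged at alternating 340/380 nm excitation every 10 s for ~20 min. The
340:380 emission ratio r(t) rises monotonically with cytoplasmic free
calcium, so each tracked cell yields a *calcium signature* — r(t) over the
recording — alongside its migration track. Signaling conjugates are rare
(a few percent of cells), so the analysis must pull small subpopulations
out of hundreds of tracked cells per field.

## What the package computes

- **Ratio imaging** (`casig.ratio`): per-pixel 340:380 ratio stacks with
  background masking, the 0.5–2.0 false-color display mapping, and
  calcium-trace extraction along tracks with a circular ROI (20 px
  diameter by default). Measurements always use the unclipped ratio.
- **Thirteen per-cell measures** (`casig.features`): mobile fraction
  (steps > 2 µm/min), track duration, t_max (time of maximum ratio),
  % of track length at t_max, returns-to-baseline count (R2B),
  min/max/median ratio, duration-normalised AUC above baseline, and the
  four pre/post-t_max motility ratios (track length, speed, meandering
  index MI = Euclidean/length, Euclidean distance). The baseline is the
  median sample of the ten lowest-range tracks; tracks shorter than 5 min
  are excluded, and cells with max ratio ≤ 1 serve as t_max-matched
  controls for the responders (max ratio ≥ 1).
- **Signature classification** (`casig.classify`): deterministic rules for
  the four signature classes — *flat* (no rise), *transient* (rise with
  return to baseline), *low* (sustained sub-threshold rise), *high*
  (onset above 1.5 sustained above 1, or any excursion above 2) — plus
  responder counting, Fisher's exact test and the Mann-Whitney U test.
- **Multivariate analysis** (`casig.multivariate`): z-scoring, PCA and
  Fisher LDA of the 13-measure table with per-class resubstitution
  accuracies and 95% confidence ellipses.
- **Interface quantification** (`casig.interface`): marker accumulation at
  the cell–cell interface (interface-membrane MFI / rest-of-surface MFI
  along 10 px-wide traces) and four-ROI polarization for permeabilized
  stains (50×50 px ROIs; signed front–back and side–side polarity).
- **Flow cytometry** (`casig.flowcyto`): live → PKH26⁺DiD⁺ → pulse-width
  gating, conjugate frequency, and Fluo-2 MFI as a percentage of the
  post-ionomycin maximum.
- **Synthetic data** (`casig.sim`): a seeded generator producing tracks,
  traces, rendered dual-channel 16-bit movies, annotated conjugate images
  and flow event tables with full ground truth at the assay's scale
  (470×470 µm field, 10 s interval, 121 frames, ~107 T cells).

## Worked example

```python
from casig.sim import SimConfig, simulate_tracks
from casig.features import (filter_tracks, compute_baseline, features_table,
                            MEASURE_COLUMNS)
from casig.classify import classify_signature, signature_frequencies
from casig.multivariate import scale_features, run_lda

cfg = SimConfig(n_tcells=300, seed=7)          # superantigen-like mixture
tracks, truth = simulate_tracks(cfg)
kept, excluded = filter_tracks(tracks)          # drop tracks < 5 min
baseline = compute_baseline(kept)
feats = features_table(kept, baseline)
labels = {tid: classify_signature(g.sort_values("frame")["ratio"].to_numpy(),
                                  baseline.value)
          for tid, g in kept.groupby("track_id")}
feats["label"] = feats["track_id"].map(labels)
print(f"baseline 340:380 = {baseline.value:.3f}")
print(signature_frequencies(feats["label"]).round(1).to_string())
complete = feats.dropna(subset=MEASURE_COLUMNS)
print(run_lda(scale_features(complete[MEASURE_COLUMNS]),
              complete["label"]).summary())
```

prints

```
baseline 340:380 = 0.804
label      flat  transient   low  high
condition
all        62.6       15.0  11.9  10.5
Fisher linear discriminant analysis
  observations: 281
  discriminants: 3
  overall accuracy: 100.0%
        flat: 100.0% (n=175)
        high: 100.0% (n=30)
         low: 100.0% (n=33)
   transient: 100.0% (n=43)
```

The classified frequencies recover the configured mixture (63/15/12/10%),
the baseline recovers the generator's 0.8 template, and LDA on the
13-measure table separates the signature classes — with 'flat' and 'high'
always the cleanest, since 'transient' and 'low' signatures overlap in
amplitude and differ mainly in their temporal course.

A command-line interface mirrors the library stage by stage
(`casig simulate-tracks`, `ratio`, `extract`, `features`, `classify`,
`match`, `mva`, `interface`, `flow`, `run`); `casig run` executes the
whole pipeline from a YAML config and writes a manifest.

## Layout

```
src/casig/
  sim/            synthetic tracks, traces, movies, conjugates, flow tables
  ratio.py        340:380 stacks, display mapping, ROI trace extraction
  features.py     thirteen per-cell measures, baseline, matched controls
  classify.py     signature rules + population statistics
  multivariate.py scaling, PCA, Fisher LDA, confidence ellipses
  interface.py    accumulation ratio and four-ROI polarization
  flowcyto.py     gating, conjugate frequency, relative calcium
  io.py, cli.py   readers/writers, pipeline orchestration, CLI
```
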