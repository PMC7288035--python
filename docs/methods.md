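# Methods

`eegsm` re-implements, as a tested pipeline on synthetic data, an analysis
of 16-channel EEG recorded from pairs of factory workers (a process owner,
PO, and their leader) while they practise one of two shopfloor-management
systems: the Hoshin Kanri Tree (HKT, direction-giving continuous
improvement) or the Balanced Scorecard (BSC, management by pre-defined
goals).  Two analyses share one data model:

1. **Channel-correlation analysis.** Per-recording 16x16 zero-lag Pearson
   matrices, Fisher-z-averaged within each of the four categories
   (HKT_PO, HKT_Leader, BSC_PO, BSC_Leader), evaluated against five
   sensor-group hypotheses (H1-H5) about coupling between the frontal
   (Fp1, Fp2, F3, Fz, F4), occipital (O1, Oz, O2), temporal (T7, T8) and
   parietal (P3, P4) groups.
2. **Soft sensor.** Each preprocessed recording is cut into 0.5 s
   segments, rendered as a jet-coloured topographic map, and classified
   into the four categories by a four-block CNN with a subject-pair-
   disjoint train/validation/test split.

The original recordings are not publicly deposited, so every stage runs on
synthetic data from the package's own generator.  What that implies for the
meaning of the results is discussed at the end.

## Signal model and the synthetic generator

A recording is 60 s of 16-channel data at 128 Hz.  The generator draws
independent Gaussian channels, band-passes them to 1-40 Hz (inside the
simulated sensor's 0.2-43 Hz bandwidth) with a common zero-phase
Butterworth filter, standardises them, and mixes them through the symmetric
square root `V sqrt(w) V'` of a target correlation matrix.  Because the
same linear filter acts on every channel, the mixture's zero-lag
correlation equals the target exactly in expectation; a 250-replicate pilot
at 60 s x 128 Hz put the 95% spread of a single recovered coefficient
within 2e-4 of its target (the symmetric factor cancels the leading
sampling-error term, which is why the spread is far tighter than the
classical `(1-r^2)/sqrt(n)` bound).

Targets are built from **condition profiles**: lists of directives pinning
the correlation within or between named sensor groups to a level in
[-1, 1], with a baseline elsewhere.  The blockwise matrix is then projected
to the nearest valid correlation matrix (iterated eigenvalue clipping with
diagonal renormalisation, tolerance 1e-8, at most 100 sweeps); the largest
entry change is reported, and a change above 0.05 triggers a warning that
the directive set is not jointly feasible.

Artifacts are additive: a slow per-channel sinusoidal drift (frequency
drawn from 0.02-0.1 Hz, default amplitude 40 uV against a 20 uV-RMS brain
signal) emulating the DC drift of AC-coupled acquisition, and an optional
50 Hz mains component (default off, as the simulated sensor applies a
hardware notch).  The 10 s leader-talks / 50 s PO-talks structure is
carried as metadata only; no phase-dependent signal change is generated
by default, though profiles can be swapped per phase by simulating the
phases separately.

Seeding is counter-based: recording `(pair, condition)` under global seed
`s` uses `SeedSequence((s, pair, condition))`, so enlarging the study never
reshuffles existing pairs.

### The hypothesis-encoding profile set

`default_profiles()` encodes H1-H5 with strong = 0.65, weak = 0.20,
baseline = 0.15 — levels inside the ranges the correlation analysis is
meant to reproduce (strong couplings 0.52-0.76, weak ones up to ~0.23).
Each category's strongly coupled groups form one *coherent set* in which
every within- and between-group link is pinned to 0.65:

| category    | coherent set                            | weak links            |
|-------------|-----------------------------------------|-----------------------|
| HKT_PO      | frontal+temporal+parietal; occipital alone | frontal-occipital  |
| HKT_Leader  | frontal+occipital+temporal+parietal     | —                     |
| BSC_PO      | frontal; occipital alone                | frontal-{occ,temp,par} |
| BSC_Leader  | frontal+occipital                       | frontal-{temp,par}    |

Pinning only the hypothesis-named links is infeasible: if frontal couples
at 0.65 to both occipital and temporal channels, the occipital-temporal
correlation cannot sit at 0.15, and the PSD repair then drags the named
links down by up to 0.14 — within one averaging-noise standard deviation
of the 0.5 support threshold.  The coherent-set form is feasible exactly
as stated (projection delta 0 for all four categories), so recovery tests
measure the pipeline, not the repair.

## Preprocessing

Fixed chain, matching the original conditioning: order-4 zero-phase
Butterworth high-pass at 0.2 Hz (the sensor's lower bandwidth edge; the
source names no cutoff) to remove DC and drift; order-8 zero-phase
Butterworth low-pass at 50 Hz (order chosen so the twice-applied response
is at least 20 dB down at 1.2x the cutoff; a separate 50 Hz notch is
subsumed); then one affine map of the whole recording onto [-10, +10].
Normalisation is deliberately *global* rather than per channel — per-
channel scaling would erase the inter-channel amplitude relations the
topographic maps display — and leaves all Pearson correlations unchanged.
Filtering uses reflect padding, three filter lengths long.

## Topographic maps

Segments are non-overlapping 0.5 s windows (64 samples; trailing remainder
dropped; 120 per recording).  Each segment is reduced to one scalar per
channel — the window mean by default ("average activity"; RMS available) —
and interpolated over the unit head disk by thin-plate-spline radial basis
functions through the standard 10-20 polar-projection coordinates
(midline at x = 0, outer ring at radius 0.9).  RBF interpolation is exact
at the electrodes (asserted to 1e-6) and extrapolates smoothly to the disk
border.  The field is rendered at 360x360 (configurable) with the jet
colormap, min-max scaled *per image*: the segment minimum maps to dark
blue, the maximum to dark red.  A field whose range is at numerical-noise
level (relative 1e-9) is treated as constant and painted the colormap
midpoint.  Pixels outside the disk take a uniform white background; since
the mask is identical in every image the choice is inert for the
classifier.

## The soft sensor

Architecture: four blocks of (3x3 same-padded convolution -> ReLU -> 2x2
max pool), flatten, one dense layer, dropout 0.2, dense output of width 4
with softmax; categorical cross-entropy; Adam (lr 1e-3).  Defaults at full
resolution: filters 16/32/64/128, dense width 128, batch 32, up to 30
epochs with early stopping (patience 5 on validation loss, best-validation
weights retained).  The engine is written directly on numpy (im2col
convolutions, explicit backprop verified against finite differences);
all randomness — weight init, shuffling, dropout — flows from one seed.

Splitting is at the *pair* level: 10/2/2 of the 14 pairs for train/
validation/test, so all 480 images of a pair share its split and the
network cannot pass by recognising individuals.  A leakage guard rejects
any training or validation stream containing images of a test pair.

### Desk-scale configuration and the separable profile set

`ClassifierSpec.desk_scale()` — 90 px images, filters 8/16/32/64, dense 64,
batch 64, at most 10 epochs (patience 3) — is the configuration used by the
study-scale validation (`eegsm.experiments.classifier_study`) so the whole
experiment, including a permuted-label control run (3 epochs), completes in
roughly ten minutes on one CPU core.

Classifier validation uses `separable_profiles()`, not the hypothesis set,
for an information-theoretic reason established in a design pilot before
the classifier was built.  Because every map is min-max colour-scaled per
segment, a single image encodes only the *relative pattern* of 16 window
means — one draw from a zero-mean Gaussian whose covariance is the
condition's target, with overall scale discarded.  For classes that differ
only in the magnitude of positive correlations, the Bayes accuracy of
classifying one such normalised draw is about 0.59 at the default levels
and only ~0.67 even with strong couplings pushed to 0.95: the four-class
problem is close to unidentifiable from a single scaled map, however good
the classifier.  Profiles that couple sensor groups with *opposite
polarity* (+0.9 within, -0.9 across a bipartition of the groups; a
different bipartition per category — frontal vs occipital for HKT_PO,
frontal+occipital vs temporal+parietal for HKT_Leader, frontal vs TPJ for
BSC_PO, occipital vs TPJ for BSC_Leader) survive the scaling as distinct
two-block colour templates, with a proxy ceiling near 0.89.  The desk-scale
CNN reaches roughly 0.80 on held-out pairs under these profiles, and
chance (~0.25) after label permutation.

## Numerical choices

* Fisher-z averaging clips coefficients to +-(1 - 1e-15) before `atanh`;
  diagonals are forced to 1 after averaging.
* Hypothesis thresholds: theta_strong = 0.5, theta_weak = 0.4 (both
  configurable, both reported in output).  A hypothesis is *supported* in
  a category when every pooled entry meets its expectation, *mixed* when
  the mean does but an extremum does not, *not supported* otherwise.
* Correlation analysis uses the full 60 s by default; an
  `exclude_first_10s` span drops the leader-talks phase.
* Max pooling breaks ties by first occurrence; odd trailing rows/columns
  are dropped.
* EDF export quantises to int16 against per-channel physical bounds taken
  from the data; the worst-case round-trip error is half a quantisation
  step.  Delimited-text round trips are exact.

## What the synthetic results do and do not show

The generator reproduces the study's *shape* (pair structure, sampling,
bandwidth, drift artifacts, condition-specific correlation structure) but
none of real EEG's rhythms, nonstationarity, inter-subject variability, or
volume-conduction geometry; all directive levels are design parameters,
not estimates from the unavailable recordings.  Passing tests therefore
demonstrate that the pipeline is correct and that the classifier can learn
pair-generalising category structure when it is present in the images —
they say nothing about whether real HKT/BSC practice produces such
structure, and the original headline classification accuracy (96.5%) is
not reproducible here.  The correlation analysis likewise recovers exactly
the structure the generator encodes; its value is as a verified
instrument, ready for real data of the same shape.
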