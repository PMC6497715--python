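# Methods

## The measurement problem

Sleep pressure manifests during wakefulness as (i) a global rise of
theta-band (5–7 Hz) EEG power and (ii) brief, spatially restricted
negative theta waves — local sleep-like events — whose scalp extent
("globality") grows with pressure and correlates with slowed reaction
times.  The package quantifies both markers from multichannel wake EEG
and links them to behavioral trial streams.

## Detection model

The detector works per scalp area (frontal: Fp1 Fp2 AF3 AFz AF4 F1 Fz
F2; central: FC1 FCz FC2 C1 CPz CP2; parietal: CP1 CPz CP2 P1 Pz P2
PO3 POz PO4).  The printed central list overlaps the parietal one on
CPz/CP2 even though the areas are meant to be non-overlapping; the
default keeps the lists as printed and warns, and a flag substitutes
Cz/C2 (used by the recovery harnesses).

1. **Reference signal** — mean over the area's channels, band-passed
   5–7 Hz with a 2nd-order Butterworth applied forward–backward.
   Zero-phase filtering is essential: trough timing feeds the
   behavioral linkage and must not be phase-shifted.
2. **Threshold** — `median − 2·MAD` of the reference over usable
   samples.  One-sided and negative: the detector targets troughs.
   "Median deviation" is read as the median absolute deviation (MAD);
   a mean-absolute-deviation variant sits behind `mad_kind`.  On a
   standard normal signal the threshold converges to
   −2·Φ⁻¹(0.75) ≈ −1.349.
3. **Candidates** — strict local maxima of the reference are paired
   consecutively; a pair whose separation lies within the theta period
   range (1/7–1/5 s, ±20% tolerance) brackets a candidate trough: the
   interior minimum, kept iff strictly below threshold and entirely
   within usable samples.  Detecting troughs *between maxima* rather
   than between zero crossings makes the rule robust to residual slow
   drift.
4. **Involvement** — the reference segment between the flanking maxima
   is compared to every channel's theta-filtered trace by Pearson
   correlation maximized over integer-sample lags within ±50 ms (a
   theta-wave scalp-travel-time argument: the window is a propagation
   delay, hence a lag range).  Channels with max r > 0.95 are involved;
   an involved channel with no involved neighbor in the montage graph
   is unmarked (single pass) — isolated channels are likely artifacts.
   A fixed-window zero-lag variant is available via `corr_mode`.
5. **Amplitude and globality** — per involved channel, the slope from
   the trough to the next-maximum sample; the channel with the median
   slope (lower median for even counts) supplies the
   trough-to-following-peak amplitude.  Globality = 100 × involved /
   analyzed channels.  Density = events per usable minute.

Because the threshold is *relative*, a quiet recording yields a shallow
threshold and the detector marks essentially every sufficiently deep
theta trough — thousands of events per hour-long session is the
expected operating regime, not a failure mode.  Parameter-recovery
analyses therefore match detections to known injection times and
evaluate the matched events.

## Electrode geometry

Positions follow the idealized spherical 10–20/10–10 scheme: midline
and ear-to-ear electrodes at 10%-arc steps, the outer ring 72° from the
vertex, intermediate rows spaced proportionally along the circle
through their ring anchors and midline electrode.  Nominal arc
distances (e.g. Fz–Cz = 36°) hold exactly, which realistic head
templates do not satisfy.  Neighbor graphs connect electrodes within a
great-circle angle (default 25°, giving 2–8 neighbors per channel on
the 56-channel analysis set: a standard 58-electrode cap minus the
excluded P5/P6).

## Spectral analysis

Welch PSDs use 4-s Hamming segments with 50% overlap; each segment is
zero-padded to an 8-s equivalent so the bin spacing is 0.125 Hz — the
only self-consistent reading of a 4-s window with 0.125 Hz resolution.
Theta band power averages bins in [5, 7) Hz (closed–open).  Per-channel
power is divided by the scalp mean, so every topography averages to
exactly 1 and scale factors cancel.

PRSA anchors are samples that decrease relative to their predecessor;
anchor-centered windows (±2 s) are averaged.  Note the selection bias:
the two anchor-defining samples converge to ∓1/√π on white noise
regardless of anchor count, while every other offset shrinks as
1/√n — the oscillatory structure PRSA reinforces lives away from that
central discontinuity.  Whether the PSD is computed on PRSA curves or
raw traces is exposed as `use_prsa` (both paths normalized
identically).

## Statistics

Paired t-maps across subjects (df = n−1) are thresholded at two-sided
uncorrected p < 0.05; same-sign neighbor-connected clusters are
corrected by sign-flip permutation (all 2ⁿ flips when requested,
identity included).  The minimum significant cluster size is the 95th
percentile of the null distribution of maximal cluster sizes, floored
at 3 neighboring electrodes.  With five subjects and 2⁵ flips the
procedure's family-wise error measures ≈1–2% in the null simulations —
conservative against the nominal 5%, driven by the cluster-size floor.

Condition effects are summarized as paired contrasts (mean difference ±
sem, paired t, df = n−1).  The original analyses fit linear mixed
models; the bespoke content is the measures fed into them, so this
package exposes the paired-contrast surface and leaves LMM variants to
standard statistical software.

Reaction times are valid in [100, 500] ms (below: false starts; above:
outliers).  The median split uses the pooled across-session median of
valid RTs with strict `>`.  Events are linked to trials over
[stim − 0.25 s, stim + 0.5 s) — motor planning through maximal RT —
and RT is regressed on the window's maximum event globality by OLS
(adjusted R², F-test of zero slope, df = n − 2).

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* **Background** — per-channel mixtures of shared "source" streams
  (placed at electrode sites, mixed with distance-decaying weights,
  decay constant 40°) plus a private stream, all shaped in the
  frequency domain as 1/f^slope (slope 1.0) with a Gaussian alpha bump
  at 9 Hz.  Identical spectral shape across components means the
  re-referenced, standardized background has a flat normalized theta
  topography in expectation.
* **Events** — Hann-windowed theta wavelets (default 6 Hz, 1.5 cycles)
  whose trough lands at a stated time on a center channel.  Spatial
  profile: full amplitude to 0.8 × radius, quarter-cosine falloff to
  zero at the radius.  The plateau is deliberate: average referencing
  subtracts the scalp-mean of the event from every channel, so
  channels whose taper weight falls below that mean flip sign and are
  physically unrecoverable; a plateau keeps the involved set a sharp,
  monotone function of radius.  Ground-truth involvement counts
  channels with taper weight ≥ 0.3 — the falloff tail receives next to
  nothing and no detector could or should mark it.
* **Amplitude ground truth** — the injected trough depth is not what
  the detector measures even in principle (average-reference leakage,
  Butterworth attenuation of a 1.5-cycle transient, median-slope
  channel selection), so recovery is scored against a noise-free
  forward model: the event rendered alone, re-referenced, filtered and
  measured by the same amplitude rule.
* **Trials** — stimuli on an ITI grid with uniform jitter;
  RT = base + β · (max ground-truth globality in the peristimulus
  window) + Gaussian noise, truncated to [50, 800] ms so both exclusion
  rules see traffic; outcomes independent of events.
* **Condition pairs** — per-subject random radius offsets (SD 1.5°)
  applied to both conditions give a random-intercept structure.  The
  radius for a target mean globality is computed by inverting the
  geometric radius→involved-count map, convolved with the generator's
  radius jitter (the map is a staircase, so jitter shifts its mean).

What the generator does **not** emulate: ocular/cardiac artifacts,
line noise, non-stationary background, traveling-wave dynamics within
events, or realistic inter-subject topographic variability.  Passing
recovery tests therefore demonstrates the pipeline's correctness and
calibration on signals with the assumed structure, not robustness to
every real-world artifact (the artifact mask and bad-channel machinery
are exercised separately).

## Recovery study conditions

Harnesses run 90-s, 56-channel sessions at 256 Hz (theta dynamics are
fully resolved far below 512 Hz; the smaller size keeps each harness in
minutes on one core): quiet background (0.1 z), 30–40 events per
session of ~10-channel extent (radius ≈ 30°) and 3.5 z troughs.  The
condition-shift harness uses 5 subjects × 2 conditions × 20 seeds with
a geometrically calibrated +4-point globality shift; the regression
harness uses the behavioral study size (237 trials, β = 2 ms/%); null
calibrations use 1000 (regression) and 500 (cluster test) experiments.

## Numerical choices

* The 0.1 Hz high-pass is applied spectrally with the exact zero-phase
  Butterworth magnitude-squared response: a recursive realization has
  its poles degenerately close to z = 1 at EEG rates and corrupts the
  passband.  The 48 Hz low-pass is a zero-phase 8th-order Butterworth.
* Downsampled artifact masks are conservative: an output sample is
  usable only if its whole source span was.
* Bad-channel flagging uses median + 5·MAD of log muscle-band power
  with an absolute floor of 0.5 nats on the criterion (the MAD of a
  homogeneous cap is arbitrarily small and would otherwise flag noise).
* Channel interpolation is inverse-angular-distance weighting over the
  neighbor graph — fully specified by the montage type and adequate
  for z-scored signals; spherical splines are a documented deviation
  not taken.
* Ties in trough location break to the first sample; candidate
  segments crossing the recording edge are dropped and logged; events
  whose involved set empties after pruning are discarded and logged.
* EDF I/O is 16-bit with 1-s records; roundtrip error is bounded by
  one quantization step of each channel's range.

## Known limitations

* Independent-component artifact removal is out of scope; the pipeline
  consumes an upstream artifact mask.
* With a corr_cut of 0.95 on ~1-period narrowband segments, involvement
  has an irreducible false-marking rate on channels that carry no
  event (theta-filtered noise can phase-align within the ±50 ms lag
  window); cluster pruning and, in synthetic tests, the
  average-reference leakage keep it manageable, but absolute globality
  levels on real data should be read as method-relative.
* The generator's event amplitude distribution is a free choice, not
  an empirical claim.
* Paired contrasts replace mixed-model inference; datasets with
  heavily unbalanced designs need external LMM tooling.
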