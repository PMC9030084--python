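# Methods

This note documents the models and procedures implemented in `gaitstride`,
the assumptions behind them, the tunable parameters and their defaults, what
the synthetic generator does and does not emulate, and the numerical
choices that make the pipeline deterministic.

## Signal model and conventions

A recording is a uniformly sampled stream of 3-axis acceleration and 3-axis
angular rate from a foot-mounted IMU. Physical axis labels are unreliable
across devices and mounting conventions (the same physical channel may be
called Y or Z on different rigs), so all algorithms address channels through
anatomical roles — *coronal* (left-right), *sagittal* (anterior-posterior),
*vertical* (gravity-aligned) — resolved through an explicit `channel_map`.
Accelerations are used raw, gravity included: stance is characterized by
values pinned near the static gravity reading, and removing gravity would
erase exactly the contrast the stance detector uses. Units are carried as
metadata and never assumed.

Sample positions use 0-based, half-open `[start, end)` intervals everywhere.
This makes phase tiling exact (the four phases of a cycle partition it with
no gap or overlap) and keeps the temporal-IoU arithmetic integral.

A stride cycle is ordered *push-off → swing → heel-strike → stance*: the
stance closes the cycle, and the end of one cycle's stance is the start of
the next cycle's push-off.

## Stride segmentation (subsequence DTW with start propagation)

- **Template**: example strides are linearly resampled to a common length
  `L` (default: the median example length, minimum 8) and averaged
  column-wise. The default matched channel is the coronal gyroscope, whose
  stride-periodic swing lobe is the most speed-stable shape in the stream.
- **Per-sample descriptors**: each sample is represented by statistics of
  its ±w neighborhood (default w = 3, replication padding): mean gradient,
  amplitude range, and window mean; a single-level db1 wavelet
  approximation is available as an alternative (`feature="wavelet"`).
  Matching descriptors instead of raw samples smooths the accumulated
  distance landscape and suppresses sensor noise. With `normalize=True`
  both signal and template are z-scored first, making the match exactly
  invariant to positive amplitude rescaling.
- **Recurrence**: unweighted steps {(1,1), (1,0), (0,1)} over the Euclidean
  descriptor distance; every stream sample may open an alignment at
  template row 0, and each cell propagates the stream index where its path
  entered row 0. Costs are non-negative, so accumulated distance is
  monotone along every path.
- **Emission** is threshold-free. Candidate ends are (a) local minima of
  the final-row accumulated distance within a competitor window of L/2
  samples (exact ties resolve to the last index, so a perfect match spans
  its whole region), and (b) the best end among competitors sharing a
  start point — needed for bout-ending truncated strides, whose minimum is
  shallower than the neighboring full stride's and would otherwise be
  shadowed. Candidates are accepted greedily by ascending distance, subject
  to non-overlap and a minimum length of L/3 (a genuine half-stride is
  roughly L/2; single-peak noise is shorter).
- **Gap closing**: in continuous walking the end of one cycle is the start
  of the next, but noise can stop a match a few samples early inside the
  quiescent stance tail. Gaps between consecutive matches up to L/2 are
  closed by extending the earlier match; longer gaps (genuine pauses)
  remain open. The raw warping-path bounds are kept on the match object.

An exhaustive open-begin-open-end DTW (independent per-start dynamic
program) is used in the tests as an oracle: on short streams the best
emitted accumulated distance equals the brute-force minimum to 1e-9.

## Gait-phase division (peak-valley pairs)

**Preprocessing.** Both acceleration channels are mean-filtered (centered
window, default 5 samples, odd) and then deflated by `y = sign(m)·m²`,
which stretches dynamic-phase amplitudes while pushing near-zero stance
samples closer to zero.

**Stance detection.** A short window (default 25 ms) slides over the
preprocessed sagittal and vertical signals; a window is *static* when, on
both channels, its variance, IQR and mean absolute level fall below
fractions of the same statistics computed over the whole stride (defaults
2%, 10%, 10%). Relative thresholds are used because absolute ones do not
transfer across walking speeds. The spread statistics alone cannot reject
a locally-flat but high-amplitude segment (the crest of a slow
oscillation), which is why the level gate exists. Qualifying windows are
grouped into runs, runs separated by gaps much shorter than any dynamic
phase (≤ 3 windows) are bridged, runs shorter than 80 ms are discarded,
and the latest surviving run is the stance (stance closes the cycle). If
nothing qualifies the caller may retry with widened thresholds
(`segment_gait` doubles them up to 3 times before reporting the stride as
failed).

**Extrema clustering.** Strict local extrema (minimum prominence 5% of the
signal range; plateaus report their first index) of both channels between
the stride start and the detected stance are pooled (peaks and valleys
together; a peaks-only switch exists) and split by a deterministic 1-D
2-means: centers initialized at the bounding stance edges, squared-distance
assignment with ties going left, mean updates, stop at 50 iterations or
center movement < 0.5 samples. The left cluster is toe-off evidence, the
right cluster heel-impact evidence. On well-separated instances this
reproduces the exhaustive minimal within-cluster-sum-of-squares contiguous
bipartition (tested against that oracle).

**Major peak-valley pair.** Within a cluster's range, each peak is paired
with the nearest valley after it (the paired valley may fall anywhere in
the dynamic region — the cluster localizes the force event, pairing acts on
the signal). Among pairs whose signal crosses zero between the extremes,
the largest span wins; a runner-up with span > ½ of the major span whose
peak lies within 5 samples of the major valley merges with it (two
back-to-back force reversals acting as one event). If no pair crosses
zero, the largest-span pair is used as a fallback and the stride is
flagged in diagnostics.

**Boundary fusion.** Two-reference mode averages, for push-off/swing, the
sagittal major-pair peak and the vertical major-pair valley; for
swing/heel-strike, the two major-pair peaks. Four-reference mode adds the
derivative zero-crossings nearest the corresponding extrema (negative
crossings mark peaks, positive mark valleys; the derivative is the first
difference, length-preserved by trailing replication) and applies
leave-one-out outlier rejection before averaging: each reference is scored
against the mean ± 3 unbiased SD of the others; rejection is skipped below
4 references (the SD of 2 points is degenerate) and never empties the set.
The fused index is the round-half-away-from-zero integer mean, and the
ordering `stride start < b₁ < b₂ < stance start` is enforced — violations
surface as per-stride diagnostics, never as silently dropped strides.

## Stride-length estimation

Twelve default features: for each of sagittal, vertical and 3-axis
magnitude — `(a_max − a_min)^¼` (Weinberg term), `(mean |a|)^⅓` (Kim
term), variance, and range. Cadence and the normalized-mean excursion
(Scarlett term) are available but off by default, keeping the default
registry auditable at 12. Flat channels define the Weinberg/Scarlett terms
as 0 rather than erroring.

Per dynamic phase (and optionally for the whole stride, as a comparison
baseline): random-forest importance selection (impurity-based, 200 trees,
seeded; keep importance > 0.05, never fewer than one feature), column
standardization to zero mean and unit *unbiased* SD (zero-variance columns
dropped and recorded), then an RBF-kernel SVR (C = 10, γ = "scale",
ε = 0.01) or an AdaBoost ensemble of 30 such SVRs (linear loss, seeded).
The fused estimate is the arithmetic mean of the three per-phase
predictions; when a phase is missing (segmentation failure) the mean of
the available ones is returned with a partial-fusion flag. Hyperparameters
were fixed a priori at common defaults and are all exposed in
configuration. The model predicts in the unit of its training references.

## Evaluation metrics

Temporal IoU divides the overlap length by the *spanning* interval
`max(end) − min(start)`; for overlapping intervals this equals the true
set union, and for disjoint intervals the intersection is zero, so the
ratio is unaffected (a strict set-union variant exists behind a flag).
Segment matching is greedy one-to-one by descending IoU with a
configurable acceptance threshold `min_iou` (default: any positive
overlap). Precision, recall and F-score follow the usual definitions with
the convention that all three are 0 when there are no true positives.
Length accuracy is the per-stride RMSE and the relative error of the
accumulated distance against a measured path length.

## Synthetic walks: what they emulate, and what they do not

Each stride is built from monotone-cubic (PCHIP) kernels through versioned
knot tables on the sagittal and vertical channels. PCHIP cannot overshoot,
so every planted extremum falls exactly on its knot: the sagittal peak and
vertical valley sit on the push-off/swing boundary, both impact peaks on
the swing/heel-strike boundary, a late sub-peak ("foot slap") in the
second half of heel-strike, and exact zeros in stance. The coronal
gyroscope carries a stride-periodic bump train for template matching.
Phase durations default to 20/35/15/30% of the cycle (typical walking
proportions). Amplitude scales linearly with cadence (8 m/s² at the
reference 0.9 strides/s), emulating the speed-magnitude relation of real
foot sensors; slow/middle/fast defaults are 0.7/0.9/1.1 strides/s at
100 Hz. Noise is white Gaussian with SD expressed as a fraction of the
amplitude. The true stride length follows a declared map — by default
`0.3 + 0.5 · (vertical range)^¼` metres on the noise-free kernel, plus
optional Gaussian noise — recorded in the walk's manifest so
parameter-recovery experiments are self-describing. The optional terminal
half-stride plays push-off and swing at 0.8 amplitude, omits the heel
impact, and rests, with half the nominal length as truth.

Limitations to keep in mind when reading test results: kernels are smooth
and stereotyped, noise is white (real foot-IMU noise is colored and
impact-correlated), there is no inter-stride shape variability beyond the
cadence-amplitude law, no sensor bias or saturation, no non-walking
activity, and phase proportions do not vary with speed. Passing tests
demonstrate correctness of the algorithms under the stated morphology and
noise model, not performance on any particular hardware or population.
In the same spirit, the generator's boundaries are ideal: real annotated
boundaries carry labeling jitter that this ground truth does not model.

## Problem sizes and numerical choices

The test suite and the acceptance script use 50-stride walks at three
cadences for phase recovery, a 100-stride speed-ramp stream for stride
detection, 500 strides for length-model training (350/150 seeded shuffled
split — the ramp profile orders strides by cadence, so a contiguous split
would measure extrapolation instead of recovery), and 400-sample streams
for the brute-force DTW oracle. All randomness flows from explicit seeds:
the generator through `numpy.random.default_rng`, the forest and AdaBoost
through scikit-learn's `random_state`; the 2-means, DTW and fusion
contain no randomness. Ties are fixed deterministically (k-means ties go
left, DTW tie ends resolve to the last index, plateau extrema report their
first index, fused boundaries round half away from zero).
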