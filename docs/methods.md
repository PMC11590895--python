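# Methods

## Signal model and units

Recordings are six-axis collar IMU time series sampled at `fs = 25 Hz`
(configurable via `SensorConfig`): acceleration `ax, ay, az` in g within a
±4 g full scale, angular velocity `gx, gy, gz` in deg/s within ±500 deg/s.
No unit conversion happens inside the pipeline; features stay comparable
to sensor specifications. Timestamps must advance by `1/fs` within a 10 %
tolerance; no filtering or denoising is applied to the raw signals before
feature extraction. The orientation-robust magnitudes
`Am = ‖(ax,ay,az)‖₂` and `Gm = ‖(gx,gy,gz)‖₂` are derived channels.

Annotations form a three-tier ethogram: `action`
(natural_suckling / feeding / rumination), `state` (lying / standing,
mutually exclusive and covering all time), `event` (coughing, duration
< 2 s). Tiers are independent because actions and postures co-occur.

## Windowing and labeling

Models 1–2 use 10 s windows (250 samples) with 50 % overlap for training.
The action label requires strictly more than 50 % occupancy — exactly half
falls to `others`; the state label is the strict coverage majority, with
an exact 50/50 tie resolved to the earlier-starting state (logged). At
inference, windows are non-overlapping so the 10 s-per-window daily
time-budget conversion cannot double-count; training keeps the overlap for
sample efficiency.

Model 3 anchors 31-sample windows (15 each side) on local maxima of `Am`
that exceed a threshold, with a minimum peak spacing enforced by keeping
the larger peak (earlier index on ties). The threshold (1.3 g) and spacing
(1.0 s) are deployment parameters exposed in `PeakConfig`; the defaults
are set so the synthetic cough transients are always detected while
quiescent postures yield no candidates. Peaks closer than 15 samples to a
recording edge are dropped rather than padded, preserving the fixed
feature geometry. A window is `coughing` iff any annotated cough interval
intersects its time span.

## Features

Twelve statistics per channel over eight channels give a 96-column grid:
mean, variance, SD (population, ddof 0), min, max, IQR, zero crossings,
dominant frequency and its power, and the mean absolute / max absolute /
SD of the forward-difference gradient `(x[n+1] − x[n])·fs`. Numerical
conventions, chosen once and frozen:

* **Quartiles** use linear interpolation between order statistics (the
  common "type 7" rule).
* **Dominant frequency** is computed on the mean-removed series over DFT
  bins `1..⌊N/2⌋` — DC is not periodicity; a constant series returns
  (0, 0) by convention. Off-bin tones are recovered within one bin width
  `fs/N`.
* **Zero crossings** are counted on the mean-centered signal; exact zeros
  inherit the previous nonzero sign, so touching the axis is not a
  crossing.
* **Gradients** are forward differences yielding N−1 values.

Selection runs in two passes fitted on training rows only: a greedy
correlation filter in fixed column order (drop when |r| ≥ 0.9 with an
already-kept feature; constants dropped outright; correlation with a
zero-variance feature defined as 0), then a single seeded decision tree
whose zero-importance features are dropped (or `top_k` kept). On the
synthetic cohort this shrinks 96 columns to order 1–10 surviving features
because the signatures are low-dimensional; real data would retain more.

## Models, splitting, imbalance

All three classifiers are LightGBM leaf-wise gradient-boosted trees run
single-threaded and deterministic, with early stopping (patience 50
rounds) on a validation set. Splitting is individual-wise: whole calves go
to train or test (42/6 at the default cohort size), and validation rows
are an 8:2 row-level split *within* the training calves — row-level
because windows from one calf already share the training side, so the
holdout that matters for leakage is the calf-level test set.

The cough model's minority class is oversampled to 1:1 with SMOTE
(interpolation between a minority row and one of its k = 5 nearest
minority neighbors, uniform interpolation factor), implemented in
`classify.oversample_minority`. Oversampling touches training rows only —
never validation folds or test calves — and `cross_validate` applies it
inside each training fold of its stratified k folds. The hyperparameter
hook `tune_hyperparameters` is a seeded random search over learning rate
(log-uniform), number of estimators, and max depth, maximizing validation
macro F1 and returning the full trial log.

## Evaluation conventions

Per-class metrics come from one-vs-rest confusion counts; the "overall"
row is the unweighted macro average, with zero-denominator (undefined)
cells excluded from the macro rather than coerced to 0 (logged). In any
binary table this yields the symmetry TPR(A) = TNR(B) and one shared
accuracy. ROC uses a full threshold sweep with trapezoid AUC, which equals
the Mann–Whitney pairwise-concordance statistic (ties ½). Time budgets
assign 10 s to each predicted non-overlapping window per calf-day and
behavior; coughs are compared as daily counts, not seconds. Cohen's kappa
is computed on aligned categorical sequences; two observers' interval
tracks are aligned by binning onto a 1 s lattice and comparing only bins
covered by both — the bin width is a preprocessing choice, exposed as a
parameter. Kappa is reported on its natural [−1, 1] scale.

## The synthetic cohort

Each behavior has a parametric signature (`synthetic.default_library`):

| behavior | signal structure | defaults |
|---|---|---|
| lying | gravity mostly on ax, low noise | orientation (0.96, 0, 0.28); σ_accel 0.010 g |
| standing | gravity on az, moderate noise | σ_accel 0.030 g, σ_gyro 2.5 deg/s |
| natural suckling | nodding oscillation on gyro-y + gravity-aligned bob | 1.5 Hz, 55 deg/s, bob 0.30 g |
| rumination | slow chewing on gyro-x | 1.1 Hz, 28 deg/s, bob 0.06 g |
| feeding | fast chewing on gyro-x | 2.4 Hz, 35 deg/s, bob 0.30 g |
| coughing | biphasic 0.5 s transient along gravity + gyro jerk | peak 2.0 g |

The "bob" term modulates `Am`, which is what makes suckling/feeding
produce above-threshold non-cough peaks (the cough model's negative
class) and coughs rise far above the quiet-posture 99.9th percentile.
Schedules alternate lying/standing bouts tiling the day and action bouts
separated by untagged gaps (the `others` class), with lognormal durations
(medians: lying 540 s, standing 360 s, suckling 240 s, feeding 180 s,
rumination 300 s, gaps 90 s, log-σ 0.45). Coughs arrive as a Poisson
process at 10/h by default — deliberately above clinical rates so that a
desk-scale cohort carries enough positive events for stable cough-model
statistics. Noise is Gaussian and white per channel.

What the simulator does **not** model: collar slippage and rotation, dam
contact artifacts, drift or temperature effects, behavior transitions that
blur window boundaries beyond the majority rule, and the true (unknown)
spectral content of calf suckling and chewing at 25 Hz — the oscillation
frequencies are separability devices, not biological claims. Consequently,
near-perfect synthetic scores demonstrate that segmentation, labeling,
features, selection, leakage-safe splitting, oversampling and evaluation
compose correctly, and that the feature families can separate behaviors
*with the assumed structure*; they say nothing quantitative about accuracy
on real farm recordings.

## Problem sizes

The default full run (`scripts/acceptance.py`, `pipeline.RunConfig`)
simulates 48 calves at 3600 s each — about 4.3 M samples, ~34 k training
windows and ~2 k held-out windows — chosen as the smallest cohort that
keeps every class well-populated on the held-out calves (including a few
dozen cough events across six test animals). The shared test fixture uses
900 s per calf for the same reason at lower cost. Feature extraction is
vectorized across windows (single `rfft`/percentile/accumulate passes per
channel), so a full run takes on the order of a minute on one core.

## Known limitations

* Recording gaps larger than one sample are rejected rather than split;
  dropout handling is out of scope.
* The event-window negative class depends on the peak threshold; with a
  different sensor or mounting the 1.3 g default would need recalibration.
* `select_by_importance` uses a single tree; importances are seeded but
  can be unstable on near-duplicate features (the correlation filter runs
  first to mitigate this).
* Multi-day time budgets assume recordings start at a day boundary.
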