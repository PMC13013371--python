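# Methods

## Problem setting

Frame-level surgical *step* recognition is supervised by expert-annotated
step segments, which are scarce: typically only a fraction α of a
deployment's videos carry them. Cheaper supervision exists at other
ontological levels — *phases* (coarse stages; every step belongs to exactly
one phase) and *elapsed time* (free, from timestamps) — and in other
procedures' step labels. The package benchmarks a two-stage recipe:
pre-train a frame classifier on one weak dataset-label pair, then fine-tune
all weights on the α-limited step labels, and prices the resulting F1 gain
in annotation effort.

## Weak label derivation

Step annotations are half-open intervals `[start, end)` in seconds; frame
`t` at sampling rate `fps` covers `[t/fps, (t+1)/fps)` and takes the label
of the segment containing `t/fps`. Shared boundaries are not overlaps;
genuine overlaps are rejected naming the offending pair.

Phase tracks apply two gap-closure rules between successive steps: a gap
between steps of the same phase takes that phase; a gap between different
phases takes the earlier step's phase (back-fill). Both rules are one
statement: each segment's phase extends forward to the next segment's
start. Frames before the first segment and after the last stay unlabeled —
the rules speak only of gaps *between* annotations, and we do not
extrapolate outside the annotated span. Unlabeled frames are excluded from
every training batch and every score.

Elapsed-time tracks assign frame `t` the bin `floor(n_bins * t/fps /
duration)`, clamped to the last bin at the exact endpoint; 10 bins by
default. Bin occupancies differ by at most one frame, every frame is
labeled, and bins are monotone within a video.

## Synthetic corpus

The corpus stands in for private surgical video. Four procedures (`slg`,
`hys`, `cho`, `rpy`) with 24/32/48/64 videos mirror a realistic size
ordering; `rpy` is a pre-training-only donor. Each procedure has 6–10
steps grouped into 3–4 phases; videos realize the phase sequence with
log-normal step durations (~24 s median), 10% step skips, and exponential
inter-step gaps, giving 120–300 frames at 1 fps.

Frames are 32×32×3 renders of a latent state. Latent components — a
step code, a phase code, a monotone time drift, a site style and a
per-video style, plus sensor noise — are summed and passed through a fixed
random per-pixel sinusoid, `pixel = 0.5 + 0.35·sin(θ_p + Σ components)`,
with post-render pixel noise on top. The nonlinearity is deliberate:
content and style entangle the way they do in real imagery, so a linear
readout cannot subtract the style patterns and a *representation* has to be
learned from diverse videos — which is exactly the asset weak pre-training
can transfer. Step, phase and drift codes are localized to small random
patches (8/14/16 px), so a classifier cannot defeat the noise by averaging
over thousands of informative pixels.

Two structural choices make the step→phase hierarchy real rather than
nominal. The phase code is the mean of its member steps' codes plus a
*weak* independent component (weight 0.3): phase recognition is thereby
forced through step appearance instead of a phase-only shortcut, which is
what makes phase pre-training transfer. And cross-procedure visual sharing
blends one procedure's step codes toward an index-aligned donor's (`rpy` ↔
`hys` at 0.5, none with `slg`), giving cross-procedure step pre-training a
designed transfer direction.

Signal amplitudes (step/phase/drift 1.2, site 1.0, video style 1.2, sensor
noise 0.8 rad, pixel noise 0.35) were chosen once, during design, so the
corpus occupies the regime the benchmark studies: the step task is
learnable but data-limited at small α, and the baseline's learning curve
rises steeply from ~0.45 weighted F1 at α = 0.25 toward ~0.7 at α = 1.0 on
the largest target. They are free parameters of the generator, documented
here, and not calibrated to any external dataset.

What the corpus does *not* emulate: temporal dependence between frames
beyond the monotone drift (no motion, no autocorrelated noise), instrument
or anatomy appearance, annotator disagreement, and non-stationary site
effects. Passing tests therefore demonstrate that the *framework* — label
derivation, splits, two-stage training, paired statistics, NNL — behaves
correctly and that the qualitative transfer phenomenology can be
reproduced, not that any particular clinical F1 level is attainable.

## Scarcity simulation

Per procedure, 20% of videos (floor for the pool: `N_train = floor(0.8 N)`)
are held out once as a test set shared by all five splits — pairing by
split is only valid because the test set and the labeled subsets are held
constant between the baseline and every pre-trained arm. Each split draws a
permutation of the pool; the labeled subset at α is its first
`round(α · N_train)` videos (banker's rounding), making subsets nested
across α like an incrementally annotated archive. Within a labeled subset,
70/30 train/validation is assigned at video level. No video ever straddles
roles.

## Training protocol

The classifier is a small fully connected network (default one 64-unit
hidden layer) over flattened, 0.5-centered pixels, trained with Adam
(lr 10⁻³, batch 64, decoupled weight decay 10⁻⁴ on matrices). Class
imbalance is met with weighted sampling — draw probability inverse to
class frequency, one epoch = N labeled draws with replacement, since
without-replacement epochs are incompatible with a non-uniform sampler.
Early stopping watches the *unweighted* validation cross-entropy
(deployment distribution, not the balanced sampler), patience 5 within a
30-epoch budget, and returns the best-validation checkpoint, never the
last. Input centering matters: with all-positive inputs an easy pre-train
stage silently kills most ReLU units and destroys transfer.

Two-stage transfer re-initializes the classification head whenever the
label vocabulary changes while carrying the trunk over bit-identically;
all weights then train (nothing is frozen). Every random draw — corpus,
splits, initialization, sampling, rendering noise — comes from a named
substream of one master seed, so entire experiments are bit-reproducible.

Weak pre-training uses the full *non-held-out* dataset of its source
procedures: the weak-label pool is never subsampled by α, but evaluation
procedures' test videos are excluded from pre-training. At desk scale,
letting pre-training see test-video frames (even with weak labels only)
familiarizes the trunk with those videos' style and adds a constant,
α-independent gain that masks the diminishing-returns pattern the
benchmark is designed to expose; a donor procedure that is never evaluated
contributes all its videos.

## Evaluation and label efficiency

Performance is support-weighted mean per-class F1 on the test set,
unlabeled frames excluded; zero-support classes get weight zero and a
class never predicted scores zero. Scenario-vs-baseline comparisons are
paired by split: mean ΔF1 (percentage points), 95% CI from t(4) over the
five splits, two-sided paired t-test, Bonferroni stars with N = the number
of comparisons in the reported table (configurable; 15 for a five-scenario
× three-target table). Zero-variance deltas report the limit p-value (0 if
the mean is nonzero, else 1) with a degenerate-variance flag.

NNL: fit `F1_base(α) = a + b·α` by OLS over the four α points, then
`Δα = ΔF1/b` and `NNL = Δα · N_train`. The primary mode fits per split and
computes Δα and NNL per split, reporting their mean and t(4) CI — CIs come
from the per-split NNL values directly, not from dividing interval bounds.
A pooled mode (single fit to per-α means) is provided for comparison.
Slopes below 0.5 F1 points per unit α are flagged non-estimable rather
than returning an unbounded video count. NNL is displayed rounded to whole
videos but stored exactly; person-hours = NNL × minutes-per-case / 60.
The best weak label per procedure is the highest mean ΔF1, ties broken by
narrower CI, then lexicographically.

## Scale of the shipped experiments

The acceptance script and the end-to-end test run the directional
experiment on the largest evaluated procedure (`cho`, 48 videos): baseline
across the α grid plus same-procedure phase pre-training at α ∈ {0.25, 1.0},
five paired splits, ~2 minutes on one CPU core. The full grid (3 targets ×
6 scenarios × 4 α × 5 splits) is exposed via `run_benchmark` with
checkpoint/resume, and a `--fast` CLI profile shrinks it for smoke runs.

## Known limitations

- The MLP trunk transfers less structure than a convolutional backbone;
  absolute gains are smaller than published GPU-scale numbers, and only
  their direction and ordering are meaningful here.
- The α grid has four points; the OLS line is a crude learning-curve model
  and NNL inherits its bias wherever the true curve is concave.
- Whether labeled subsets should be nested across α, and the video- vs
  frame-level granularity of the 70/30 split, are underdetermined by the
  protocol the benchmark follows; both choices here are documented above.
- With five splits the paired t-test has 4 degrees of freedom; per-cell
  significance is fragile by construction, which is why the headline
  checks compare means and orderings rather than stars.
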