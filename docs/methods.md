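# Methods

This note records the models and procedures buzzscan implements, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic benchmark does and does not demonstrate.

## Frame model and audio handling

All classification happens on discrete, non-overlapping 0.96-s frames at a
16 kHz model sample rate — the frame geometry of the AudioSet family of
audio embedding backbones, which the provider contract targets.  Input
recordings are decoded once at native rate, mixed to mono by channel mean
(field recorders are mono; stereo inputs are a convenience), resampled
with a polyphase filter, and tiled into frames.

*Trailing audio shorter than one frame is dropped, not zero-padded.*
Frames are meant to be units of real recorded sound; padding would
manufacture unlabeled audio and bias the final frame's statistics.  The
trade-off is that up to 0.96 s per file is never scored.

Only uncompressed WAV is decoded.  Field studies often record compressed
audio (e.g. 48 kbps MP3); such files must be transcoded to WAV before
analysis.  Compressed inputs are recognised by magic bytes and rejected
with an error naming the codec, rather than misread.

## Annotations and the matching rule

Annotations are Audacity label tracks: tab-separated (start, end, label)
intervals, read and written unchanged so annotators can keep using
Audacity.  Volume tags (`quiet`, `loud`), a whole-period `background` tag
and a buzz pitch class (`low`/`medium`/`high`, relative to the ~230 Hz
honey-bee flight tone) ride on the label text as dot suffixes
(`ins_buzz.quiet`) — the plain format has no side channel for metadata.

A frame is truth-positive for a label when its summed overlap with merged
events of that label reaches 10% of the frame (0.096 s at defaults), or
when an entire event lies inside the frame.  The containment branch keeps
very short buzzes (an insect passing the microphone) from being
structurally undetectable.  Overlap is summed across same-label events
*after* merging abutting fragments, so a buzz annotated in quiet/loud
sections is judged as one interval; this is an interpretation — the rule's
behaviour for multiple sub-threshold fragments in one frame is otherwise
undefined.  Intervals are closed-open `[start, end)` with a 1e-9 s
tolerance for boundary equality.

Whole-period `background` hum events (constant, nondistinct insect
activity) are excluded from truth by default — they are ambiguous as
positives and would otherwise dominate negatives; policies `positive` and
`negative` are available for sensitivity analyses of that choice.

## Embeddings

The built-in provider is a deterministic log-mel summary extractor:
25 ms Hann windows with a 10 ms hop (96 windows per frame), 512-point FFT,
64 triangular HTK-mel bands spanning 60–7800 Hz, log energies floored at
1e-6, summarised per band by mean and standard deviation over time, plus
spectral-centroid mean, spectral-flux mean, RMS and zero-crossing rate —
132 dimensions, double precision throughout.  Quasi-harmonic buzzes
concentrate energy in a few low-mel bands while the interferers are
broadband or pulsed, so these statistics are linearly separable for the
events of interest (a guard test asserts ≥95% linear training accuracy on
buzz-vs-noise frames).  Large pretrained backbones attach through the same
provider contract (deterministic, fixed dimension, declared rate and frame
length) and are never required.

## Classification head

The head is a single affine map to per-label logits trained with
independent per-label sigmoid/binary cross-entropy.  Field frames
genuinely contain co-occurring events (a buzz over cricket trills), which
a softmax would forbid; independent logits also give each label its own
meaningful threshold scale.  Training is full-batch gradient descent with
a fixed step 1/L, where L is the trace bound on the logistic-loss
curvature of the internally standardised features (plus the L2 term) —
chosen for guaranteed monotone loss decrease and bit-reproducibility under
a fixed seed, not for speed.  Defaults: max 2000 epochs, early stop at
relative loss change < 1e-7, L2 penalty 1e-4 (stabilises separable
problems), N(0, 0.01) seeded initialisation.  Standardisation is folded
back into the stored weights, so inference is always `Wᵀe + b` on raw
embeddings.  Vocabulary labels without training data receive zero weights
and a −30 bias so they can never fire.

The default vocabulary is the 13-label annotation scheme
(ambient_background … bird_goose); a collapse map supports coarser neuron
groupings (e.g. 8 outputs) without changing the annotation files.

## Detection and calibration

A detection is `activation > θ`, strictly: boundary equality is not a
detection, so sweeping θ over the unique activation values enumerates
every distinct confusion table.  Metric curves report sensitivity, false
positive rate and precision at each operating point; precision is
*undefined* (NaN), not 1.0, where nothing is detected — treating empty
operating points as perfectly precise would let calibration return
vacuous thresholds.  Calibration returns the smallest θ whose precision on
the calibration set reaches the target, i.e. the sensitivity-maximising
qualifying threshold; if no θ qualifies, it fails loudly with the maximum
achievable precision.

Per-buzz sensitivity asks whether each merged buzz event has at least one
detected frame among the frames matched to it by the same overlap/
containment rule.  Duration classes are <0.5, 0.5–1.5, 1.5–3, 3–6 and
>6 s — the 3–6 s bin is included so the classes partition the line.
Stratified sensitivity assigns each buzz-positive frame to exactly one
stratum: `none`, a single overlapping non-buzz label, `multiple`, or
`multi_buzz`; non-buzz strata take precedence, `multi_buzz` applying only
when a second buzz is the *only* overlap.

Validation-campaign intervals are exact Clopper–Pearson: equal-tailed beta
quantiles, conservative by construction (empirical coverage at p = 0.28,
n = 300 sits at or above the 95% nominal level).

## Activity analysis

Frames are assigned to clock-aligned bins (default 10 min) by their start
timestamp, wrapping at midnight; binning conserves frame and detection
totals.  A recorder-day summary holds:

- `mean_rate`: frame-weighted mean detection rate (weighting by frames
  keeps partial edge bins from distorting the daily mean — the unweighted
  bin average is the other defensible reading of "average detection rate
  across the day");
- `scaled_rate`: `mean_rate / plant_sensitivity`, clamped into
  (1e-6, 1−1e-6) since division by sensitivity can exceed 1 and the beta
  likelihood needs an open interval;
- `peak_time`: midpoint of the highest-rate bin as a fraction of the day
  (0 = midnight, 0.5 = noon), ties broken to the earliest bin.

The beta regression is plain maximum likelihood: logit(μ) = Xβ with
treatment coding and a common precision φ, optimised by BFGS from
moment-based starts, standard errors from the inverse observed information
(no small-sample bias correction).  Peak time is modelled by OLS; a
normal-quantile correlation of the residuals is reported as the Q–Q
diagnostic.  Pairwise group contrasts use the studentized-range
(Tukey–Kramer) adjustment — on the link scale with a normal approximation
for the beta model, on the response scale with residual degrees of freedom
for the linear model; at k = 2 the adjusted p-value reduces exactly to the
unadjusted two-sided test.

Day fractions use the recording's local clock; no time-zone or solar
correction is applied.

## Synthetic soundscapes

The generator emulates the *structure* of the detection problem, not the
acoustics of any species: buzzes are quasi-harmonic stacks (fundamental +
4 harmonics at 1/k amplitude, ±3% slow frequency jitter) at 130/230/450 Hz
for the low/medium/high pitch classes — 230 Hz is the honey-bee flight
reference, the other two are fixture choices; the high class is
additionally amplitude- and frequency-modulated at 8–15 Hz ("erratic and
quavering").  Interferers are acoustic caricatures: a 4.5 kHz 30 Hz-gated
pulse train (cricket), a low-passed brown-noise swell (vehicle), a
broadband drone with a 100 Hz hum (plane), a 700–1500 Hz slow FM sweep
(siren), over white or pink background noise (RMS 0.03).

Scene defaults: 5-min scenes at 16 kHz, Poisson arrivals at 2 events/min
with uniform placement (overlaps allowed deliberately, to exercise the
overlap-stratified evaluation), a kind mixture weighted toward medium
buzzes, and buzz SNRs drawn from 0 dB (tagged `quiet`), 10 dB (untagged)
and 20 dB (tagged `loud`) with probabilities 0.25/0.55/0.20 — quiet means
at the background level, loud means clearly dominant, mirroring how the
volume tags are assigned by ear.  Every scene is exactly reproducible from
its seed; dataset splits use disjoint seed streams.

**What passing on this benchmark shows — and does not.**  The end-to-end
experiment (50 train / 15 calibration / 20 test scenes) demonstrates that
the pipeline is wired correctly: a threshold calibrated to 95% precision
transfers to held-out scenes from the same distribution, quiet buzzes are
detected less often than loud ones, and longer buzzes are more likely to
be detected at least once.  It does *not* predict field performance: real
recordings have lossy-codec artefacts, wind, rain, non-stationary
backgrounds and insect sounds far harder than these caricatures, and real
sensitivities are far lower than the synthetic ones.  The directions, not
the magnitudes, are the claim.

## Problem sizes and numerical choices

The shipped experiment sizes (scene counts above, 200-replicate
beta-regression recovery at n = 20/group and φ = 50, 10,000-replicate
coverage simulation, 1,000-instance matching-rule fuzz) were chosen as the
smallest sizes at which the checked properties are statistically stable.
Floating-point feature math is double precision; mel filters use the HTK
scale; comparisons on seconds use a 1e-9 tolerance; reported percentages
round half away from zero.  Degenerate inputs fail loudly rather than
silently: empty training data, single-class labels, unreadable files,
unachievable precision targets and out-of-range beta responses all raise
typed errors.

## Known limitations

- No compressed-audio decoding; WAV only.
- The built-in extractor is not a learned representation; with it the
  detector is a strong tonal-vs-broadband discriminator, not a
  species-grade classifier.
- The beta regression is unpenalised ML; with very small groups the
  precision φ is noticeably biased (the recovery test averages over
  replicates).
- Stratified sensitivity assumes the overlap labels are themselves
  annotated; unannotated interferers dilute the `none` stratum.
- Throughput depends on hardware and is not a tested property.
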