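# Methods

This note records the modeling choices behind `gazetwin`: the network and
losses, the synthetic study conditions, the evaluation definitions, and the
numerical details a user would need to interpret or extend results.

## Scanpath model

**Data model.** A fixation is `(x, y, t)` with `x, y` normalized to [0, 1]
(origin top-left, `x` = column fraction) and `t` in seconds. All model math
happens in normalized space; pixels appear only at I/O and rendering. The
regression targets are therefore bounded, and trained models transfer
across image resolutions.

**Architecture.** Images are cut into `patch_size²` patches, linearly
embedded, given separable 2-D sine/cosine positions, and contextualized by
`n_enc_layers` pre-norm transformer encoder layers (default 6). Reports are
word-level tokenized against the generator's closed vocabulary (PAD/UNK
special tokens), embedded with 1-D sinusoidal positions, and encoded by a
shallow text transformer; sequences are padded/truncated to `max_text_len`
(default 32). Both streams are linearly projected to `d_model`, given a
learned modality-type embedding, concatenated into the multimodal memory
(the visual block receives the fixed 2-D positional encoding again at this
point), and attended by `F` learnable fixation queries through
`n_dec_layers` decoder layers (default 6) with padding-aware cross-attention.
Separate MLP heads produce `(mu, lam)` for x, y, duration and two validity
logits per step.

The full-scale design this emulates wraps frozen pretrained encoders (a CNN
feature extractor, a query-former bridge and a frozen LLM) around the same
contract; `encode_image` / `encode_text` are the documented swap points —
any module producing `(batch, sequence, d_model)` embeddings can stand in.
The encoders here are small and trained end-to-end because pretraining at
that scale is outside this package's scope.

**Sampling and termination.** `X = mu + eps * exp(0.5 * lam)` per channel;
`eps = 0` is mean mode (deterministic, the evaluation default), `eps ~ N(0,1)`
is sample mode. Validity logits are softmaxed into a padding probability V;
the prediction terminates at the first step with V > 0.5 (V is the
*padding*-class probability — the convention that makes "terminate when
V > 0.5" coherent). Termination at step 0 yields an empty prediction
flagged `degenerate` rather than an error. Coordinates are clipped to
[0, 1] and durations floored at `t_min = 0.02 s` **at export only**, keeping
the training-time transform an exact affine map.

**Losses.** Per case, `L_spa` is the L1 error over x, y, t summed over the
first `l` (ground-truth length) steps and divided by `l`; padded steps are
excluded. `L_val` is the binary NLL of the valid-class probability over all
F steps with 1/F normalization, probabilities clamped to
[1e-7, 1 - 1e-7]. The printed form of the validity sum elsewhere ranges
over steps 1..L-1; we read that as a typesetting slip (it would ignore the
first token) and sum over all steps — `literal_val_range=True` reproduces
the literal range. The total `L_t` averages `L_spa + L_val` over the batch.
Training predictions are reparameterized samples by default so gradients
reach both `mu` and `lam`; `sample_mode=False` trains on means.

**Initialization.** Xavier-uniform linears; fixation queries drawn from
N(0, 1/d_model). The log-variance output channels start at −3 (std
≈ 0.22) so early sample-mode training is not drowned in sampling noise, and
the mean heads start at the image center (0.5, 0.5) and a typical fixation
duration (0.25 s) instead of the corner (0, 0, 0).

**Optimization.** Adam with two parameter groups — encoders vs
queries/decoder/heads/projections ("disjoint optimization"); every
trainable parameter must belong to exactly one group. Defaults: lr 1e-3 for
both groups, global gradient-norm clip 1.0, 20-step linear warmup followed
by cosine decay to a 5 % floor, and Polyak (EMA) averaging of the weights
(decay 0.995) with the averaged weights taken as the final model. Batch
size defaults to 32 and epochs to 200 (the full-scale recipe); the tiny
profile (below) uses batch 16 and 30 epochs. These optimizer settings were
chosen for stable convergence of the small-data profile; all are config
fields.

## Synthetic study conditions

The generator emulates the structure of radiology gaze corpora — image +
report + ordered fixation sequence with durations, lengths ≤ 50 — without
any photorealism:

- **Scenes.** 64×64 rasters, constant 0.25 background, 0–3 isotropic
  Gaussian "finding" blobs (count uniform; centers uniform in [0.1, 0.9]²;
  extent sigma ~ U(0.05, 0.11) of image width; salience lognormal with
  dispersion 0.3 around 1), additive N(0, 0.02) pixel noise, clipped to
  [0, 1].
- **Reports.** Deterministic closed-vocabulary templates: one sentence per
  blob, "`<label>` in the `<left|right> <upper|mid|lower>` zone."; zero
  blobs yield the fixed sentence "heart and lungs are normal." The 3×2 zone
  grid gives the text a learnable spatial code; full-report language is out
  of scope.
- **Scanpaths.** Per blob, Poisson(4 × salience) fixations drawn from a 2-D
  Gaussian at the blob center (std = blob sigma), with lognormal durations
  (median 0.25 s × salience, dispersion 0.5). Blobs are visited along a
  nearest-neighbor tour from the image center; exploratory fixations from a
  broad central prior (N(0.5, 0.25) per axis) are interleaved with per-slot
  probability 0.2. Zero-blob cases draw Poisson(4) (min 1) exploratory
  fixations. Lengths are clipped to [1, 50].

Built-in, testable signals: fixation density concentrates at blob centers;
expected total duration is non-decreasing in blob count (Spearman > 0.3
over hundreds of cases) — the desk-scale analogue of "harder cases take
longer". What the generator does **not** model: anatomy and realistic
texture, inter-reader variability beyond the stated noise, saccade dynamics
and re-reading behavior, or free-text report language. Passing tests here
demonstrate that the pipeline can learn report/image-conditioned gaze
structure at this scale, not clinical-grade performance on real data.

## Evaluation definitions

- **Heatmaps.** Sum of duration-scaled unit-peak Gaussians at fixation
  locations, truncated at 3 sigma (circular), default spread sigma = 50 px
  on a 512×512 rendering raster, max-normalized for storage. Before
  normalization the mass equals `sum_i t_i ×` (truncated kernel mass) for
  kernels fully inside the raster.
- **IoU.** Masks are `value > tau * max` with tau = 0.1 (the binarization is
  not standardized anywhere authoritative; tau is configurable and
  `iou_threshold_sweep` exposes the sensitivity). An empty union defines
  IoU = 0 with a warning.
- **CC.** Pixelwise Pearson correlation of z-normalized maps; constant maps
  give NaN, excluded from means.
- **MultiMatch.** Saccade vectors aligned by a dynamic program (right/down/
  diagonal moves) minimizing the summed vector-difference norm; per aligned
  pair the dissimilarities are vector difference (shape), amplitude
  difference (length), angular difference (direction), onset-fixation
  distance (position) and relative duration difference; spatial terms are
  normalized by the image diagonal (√2), direction by π; similarity =
  1 − mean, clipped to [0, 1]. Scanpaths with fewer than two fixations get
  NaN vector dimensions; position/duration fall back to fixation-level
  alignment. `mMM` averages the four spatial dimensions; duration is
  reported separately as `mD-MM` (results tables keep them as separate
  columns); `include_duration` switches to the 5-dimension mean.
  Amplitude/direction-based scanpath simplification exists but is off by
  default so comparisons are deterministic in the number of fixations.
  Zero-length saccade vectors take angle 0, and two zero vectors have zero
  direction dissimilarity.
- **Split evaluation.** Per-case metrics averaged (NaNs excluded);
  percentile bootstrap over cases (default 1000 resamples, seeded, the same
  resampling indices reused for every metric) gives 95 % CIs; the report is
  keyed by spread sigma so a spread sweep reproduces curve-style analyses.
- **Workload.** Total fixation duration per case; rank 1 = longest = highest
  workload; Pearson on totals, Spearman on average-tie ranks; extreme-case
  listing breaks ties lexicographically by case id. These mirror the
  analysis that high-workload cases typically carry multiple findings.

## Desk-scale profile and measured behavior

The shipped `tiny` preset — 300 training cases, 64×64 images, d_model 64,
F = 12, 2 encoder / 2 decoder / 1 text layer, 4 heads, max_text_len 24,
dropout 0.1, 30 epochs at batch 16 — trains in roughly a minute on one CPU.
Layer counts and batch size are profile choices for this data scale; F = 12
matches the generated length distribution the way F = 50 matches clinical
corpora (ground-truth paths longer than F are truncated to their first F
fixations, so length metrics compare against `min(l, F)`, the model's
representable range).

The acceptance script (`scripts/acceptance.py`) recomputes, from scratch at
a given seed: the final/first-epoch loss ratio; mean-mode heatmap mIoU and
mCC on the 100-case test split; the same mIoU for a shuffled-scanpath
baseline (each case scored against the prediction for the next case, a
derangement — the control for report/image conditioning); mMM and mD-MM;
the mean absolute scanpath-length error; Pearson/Spearman between predicted
and true total durations; and the generator's blob-count/duration Spearman.
The test suite asserts the qualitative versions of these (loss halves,
mIoU ≥ 2× the shuffled baseline, length MAE ≤ 2, workload Spearman > 0.3)
at a fixed seed. Seed-to-seed scatter on the IoU ratio is noticeable
(roughly 1.8–2.2 across seeds) because 300 training cases and ~600 gradient
steps leave the model underfit relative to a generative oracle, which
reaches ≈ 2.6 under the same conditions.

## Known limitations

- The encoders are trained from scratch on synthetic data; nothing here
  speaks to transfer onto real chest films without the pretrained stack.
- Mean-mode predictions are per-step conditional medians; for scenes with
  several findings the early steps resolve the nearest finding well, later
  steps blur between findings when the training budget is small.
- The L1 loss aligns fixations by index; models are not rewarded for
  covering findings in a different but valid order.
- MultiMatch is computed without simplification by default, which scores
  long jittery paths slightly differently from the original
  amplitude-clustered variant.
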