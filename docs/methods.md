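# Methods

## Model

The classifier operates on fixed-length frames of the raw waveform
(default `cw_len` = 10 ms; at 44.1 kHz that is 441 samples, at 16 kHz
160). A frame passes through:

1. **Input layer normalization** (per-sample, affine) — raw audio frames
   vary strongly in level; normalizing the frame stabilizes the first
   convolution. Configurable (`input_layernorm`).
2. **Frontend convolution**, one of two variants sharing the same output
   shape:
   - *sinc*: each of `n_filt_1` filters (default 80, length 251) is
     materialized from two learnable parameters through
     `f_l = |p_low|`, `f_h = f_l + |p_band|` (clipped to `[0, f_s/2]`)
     and the windowed difference-of-sincs kernel
     `g[n] = 2 f_h sinc(2π f_h n) − 2 f_l sinc(2π f_l n)` × Hamming.
     Frequencies are normalized by `f_s` inside the sinc argument so the
     kernel is dimensionless; `sinc(0) = 1` by continuity. Cutoffs are
     initialized at the mel-scale band edges
     (`mel(f) = 2595 log10(1 + f/700)`, `f_min` = 0 by default):
     `n_filt+1` equally spaced mel points whose adjacent pairs form
     contiguous, strictly increasing bands.
   - *standard_conv*: an unconstrained convolution of identical shape.
   Neither variant carries a bias term, so the learnable counts are
   exactly `2·n_filt_1` vs `n_filt_1·len_filt_1`.
3. **Conv stack**: per configured layer (default two of 60 filters,
   length 5): convolution → max pooling (length 3, non-overlapping) →
   layer normalization → leaky ReLU (slope 0.2).
4. **FC stack**: three fully connected layers (default 2048 wide) with
   batch normalization, leaky ReLU and optional dropout (default 0).
5. **LogSoftmax** over the classes; training minimizes the mean negative
   log-likelihood of the frame labels (each frame inherits its file's
   class).

A file is classified by tiling frames at stride `cw_shift` (default 1 ms)
across the labeled call, exponentiating the log-posteriors, averaging
over frames in probability space and taking the argmax (lowest index on
ties). Averaging in probability rather than log space is deliberate —
the vote is over the *mean posterior*; a `log_space` option exists for
comparison. Calls shorter than one frame are evaluated on a single frame
with the call centered (training instead places the call uniformly at
random inside the frame, completed with surrounding audio — the "uncut"
list dialect).

### Backpropagation

No deep-learning framework is used: every layer implements an explicit
backward pass on NumPy arrays. The sinc layer's gradient uses the
closed-form derivative of the windowed kernel,
`∂k[n]/∂f_h = 2 cos(2π f_h n) · w[n]` (and its negative for `f_l`),
chained through the constraint mapping with subgradient 0 where the clip
is strictly active (the boundary itself is kept live, so a filter whose
upper edge sits exactly at Nyquist after mel initialization can still
shrink). Valid convolutions are computed as BLAS matrix products of a
sliding-window view; the input gradient is one `(B·L, O) × (O, C·K)`
product followed by K shifted accumulations. Finite-difference tests pin
all gradients.

The optimizer is RMSprop with learning rate 0.001, smoothing constant
0.95, no momentum and no weight decay; minibatches of 128 frames, each
frame drawn from a uniformly random training item with a random window
position and a random gain `U(1−a, 1+a)` (default a = 0.2; 0 disables).
Item choice, window placement and amplification use separate named RNG
streams spawned from the training seed, so ablations change exactly one
factor; disabling amplification leaves window positions untouched.
An epoch is `batches_per_epoch` minibatches (default 800 — the epoch
definition is by batch count, not dataset passes, so it is
hardware-independent); training aborts with a diagnostic on a non-finite
loss. Weight initialization is uniform `±(1/fan_in)^1/2` under a fixed
seed.

## Labels, class modes and lists

Rich labels are per-recording CSVs (`start,duration,tag`, seconds, UTF-8);
`human`/`unknown` tags are parsed but flagged as nuisance. Cropping cuts
each event into its own peak-normalized WAV named
`<recording>_<seq>.wav`, where `seq` is the zero-padded order-by-start
index, so tags re-associate by name; silent segments are written
unnormalized with a warning. Normalization is per cropped segment
(max |x| = 1) — the common speech-recipe choice.

Three class modes map tags to dense indices, ordered by taxonomic group
(insects, amphibian, birds) then alphabetically: `all_classes` keeps
every non-nuisance tag, `bird_classes` drops non-bird tags,
`bird_species` merges each bird species' call/song/drumming tags. The
taxonomic grouping is dataset knowledge and is supplied as a tag → group
table (all-bird by default, which fits the synthetic corpora). Train/test
lists are a 75:25 random split by event (train takes the floor) after
removing nuisance events and events shorter than 10 ms; the cut dialect
lists segment paths, the uncut dialect `(recording, start, duration)`
triples. Overlap between events uses half-open intervals
`[start, start+duration)`, so abutting events do not count.

## Synthetic soundscapes

The generator emulates the structure of a richly annotated field corpus
without imitating any particular recording:

- **Species templates**: `k` carrier bands jittered inside contiguous
  log-spaced slots of (300 Hz, 0.45·f_s) — pairwise disjoint, inside
  Nyquist. Each template carries a harmonic count (0–2 extra partials),
  a chirp rate (up to ±0.5 bandwidths/s) and uniform duration bounds
  (minimum 0.05–0.12 s, width 0.1–0.3 s).
- **Calls**: harmonic stacks with a linear chirp and quarter-sine
  attack/decay envelope. The fundamental and every retained partial stay
  inside the band with a 15% interior margin, chosen so that the spectral
  leakage of even 50 ms calls keeps ≥ 95% of call energy inside the
  nominal band (a tested invariant).
- **Corpora**: per-class event counts are log-uniform between
  configurable bounds (default 9–60, mimicking the order-of-magnitude
  class imbalance of field annotation sets without copying any specific
  distribution); recordings hold 1–3 events of distinct species drawn
  without replacement. Each event after the first overlaps a
  different-species event with probability `overlap_prob`, which makes
  the realized fraction of overlapping events track `overlap_prob`
  (~0.21 measured at 0.2 across seeds; overlap pairs count two events).
  Durations never truncate — they are redrawn until the call fits.
  White noise is added at `noise_snr_db` relative to whole-file signal
  power; optional nuisance events are low-band tonal bursts. WAVs are
  16-bit PCM by default (32-bit configurable); label times are printed
  with 6 decimals, which round-trips to the exact sample index.

What the generator does *not* emulate: colored/structured background
noise (the field noise spectrum is not characterized; white noise is a
stand-in), reverberation and distance effects, within-species acoustic
variability beyond the chirp/harmonic jitter, and non-stationary event
rates. Passing tests on this corpus therefore demonstrate that the
pipeline's mechanics and learning dynamics are correct on band-separable
signals, not that field-recording accuracy is attained.

## The desk-scale study

The canonical end-to-end experiment
(`sincbird.scaled_synthetic_experiment`) uses 5 species, 40 one-call
files per class of 0.5–1 s at 16 kHz with 10 dB SNR; the model shrinks to
16 sinc filters × 65 taps, two (16, 5) conv layers and three 64-wide FC
layers, trained 10 epochs of 100 minibatches per replicate, 3 replicate
splits, with the corpus shared across frontend variants so the
sinc-vs-standard comparison differs only in the first layer. These sizes
make a full replicate-set run in a couple of minutes on one CPU while
leaving the task's chance level at 0.2; both frontends reach ≥ 0.9 test
accuracy with a margin.

## Numerical choices and edge cases

- Kernel length must be odd so the kernel has a center tap and is
  even-symmetric; convolution is implemented as cross-correlation, which
  coincides with true convolution for symmetric kernels (the
  impulse-response test pins the convention).
- `f_l = f_h` yields the all-zero kernel (zero-width band), not an error.
- No minimum cutoff or bandwidth is imposed beyond ≥ 0. Consequently the
  lowest bands of a dense mel initialization (~30 Hz wide at 80 filters)
  are narrower than a 251-tap kernel's spectral resolution
  (`f_s/I` ≈ 176 Hz); their spectral peak smears toward DC, which is a
  property of finite FIR kernels, not of the implementation. Band-pass
  assertions are therefore made at the resolution limit: peaks within one
  `f_s/I` cell of the band, strictly ordered for filters wider than the
  limit.
- Tie-breaks are deterministic everywhere: argmax votes take the lowest
  class index, top-k ranking uses a stable sort, the 75:25 split gives
  train the floor.
- ROC AUC is one-vs-rest per class present in the test truth, weighted by
  support, with midrank tie handling (scikit-learn's implementation);
  classes absent from the truth are excluded with a warning since their
  one-vs-rest problem has no positives.
- Cropping uses `round(start·f_s)` and `round(duration·f_s)` sample
  indices; an event extending past the end of its recording is an error,
  never clipped.
- All randomness flows from `numpy.random.SeedSequence`: experiments
  derive replicate seeds by spawning, training spawns separate streams per
  augmentation factor, and identical (seed, config, corpus) reproduce
  bit-identical histories on one platform.

## Known limitations

- The NumPy implementation is single-threaded CPU code; it is sized for
  the desk-scale study, not for the multi-hour GPU training that full
  field corpora require.
- Frame labels inherit the file's class; frames never span two events,
  and no multi-label output is produced for overlapping calls (the
  overlap-credit analysis quantifies, post hoc, how much of the error is
  explained by overlap instead).
- The uncut dialect completes short calls with surrounding audio, which
  can include other species' sound; this mirrors how such windows must be
  filled in practice but mildly contaminates short-call frames.
- Checkpoints use NumPy's `.npz` container and are portable only across
  platforms with identical float semantics.
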