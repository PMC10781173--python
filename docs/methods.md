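# Methods

## Discrete S-transform

The S-transform of a segment x is evaluated on the sample grid,

S(τ, f) = Σₜ x[t] · (f/√(2π)) · exp(−(τ−t)² f²/2) · exp(−i2πf·t/fs),

with one row per **integer frequency** in the requested band and one
column per sample. For the canonical 4-s, 1024-point, 256 Hz segment over
1–128 Hz this yields the 128 × 1024 matrix; integer-Hz rows are the only
grid consistent with that shape. Zero and negative frequencies are
excluded (the analysis band starts at 1 Hz). All arithmetic is double
precision.

**Edge handling** is circular: the Gaussian voice window is periodised
over the segment length (wrap count chosen so truncated tails are below
double precision). Both implementations share this convention, so they
agree to machine rounding:

* `stockwell_direct` — the literal O(n²)-per-row sum, kept as the
  brute-force oracle;
* `stockwell_fft` — per voice, a circular convolution evaluated in the
  frequency domain. By Poisson summation the DFT of the periodised sampled
  Gaussian equals the aliased samples of its continuous spectrum,
  G[m] = fs·Σ_q exp(−2π²(ν_m − q·fs)²/f²); |q| ≤ 2 bounds the aliasing far
  below 1e−15 for f ≤ fs/2. When every requested frequency falls on a DFT
  bin (true for 1024-point, 256 Hz segments), demodulation reduces to a
  spectrum shift and a single signal FFT serves all rows; off-bin
  frequencies fall back to one FFT per voice.

**Collapse property.** Under this discretisation the window's discrete sum
is fs (up to the same negligible aliasing), so Σ_τ S(τ, f) = fs · X(f)
where X is the DFT of the segment. Tests therefore compare
Σ_τ S(τ, f)/fs against the FFT coefficient, to 1e−6.

## Band-energy features

Bands are half-open [low, high) on the integer-Hz grid: delta rows 1–3,
theta 4–7, alpha 8–11, beta 12–29, gamma1 30–39, gamma2 40–49. The printed
rhythm boundaries overlap at the band edges (4 Hz is the top of delta and
the bottom of theta); the half-open rule is the disambiguation used
throughout, and it keeps rows 1–49 of the 1–50 Hz selection. The 4-s
window splits into two 2-s column blocks; each of the 12 units is the sum
of |S|² over its rows × columns, so the units exactly partition the
in-band energy (additivity is a test invariant). Features scale as
amplitude², and permuting channels permutes feature rows.

Feature normalisation (z-scoring each of the 12 columns with statistics
fitted on the training set, zero-variance scales clamped to 1) is a
numerical-stability choice for the small model, not part of the feature
definition; an identity mode is available.

## Transformer encoder

Tokens are channels; there is no positional encoding, making the class
probabilities channel-permutation invariant once combined with the
max-pool head (asserted on random inputs). Widths: d_model = 12 (equal to
the feature width, so no input projection), h = 3 heads,
d_k = d_v = d_model/h = 4 (enforced at construction), L = 6 layers.
Attention is softmax(QKᵀ/√d_k)·V; the √d_k scaling follows the original
Transformer mechanism. Each layer applies

y_i = MSA(LN(S_{i−1})),  S_i = S_{i−1} + y_i + MLP(LN(y_i)),

i.e. the feed-forward branch reads the attention output, not the running
stream. This differs from the standard pre-LN block; a `standard_block`
flag switches to the conventional form for ablation. The head max-pools
over channels, then a 12→32→2 MLP with softmax.

Per-channel attention weights are obtained from the final layer by summing
the h head matrices and averaging each column of the sum.

The network is small enough that it is implemented directly in NumPy:
explicit forward pass, hand-derived backward pass (checked against central
finite differences to ~1e−7 relative in the test suite), Adam
(lr 1e−3, β = 0.9/0.999), batch size 32, up to 200 epochs with patience-10
early stopping on a seeded 10% validation split, best parameters restored.
Optimiser settings are not part of the published method; they are defaults
exposed in `TrainConfig`. Dropout defaults to 0 (the model is tiny and the
synthetic task is data-rich); the closed-form parameter count (11,498 for
the default configuration) is asserted against the actual arrays. All randomness flows from one integer seed;
training is bit-reproducible.

## Post-processing

Stage order is fixed: moving average → threshold → collar → K-of-N.

* MAF: centred mean over `maf_window` epochs (default 3; odd required),
  truncated windows at the edges.
* Threshold: score ≥ θ → 1, default θ = 0.5.
* Collar: each maximal run of 1s grows by `collar_epochs` (default 1) on
  both sides, clipped at the trace bounds.
* K-of-N: default K = 5, N = 10 (a 40-s window of 4-s epochs); every
  N-window containing ≥ K positives marks its **entire span**, and
  overlapping triggered windows union. Equivalence with exhaustive window
  enumeration and monotonicity (adding input positives never removes
  output positives) are test invariants.

MAF window, collar width and threshold are not published values; the
defaults above are design choices, all config-exposed.

## Evaluation

Segment metrics are the usual confusion-count ratios reported in percent;
an empty denominator yields NaN ("undefined"), never 0. AUC is the
probability a positive segment outscores a negative one (Mann–Whitney,
ties ½; computed via the ROC integral, tested against all-pairs
enumeration).

Event scoring uses **any-overlap**: a predicted (start, end) intersecting
an annotated [onset, offset) counts that seizure as detected — each
seizure at most once, latency measured from onset to the earliest
overlapping prediction and clamped at 0 for early detections; a predicted
event spanning two annotations credits both; predictions overlapping
nothing are false alarms, reported per hour. Multi-patient totals support
both equal-weight patient averaging and count pooling, since the two can
differ materially.

## Synthetic data

The generator emulates the structure of long-term pediatric scalp EEG:
23 bipolar 10–20 channels, 256 Hz, microvolt amplitudes. Background is
1/f-power-weighted Gaussian noise at 30 µV RMS per channel (DC removed).
Each ictal episode adds a rhythmic oscillation — fundamental drawn from
3–12 Hz plus a half-amplitude harmonic capped at 30 Hz — at 3× the
background RMS (the dominance of 3–30 Hz activity at visibly elevated
amplitude is the defining feature being emulated), with per-channel gain
(0.7–1.3) and phase jitter (σ = 0.3 rad) and 2-s cosine on/off ramps.
Episodes default to 20–90 s, separated by ≥ 60 s, placed uniformly at
seeded random.

What it does **not** emulate: physiological artifacts (blinks, EMG,
electrode pops), spatial correlation structure across electrodes,
patient-specific seizure morphologies or evolving seizure frequency
dynamics. Passing tests on this generator therefore demonstrate the
pipeline's mechanics (feature separability, training, event recovery) —
near-perfect synthetic scores say nothing quantitative about performance
on clinical recordings, where class overlap is far larger.

Segmentation: ictal windows 4 s at 2-s stride (50% overlap), fully inside
an annotation; interictal windows 4 s at 4-s stride, fully outside all
annotations; boundary-straddling windows are discarded; balanced mode
subsamples interictal windows at seeded random to the ictal count. The
train/test split is a seeded shuffle at 3:1.

## Study sizes

The end-to-end study (tests and `scripts/acceptance.py`) trains on a 1-h
recording with 8 seizures (~450 balanced segments, 3:1 split) and
evaluates events on an independent 2-h recording with 10 seizures
(1800 scored epochs). These sizes give stable metrics at a few minutes of
single-CPU runtime; longer records only increase the interictal share.

## Known limitations

* The EDF writer supports the subset of EDF needed here (uniform rate,
  1-s records, 16-bit); it is not a general EDF+ implementation.
* Event scoring implements any-overlap only, not OVLP/TAES variants.
* Thresholds are global, not patient-adaptive; processing is offline.
* The direct S-transform oracle is O(n²F) and intended for n ≤ 256.
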