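# Methods

This note documents the models, algorithms and numerical choices behind
`silentspeech`, the assumptions they rest on, and what the synthetic-data
experiments do and do not establish.

## Signal model and montage

Recordings are 40-channel scalp EEG at 500 Hz, referenced to Afz,
microvolt units. The montage (`layout.DEFAULT_CHANNEL_NAMES`) is a 10–20
scheme densified over the temporal areas. Three spatial structures matter
downstream:

- **Hemisphere partition.** Lateral electrodes follow 10–20 numbering
  (odd = left, even = right). The eight midline electrodes (`z` suffix)
  belong to neither hemisphere anatomically; the default assigns
  Fpz, Fcz, Cpz, Poz to the left and Fz, Cz, Pz, Oz to the right —
  alternating front-to-back so both sides keep 20 channels and a similar
  anterior–posterior footprint. The assignment is configurable; nothing
  downstream depends on it beyond the row ordering of the input tensor.
- **Frontal triads.** Ocular noise is extracted per triad of frontal
  electrodes. Four classical triads sit around the reference —
  {Fpz, Fz, F3}, {Fp1, F3, F7}, {Fpz, Fz, F4}, {Fp2, F4, F8} — and two
  symmetric fronto-polar completions ({Fp1, Fpz, F3}, {Fp2, Fpz, F4})
  bring the count to six, three per hemisphere, matching the six
  eye-noise rows the tensor layout reserves. Any triad list is accepted.
- **Temporal groups.** The left-temporal group defaults to
  {T3, Ft7, C5, Tp7} (the electrodes nearest the speech areas; C5 stands
  in for a "C7" label that no 40-channel 10–20 montage defines), the
  right to {T4, Ft8, C6, Tp8}. The separability features use the left
  group only, on the proximity-to-speech-cortex rationale; the group is a
  parameter.

## Epoching and amplitude filters

An epoch is the half-open window `[onset, onset + 2048)` at the
presentation mark (0-based sample indexing throughout): 4.096 s covering
the 3 s presentation and ~1.1 s of the following blank. The offset is
configurable since nothing pins the window's exact alignment inside the
5 s trial.

Both rejection filters use the same statistic, the total modulus
t = Σ|x| over the whole epoch:

- **Stage 1** removes epochs that are broken rather than merely noisy:
  any non-finite sample, any all-zero channel (missing data), or
  t > `abs_cap`. The default cap is 10× the median epoch total — a
  scale-free choice that needs no dataset-specific constant and only
  triggers on order-of-magnitude outliers.
- **Stage 2** computes the 95th percentile of the survivors' totals
  (linear interpolation, numpy's default convention; midpoint conventions
  differ by at most one epoch at n = 1000) and removes epochs strictly
  above it. With n distinct totals this retains ⌈0.95 n⌉ ± 1 — exactly
  950 of 1000.

Whether the two filters of the original procedure shared one statistic or
used two is not determinable from its description; one statistic with two
cutoffs (a hard cap, then a percentile trim) is the reading implemented,
and the filter log (`EpochSet.provenance`) records what each stage removed.

## Ocular-component extraction

Per triad: (1) FastICA, 2 components, deflation, `random_state=42`,
library defaults otherwise; (2) per component, zero the 3 lowest
nonnegative-frequency FFT bins (including DC — the step's purpose is
trend removal) and invert; (3) Savitzky–Golay smoothing, window 21,
polynomial order 5; (4) keep the component with the largest max − median.

Two non-obvious choices:

- **Sign ambiguity.** ICA components have no canonical sign, and
  max − median is sign-sensitive (a downward blink bump would score
  poorly). Each component is scored in both orientations and the better
  one used. Consequently the returned series is defined up to this
  orientation rule, and correlation-based checks use |r|.
- **Degenerate input.** A constant (e.g. all-zero) triad cannot be
  unmixed; the extraction returns zeros and flags the group with
  `chosen_index = -1` instead of raising, so a dead frontal patch does
  not abort tensorization.

The input segment is never modified — the procedure selects a component,
it does not clean the EEG. During tensorization the extraction runs on
the 62.5 Hz phase-0 series (length 256 ≥ the smoother window); it can
also be run on raw epochs for diagnostics (`silentspeech inspect-ocular`).

## Index-mask downsampling and the input tensor

Downsampling by factor f keeps all samples as f phase sub-series (indices
≡ 0..f−1 mod f). This is deliberate: no anti-alias filter, no information
loss — the phases interleave back into the original exactly, which the
tests assert. An epoch therefore becomes two 40 × 1024 samples at 250 Hz
(Sample 01 = even columns, Sample 02 = odd), and each sample one tensor.

The published block order (eye noise left, left-hemisphere data, Ft7/T3
median, all-channel 62.5 Hz data, Ft8/T4 median, right-hemisphere data,
eye noise right) does not come with block sizes that sum to 256 under any
literal reading, so the package fixes one concrete layout honoring the
order, the 160-row 62.5 Hz block and the 256 × 256 total:

| block | rows |
|---|---|
| eye noise, left triads | 3 |
| 125 Hz phases, left hemisphere, first 256 columns | 40 (20 ch × 2) |
| median(Ft7, T3): 125 Hz half + four 62.5 Hz phases | 5 |
| 62.5 Hz phases, all channels | 160 (40 ch × 4) |
| median(Ft8, T4) | 5 |
| 125 Hz phases, right hemisphere, first 256 columns | 40 |
| eye noise, right triads | 3 |

"First half" of a 512-long 125 Hz phase means columns 0–255. The median
of two channels equals their mean and is computed element-wise. Every
tensor carries its `row_map`, so downstream code never hard-codes the
layout. No amplitude normalization is applied at this stage (an optional
flag exists on the classifier side instead).

## Separability analysis

Features: per epoch, the rFFT magnitudes of the left-temporal channels
restricted to 5–49 Hz (frequencies outside zeroed), concatenated — 4
channels × 180 bins = 720 features at 2048 samples. Magnitudes rather
than complex parts make the feature phase-invariant, which suits a test
of *where spectral energy sits*; a `return_time` flag exposes the
band-limited series instead. The transform runs per epoch (running it per
concatenated session would entangle epochs and is not what the epoch-wise
KS comparison needs).

Embedding: PCA to 50 components, then t-SNE to 3 with perplexity 30,
learning rate 10, up to 5000 iterations (tests and the CLI pass smaller
iteration counts; the embedding stabilizes long before 5000 on these
sizes), exact-gradient method (the tree approximation is unavailable for
3-D output), PCA initialization, fixed seed (default 0) since t-SNE is
otherwise stochastic. With fewer than ~90 points the perplexity is
reduced to (n−1)/3.

Testing: for every unordered word pair and each of the 3 components, the
two-sample KS statistic D = sup|F₁ − F₂| with the asymptotic p-value
(clamped away from exact zero when the formula underflows);
`best_component` is the argmin-p component per pair, mirroring how such
tables report "the component where the test is most convincing". No
multiple-testing correction is applied by default — the reported values
are raw per-pair p-values — but Bonferroni/Holm can be applied to the
long-format table by the caller. Words with fewer than 5 points are
excluded with a warning.

## Classifier

Architecture (full preset): stem 7×7 conv, stride 2, + batch norm + ReLU
(the stem adapts the single-plane 256 × 256 input); four stages of
basic residual blocks (2/2/2/2 at widths 64/128/256/512, first block of
each stage stride 2) without any trunk-level fully connected layer or
softmax; the final 512 × 8 × 8 feature map is read column-wise — map
columns become 8 time steps of 4096 features, preserving the tensor's
left-to-right axis — into a 2-layer GRU with 1024 hidden units;
the last step's hidden vector is average-pooled with width 2 down to 512;
a fully connected layer with ReLU and an output projection produce the
softmax class probabilities. (The pooled 512 values feed "a fully
connected layer with ReLU"; a ReLU applied directly to class logits
would clamp them at zero, so the head is read as FC 512→512 + ReLU
followed by the class projection.) Deeper presets (50, 101) raise the
stage depths; they share the basic-block design — depth is the knob, the
bottleneck variant is out of scope. No dropout.

The `lite` preset (stem 3×3; stages 16/32, one block each; GRU hidden 64;
64 × 64 input obtained by stride-4 index subsampling of the tensor —
the same phase-mask idea, keeping raw samples rather than smoothing them)
exists so the full training protocol runs in ~1 minute per 100 steps on
one CPU core. Classifier-side input preparation standardizes each tensor
to zero mean, unit variance; this is a conditioning step for optimization
and does not alter the stored tensors.

Training: Adam (β = 0.9/0.999), mini-batch 16, lr 0.01 divided by 10
after optimizer steps 500 and 1000 ("iterations" count optimizer steps;
an epoch-based schedule is configurable), up to 2500 steps,
cross-entropy. Weight init: He-normal for conv and linear, orthogonal for
GRU recurrent matrices, all seed-controlled; given the data and seeds,
training is bit-deterministic on one device. Divergence (non-finite
loss) raises immediately. The validation split is measured, never used
to adjust weights.

Splitting is stratified by word at the *trial* level: the two tensors of
one epoch always land in the same partition (the stricter reading of how
paired samples should be handled — anything else leaks near-duplicate
trials across splits), 70/20/10 train/validation/test, with out-of-sample
subjects removed from all three splits entirely.

The autograd core beneath the model is part of the package: reverse-mode
differentiation over numpy arrays with conv2d (im2col), batch norm, GRU
cells, pooling and a fused softmax cross-entropy. Every operator's
gradient is validated against central finite differences in the test
suite, which is the contract that makes the rest of the classifier
trustworthy.

## Synthetic data: what it emulates and what it does not

`generate_recording` produces, per trial, 5 s of signal (3 s presentation
+ 2 s blank) with a mark at presentation onset:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 1 | subjects, concatenated into one recording |
| `sessions_per_subject` | 5 | sessions (experiments ran 5–14) |
| `words_per_session` | 10 | words read per session |
| `rate` | 500 Hz | sampling rate |
| `class_effect` | 1.0 | word-signature amplitude scale (1.0 ≈ 4 µV against ~10 µV background) |
| `subject_effect` | 0.5 | scale of subject-specific random channel mixing |
| `blink_rate` | 0.2 /s | expected frontal blink events |
| `words` | all 9 | vocabulary (subsets for binary experiments) |
| `seed` | 0 | single source of all randomness |

Construction: per-channel 1/f (α = 1) background at ~10 µV plus a small
spatially common 1/f component; per word, a fixed signature of three
narrowband oscillations (centre frequencies drawn once per vocabulary
from 5–49 Hz) with per-trial random phase and a per-word random
topography emphasizing the temporal electrodes, active only during the
presentation window (0.1 s cosine ramps); per subject, a fixed mixing
matrix I + `subject_effect`·R/√n applied to the neural signal; blinks as
squared-sine bumps (0.25–0.45 s, 60–120 µV, ≥95% of energy below 3 Hz)
with weights supported only on the frontal electrodes, added after
mixing. All draws flow from one seeded generator; identical configs give
bit-identical recordings.

The defaults aim at the regime where the pipeline's behaviour is
informative: a class signal that is present but not dominant, visible
blink artifacts, mild subject idiosyncrasy. `class_effect` values used in
the tests — 0 (null), 2.5 (learnable), 4 (strongly separable) — bracket
the lite classifier's learning threshold, which sits between 1.5 and 2.5
at desk-scale training budgets (at 1.5 the model memorizes the training
set without generalizing). For cross-subject experiments the tests use
`subject_effect` = 4 with `class_effect` = 2.5: the word signal is
learnable within a subject while the mixing dominates it across subjects,
reproducing the qualitative high-within / near-chance-transfer pattern.

What the generator does **not** model: volume conduction from actual
cortical sources (mixing is an abstract linear map, not a head model),
muscle/EMG artifacts, line noise, electrode drift or impedance changes,
non-stationarity across a session, and any genuine neurophysiology of
inner speech — word "signatures" are arbitrary spectral patterns. Passing
tests therefore demonstrate that the *pipeline* does what it claims
(recovers injected structure, controls false positives, respects its
invariants), not that silent words are decodable from real EEG at any
particular accuracy. Published accuracies from the 270-subject study this
pipeline targets are not reproducible without that (undeposited) dataset
and are deliberately not asserted anywhere; the cross-subject and
separability structure is checked directionally instead.

## Numerical choices and degenerate inputs

- EDF+ serialization quantizes to 16 bits against a per-channel symmetric
  physical range (error ≤ range/65535, asserted in tests); recordings are
  padded to whole 1 s records; marks ride in the TAL annotation track and
  redundantly in a sidecar CSV (which also carries subject/session ids
  for readers that drop annotations).
- Percentiles use linear interpolation (numpy default).
- The KS p-value uses the asymptotic two-sample distribution; the
  statistic itself is tested against an exhaustive ECDF-difference oracle
  for all sizes up to 200.
- t-SNE: exact method, fixed seed; duplicate feature rows embed at
  coinciding coordinates.
- Epochs too close to the recording end are skipped with a warning, not
  padded. Empty epoch sets are an error for stage 2 (a percentile of
  nothing is undefined) but fine for stage 1.
- All-zero tensor inputs produce all-zero data blocks and flagged
  (−1) eye rows.
- Training aborts on non-finite loss rather than continuing silently.

## Test problem sizes

The suite runs everything at desk scale, chosen so the full run fits
comfortably in ~20 minutes on one CPU core: binary classification on
~114 epochs (228 tensors) with 150–300 optimizer steps; cross-subject
runs on 2 × 8 sessions over 5 seeds; type-I control on 475 null epochs
(9 words, ~53 per word); the all-pairs separability check on ~1900 epochs
(~210 per word); blink recovery on 50 seeded mixings. The acceptance
script (`scripts/acceptance.py`) re-runs the same computations from
scratch under a caller-supplied seed.

## Known limitations

- The full-size trunk (ResNet-18-scale + GRU 1024) is implemented and
  buildable but impractically slow to *train* in pure numpy; the training
  protocol is exercised end to end on the lite preset. The 50/101 presets
  deepen the basic-block trunk rather than implementing bottleneck blocks.
- The EDF writer covers what the pipeline needs (16-bit EDF+C, one data
  record per second, text annotations); it is not a general-purpose EDF
  library.
- The ocular module extracts eye-noise components; it does not subtract
  them from the EEG (regression/ICA-cleaning is explicitly out of scope).
- KS p-values at the sizes used are conservative (asymptotic formula,
  small n), which makes the type-I check easy to pass; the statistic, not
  the p-value, carries the oracle guarantee.
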