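# Methods

## Signal model and grid

An averaged click-ABR sweep is represented on a fixed uniform grid of
1,024 samples with spacing Δt = 0.025 ms. The printed endpoints of the
clinical acquisition window (−12.78 and 12.80 ms) and the spacing are not
mutually consistent at full precision, so the grid is *defined* as
t(i) = 0.025·(i − 511): stimulus onset falls exactly on sample 511, the
analysis window [0, 8] ms contains exactly 321 samples (indices 511–831),
and the endpoints reproduce the printed values after rounding to two
decimals. This is the only anchoring that reconciles all three printed
constants, and every index↔time conversion in the package derives from it.
Sub-sample latencies snap to the nearest grid index, with exact
half-sample ties resolved to the lower index (a documented convention;
clinically marked latencies are assumed grid-aligned, which the simulator
enforces by construction).

## Label construction

Each annotated wave contributes a single 1 in a 321-long binary target
vector at its nearest window index. Before training, marks are dilated by
radius 4 samples (0.1 ms) per side into nine-sample feature areas; the
dilation is a set union, so areas that overlap are not double-counted, and
areas are clipped at the window edges. Dilation serves two purposes:
3 positives out of 321 samples leave the per-step cross-entropy almost
flat, and manual marks carry sub-sample reading error that a nine-sample
target absorbs. Inputs are z-scored per trace before model ingestion
(recurrent optimization is scale-sensitive); raw µV values are preserved
for IO and inspection.

## Sequence classifier

The classifier is a stack of 1–5 recurrent layers, unidirectional or
bidirectional, followed by an affine head shared across time and a
two-class softmax per step. The LSTM cell is the standard four-gate
recursion (forget, input, candidate, output) with memory cell
C_t = C_{t−1}⊙f_t + i_t⊙a_t and output h_t = o_t⊙tanh C_t. In
bidirectional layers the forward and backward hidden states are
concatenated before feeding the next layer. A two-class softmax head is
used (an equivalent parameterization of a sigmoid output for binary
targets) so the per-step loss is the categorical cross-entropy.

The network is implemented directly on numpy arrays with a fused-gate
weight layout (one GEMM per time step per direction) and hand-derived
backpropagation through time; a scalar per-gate reference cell provides an
independent second route through the same algebra. Correctness is pinned
two ways: the vectorized recursion matches the reference cell to <1e−5 on
random instances, and BPTT gradients match central finite differences to
1e−4 relative at random parameters. Training uses Adam (lr 1e−3, β =
0.9/0.999), batch size 32, 60 epochs by default — standard, stable choices
for recurrent nets of this size; all are exposed in
`SequenceModelConfig` and recorded in the training log. Initialization is
uniform ±1/√H with the forget-gate bias offset by +1 (remember-by-default,
the usual LSTM initialization). No inter-layer dropout is applied by
default. A validation fraction (default 10%) is carved deterministically
from the training material — never from a held-out test set — and scored
once per epoch with frozen weights. Float32 is the default compute dtype;
float64 is available (and used by the gradient tests).

## Wavelet preprocessing

The optional denoiser decomposes the 321-sample window with a six-level
discrete wavelet transform and reconstructs from the level-6 approximation
plus the details of levels 4–6. At the 40 kHz sampling rate this keeps
content below ≈2.5 kHz and removes the three finest detail bands. The
mother wavelet is Daubechies-4 with symmetric boundary extension and
truncation back to 321 samples after the inverse transform; the family and
boundary mode are configurable, and because the smoothing/distortion
trade-off depends on both, comparison experiments should be reported
per-family. Six levels on 321 samples means every coefficient feels the
boundary extension (the transform library warns accordingly); perfect
reconstruction still holds to machine precision, which the tests assert at
1e−8 relative together with sub-band additivity (retained + complement =
original) and linearity.

## Postprocessing

Probabilities are thresholded at 0.5 (≥ counts as positive — the boundary
convention is documented and tested), maximal positive runs are extracted,
and runs whose inter-run gap is below 20 samples (0.5 ms) are merged
transitively into wave regions: "within 20 sampling points" is read as
gap < 20, so the largest bridged gap is 19 samples. A region's latency is
the mean of its first and last sample times. Regions supported by fewer
than 3 positive samples are discarded — a minimum-support rule reflecting
the clinical reading that a wave without enough continuous identification
points is not trusted; the exact cutoff is a package choice and is
configurable. Finally regions are assigned wave identities by latency
gates (defaults I: 1.0–2.4 ms, III: 3.0–4.6 ms, V: 4.8–7.0 ms, typical
click-ABR ranges at high stimulus level), earliest qualifying region
first; unassigned regions are retained unlabeled. The binary labeler
cannot itself name waves, so gating is the minimal assumption that turns
regions into per-wave latencies.

## Evaluation

A predicted region matches a marked point when |predicted latency −
marked latency| ≤ ME, with ME ∈ {0.1, 0.15, 0.2} ms; 0.2 ms is the scale
usually accepted for clinically marked points. Matching is one-to-one:
marked waves are processed in latency order and each greedily takes the
nearest unmatched region center within ME. A brute-force optimal
assignment is available behind a flag; on random instances greedy trails
optimal by at most one match (a property test), and on clean data they
coincide. ACC = r_p / p_n pools matched and total marked points over all
sweeps before dividing (micro-average), so sweeps with absent waves
contribute fewer points. The metric is recall-like — spurious predictions
far from every mark never lower it — so false positives are reported as a
supplementary count. Repeated k-fold cross-validation (default 5 repeats
of 9-fold) reshuffles per repeat with seeds derived from a master seed and
accepts an arbitrary train/predict callable, so the scoring machinery is
testable with dummy predictors.

## Synthetic data generator

Each sweep is a sum of Gaussian bumps (waves I–V) plus noise. Default
templates (normal hearing, 96 dB nHL): latencies 1.6, 2.8, 3.9, 5.1,
5.7 ms with SDs 0.10–0.15 ms; amplitudes 0.30, 0.12, 0.35, 0.15, 0.45 µV
with SDs 0.04–0.08 µV; bump widths 0.22, 0.22, 0.28, 0.20, 0.30 ms; waves
II and IV are generated for morphological realism (fused IV–V complex) but
never annotated. Latency draws are snapped to the grid before synthesis,
so annotations coincide exactly with grid samples. Widths were chosen
narrow enough that a neighbouring bump displaces each annotated wave's
composite local maximum by less than half a sample — with broader bumps
wave IV shifts the wave-V crest by several samples, which would break the
correspondence between annotation and visible peak that the tests rely
on. Realized latency vectors are rejection-sampled until strictly
increasing with a two-sample margin, so annotations always satisfy the
I < III < V ordering contract.

Abnormal-hearing sweeps scale amplitudes by 0.45, double latency jitter
and reduce per-wave presence probability (I 0.55, III 0.65, V 0.90 of the
template value); a wave whose drawn amplitude falls below the visibility
floor (0.08 µV) is synthesized but not annotated, emulating waves too
faint to mark. Noise is broadband Gaussian (default SD 0.03 µV) plus slow
sinusoidal drift (0.05 µV, 20 ms period, random phase) and, with
probability 0.3, a late-window (t > 8 ms) artifact burst emulating
myogenic contamination — which the windowing step then excludes by
construction. The default dataset composition is 70.5% abnormal
(433/614), matching the clinical prevalence the generator stands in for.
Per-sweep generators are spawned from a master seed, so datasets are
bit-identical across runs.

What the generator does *not* emulate: real ABR waves are asymmetric
(sharp rise, slow decay), noise is colored and nonstationary, latencies
shift systematically with stimulus level and pathology type, and manual
marks disagree between readers. Passing tests therefore demonstrate that
the pipeline recovers peaks under the stated statistical structure, not
that any particular clinical accuracy would be attained; the clinical
noise statistics were never characterized in a reproducible form, so the
synthetic defaults cannot be validated against them.

## Experiment presets and problem sizes

Two presets ship: `easy` (all waves present, baseline SD 0.02 µV, drift
0.02 µV, no late artifacts, normal class only) and `clinical` (the default
generator). Qualitative architecture orderings (bidirectional beats
unidirectional; three layers beat one) are asserted only on `easy`, where
training variance is small. The benchmark comparison
(`run_easy_benchmark`, also what `scripts/acceptance.py` runs) uses 600
sweeps, a 480/120 split, 128 hidden nodes, batch 64 and 10 epochs — sizes
chosen so a full comparison trains in a few minutes on one CPU while
leaving the ordering stable; at these sizes the three-layer BiLSTM
saturates near-perfect recovery on the easy preset while the single-layer
LSTM does not. Per-sweep wall-clock prediction time is logged but never
asserted (hardware-dependent).

## Numerical choices and degenerate inputs

* Constant traces z-score to all zeros (SD floor 1e−12).
* Softmax is computed with max-subtraction; cross-entropy clamps picked
  probabilities at the dtype's tiny value.
* A non-finite training loss aborts with a diagnostic rather than
  continuing silently.
* `binarize` requires the cutoff strictly inside (0, 1); probabilities at
  exactly the cutoff count as positive.
* Empty annotations produce all-zero label vectors; empty prediction sets
  score zero matches; accuracy over a dataset with zero annotated points
  is rejected rather than returning 0/0.

## Known limitations

* Wave identities come from fixed latency gates; strongly delayed
  responses (e.g. low stimulus levels) would gate incorrectly — the
  package targets the high-level (96 dB nHL) regime.
* ACC has no false-positive term by design; a model that over-predicts is
  penalized only through the supplementary count.
* The generator's Gaussian-bump morphology makes the easy preset
  considerably easier than clinical data; absolute ACC values on synthetic
  data are not comparable to clinical accuracies.
* Training is CPU-bound numpy; it is adequate for hundreds of sweeps and
  hidden widths ≤ 512 but not for large-scale hyperparameter searches.
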