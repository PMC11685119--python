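# Methods

## Feature pipeline

Raw multichannel EEG (nominally 62 channels at 200 Hz, microvolts) is
band-pass filtered into the five canonical rhythms — δ 1–4, θ 4–8, α 8–14,
β 14–31, γ 31–50 Hz — with a Butterworth filter applied forward–backward
(`sosfiltfilt`), so the output is zero-phase and windows cut afterwards stay
aligned with the raw time axis. The default order is 5 per pass. A
consequence worth knowing: the −3 dB band edges are traversed twice, so a
white signal's power summed over the five separately filtered bands
recovers ~92% of its 1–50 Hz power at order 5 (≥95% at order 10). Band
allocation of mid-band energy is unaffected; only energy within a few Hz of
the edges is attenuated. The order is a constructor argument for users who
prefer sharper partitions.

Each channel–band–window triple is summarised by its differential entropy
under a Gaussian model, `h = ½ ln(2πe σ̂²)` nats, with `σ̂²` the biased
(1/n) sample variance of the 4-s band-filtered window. At n = 800 samples
the estimator's standard deviation is `½·√(2/n) ≈ 0.025` nats, so single
windows scatter ±0.05 nats around the closed form at the 2σ level; tests
and the acceptance script therefore check calibration on Monte-Carlo means
over many windows, not on single draws. Windows are non-overlapping and a
trailing partial window is dropped. Zero-variance windows raise an error
rather than returning −∞.

The 62×5 DE matrix feeds two views:

* **Activity map** — a 9×9×5 tensor; each electrode's band vector is
  written at its grid cell of a packaged 62-channel 10–20 montage
  (`eegdann/data/layout_9x9_v1.tsv`: names, grid row/col with row 0
  frontal, planar unit-square coordinates). The electrode→cell map is
  injective; empty cells are exactly zero, so the map's sum equals the DE
  matrix's sum and the matrix is recoverable by inverse lookup. 9×9 is the
  smallest lattice that admits an injective placement of this montage.
* **Topology graph** — node features are the DE matrix in layout order;
  the adjacency is a documented choice, not a measured connectivity:
  default k-nearest-neighbour (k = 4) on the planar coordinates,
  symmetrised by OR, with unit self-loops (`radius` and `full` rules are
  available). Self-loops guarantee every attention neighbourhood is
  non-empty.

Before entering the model, features are z-scored per (electrode, band)
cell with statistics fit on the training split only; the statistics travel
with the checkpoint. The same normalised matrix populates both views.

## Model

**Graph-attention branch.** Single-head attention layers: scores
`e_ij = LeakyReLU(aᵀ[W h_i ∥ W h_j])` (slope 0.2) over the neighbourhood
including self, softmax-normalised per centre node, output
`h'_i = ELU(Σ_j α_ij W h_j)`. Defaults: two layers 5→32→32 and a mean-pool
readout over nodes, which makes the branch invariant to a joint
permutation of nodes and adjacency (a flatten readout is available when
electrode identity should be preserved). Depth, widths, slope, output
nonlinearity and readout are configurable; attention rows summing to one
is asserted in tests.

**Residual-CNN branch.** Stem: 7×7 convolution with 5 input channels, 64
output channels, stride 2, padding 4, no bias (the padding follows the
reference architecture rather than the usual 3), then BN → ReLU → 3×3
max-pool (stride 2, padding 1). On a 9×9 input this yields 6×6 then 3×3.
Four stages of two basic blocks (widths 64/128/256/512). A basic block is
`X_main = BN(Conv3×3(ReLU(BN(Conv3×3(x)))))` plus a shortcut, ReLU after
the sum. The default shortcut is the standard one — identity when shapes
match, stride-matched 1×1 conv + BN otherwise; a `composite_shortcut` option
instead applies BN(Conv1×1(Conv3×3(x))) on every block, reproducing a
variant of the reference architecture whose own description of the
shortcut is self-contradictory. Since the spatial extent is already 3×3 after the
stem, stage 2 keeps stride 2 (3→2) but stages 3 and 4 fall back to stride
1 whenever the incoming extent is ≤ 3, preserving the 8-block depth
without collapsing below 1×1. Global average pooling gives a 512-vector.

**Fusion.** Concatenation, activity branch first; both inputs are
recoverable by slicing. Dropout (default rate 0.7, the reference
protocol's value; placement was unspecified, so it is applied to the fused
vector before both heads) precedes the classifier heads.

**Heads.** Emotion: one fully connected K-way layer. Domain: a 2-layer MLP
(fused→64→2, ReLU) behind a gradient-reversal node — identity forward,
gradient multiplied by −λ backward.

## Training

Optimiser Adam, learning rate 5e-4, batch 64 (half source, half target),
cross-entropy losses, all per the reference protocol. The adversarial
objective is `E = Σ_source L_emotion − λ Σ_{source∪target} L_domain`. Two
realisations are provided:

* `grl_joint` (default): one optimiser minimises
  `L_emotion + L_domain`; the reversal layer injects the −λ factor into
  the extractor's gradients, which is the canonical single-pass
  realisation of the minimax.
* `alternating`: explicit alternation — minimise `L_emotion − λ L_domain`
  over extractor + emotion head, then minimise `L_domain` over the domain
  head on a fresh forward pass.

λ was not specified by the reference protocol; the default schedule is the
standard ramp `λ(p) = 2/(1+e^{−10p}) − 1` over training progress `p`
(constant λ available), because a full-strength adversary at
initialisation destabilises the extractor. The epoch budget defaults to
100 with the final-epoch model retained; no early stopping, so target
labels are never consulted during training (transductive protocol: the
held-out subject's windows enter only the domain loss).

The source and target half-batches pass through the extractor separately,
each normalised by its own batch statistics. This keeps a λ = 0
adversarial run *exactly* equal, step for step, to a plain supervised
control (asserted bitwise in tests): the domain branch contributes zero
gradient, batch statistics of the emotion pathway are untouched, and every
RNG stream (initialisation per component, batching, the two dropout masks)
is named and independent, so the shared components consume identical
randomness in both configurations. All arithmetic is float64 numpy; a
rerun with the same seed is bit-identical, and NaN losses abort with a
diagnostic rather than propagating.

## Evaluation harness

Leave-one-subject-out: one split per subject, sources = everyone else.
Classification is per 4-s window (windows are the sample unit of the
feature pipeline; a trial-level majority vote is deliberately out of the
default path). Metrics: accuracy, macro-averaged F1 over classes present
in truth or predictions, and Cohen's kappa `(p_o − p_e)/(1 − p_e)`;
implemented via scikit-learn behind the `compute_metrics` surface and
verified in tests against hand-evaluated definitions. Summaries report
mean ± STD across splits. Six ablation variants toggle the three
components: SAE (activity branch only), STE (topology branch only),
SAE-STE (fused, no adversary), SAE-DANN, STE-DANN, DSP (all three).
Per-split training seeds derive deterministically from the run seed and
split index.

## Synthetic cohort

The generator emulates the *shape* of a SEED-like corpus — 15 subjects, 3
or 4 emotion classes, 62 channels at 200 Hz — with known ground truth.
Each trial is a sum of per-band Gaussian noise processes (zero-phase
band-limited, renormalised to unit variance so stated amplitudes are
realised standard deviations; base amplitudes 10/8/8/6/4 for δ/θ/α/β/γ),
plus broadband sensor noise (sd 2) and a DC offset. Class structure enters
twice, each switchable:

* **Amplitude effects**: per class, multipliers on (band, scalp-region)
  cells — regions are the frontal/central/posterior thirds of the grid. A
  multiplier m shifts that band's DE by exactly ln m on affected channels,
  giving a closed-form calibration target (verified: a ×2 α-posterior
  effect shifts DE by ln 2 ± 0.05).
* **Topology effects**: per class, shared band-limited components added to
  chosen electrode pairs, inducing inter-channel correlation (and a
  variance bump) at specific sites.

The per-subject domain shift has three parts: a per-channel multiplicative
gain (log-normal, sd 0.4 in log space), a per-band multiplicative spectral
tilt shared by all channels (log-normal, sd 0.4), and a per-channel DC
offset (sd 5, removed by filtering). The channel gain alone turned out to
be a weak confounder: it shifts all five bands of a channel equally, so
any classifier using within-channel band contrasts cancels it exactly.
The spectral tilt is the classic inter-subject nuisance in this domain —
subjects genuinely differ in global band power — and it moves the
class-informative band cells directly; with it, a source-only linear
baseline loses ≥10 accuracy points cross-subject at 2× the default sd,
which is the premise the adversarial branch exists to repair. All draws
descend from the cohort seed through named `SeedSequence` children
(per-trial and per-subject), so cohorts are bit-reproducible and the
ground truth (labels, gains, tilts, offsets) is serialised beside the
data.

What the generator does *not* emulate: 1/f background spectra, artifacts
(blinks, EMG), ERP-like transients, non-stationarity within trials, or
volume-conduction correlation structure. Passing tests therefore
demonstrate that the pipeline and the adversarial mechanism work as
specified on data with the right statistical skeleton — not that the model
attains any particular accuracy on real EEG.

## Scaled-down study conditions

The end-to-end studies in the test suite and `scripts/acceptance.py` use 6
subjects × 3 classes × 2 trials of 20 s (30 windows per subject), model
widths 8/16/16/16 (CNN) and 16/16 (attention), batch 32, 15 epochs, and
medians over 5 cohort seeds. These sizes were chosen as the smallest
conditions at which the studied contrasts are stable at the seed-median
level. Two cohorts are used deliberately:

* **Adaptation study** (shifted cohort, default shift): adversarial DSP vs
  source-only SAE-STE. The shift is strong enough that the source-only
  model hovers near chance, which is precisely the regime where the
  adversary's contribution is visible.
* **Complementarity study** (no shift): SAE vs STE vs SAE-STE. Fusion's
  advantage is a feature-capacity question; under a dominating domain gap
  all non-adaptive variants are pinned near chance and the comparison is
  uninformative, so this study removes the shift.

## Numerical choices and edge cases

float64 throughout; BN eps 1e-5, momentum 0.1, eval mode uses running
statistics. Attention softmax subtracts the row max and masks excluded
pairs to exact zero probability. Adjacency kNN ties break by stable sort
of distances (deterministic for the packaged layout). Degenerate inputs
raise typed errors: bands outside (0, Nyquist), recordings shorter than
the filter warm-up or one window, zero-variance windows, layout
collisions, missing channels, emotion labels on target-domain samples,
empty domains. CLI exit codes separate configuration (2), data (3) and
numerical (4) failures.

## Known limitations

Single-head attention only (multi-head, edge weights and learned
adjacencies are out of scope); basic blocks only (no bottlenecks); the
numpy engine is CPU-bound and float64, so full-width training at realistic
cohort sizes is slow — the default widths exist for fidelity to the
architecture, the narrow configs for practice; EDF export is not provided
(no writer dependency), only EDF reading; and synthetic results do not
transfer to claims about access-controlled benchmark corpora.
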