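# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `nirsblock`. It is the place to look when a default
needs justifying or a limitation needs checking.

## Problem setting

High-density (HD) frequency-domain fNIRS measures, for every
source-detector pair (channel), the amplitude attenuation and phase shift
of intensity-modulated near-infrared light diffusing through the scalp and
outer cortex. During a lateralised motor task (here, 10 s finger-opposition
blocks with the left or right hand), oxy-haemoglobin (HbO) rises and
deoxy-haemoglobin (Hb) falls over the contralateral motor cortex. The
package classifies 10-second windows of processed HD-fNIRS data into
left / right / rest, and asks a specific methodological question: does
arranging the channels as *topographic image stacks* and extracting
features with a positionally invariant 3D convolution help, compared to
treating each channel as an independent row?

## Probe geometry

Each pad is a 4 x 8 checkerboard of sources and detectors at 13 mm pitch
with one detector corner unpopulated (16 sources, 15 detectors per pad);
two mirror-image pads sit over the left and right motor cortices, separated
by a 26 mm gap chosen so the full frame has a half-pitch voxel column
exactly on the midline (required for mirror-flip augmentation). Channels
are classed by source-detector separation (SDS):

| class | lattice step | SDS | depth sensitivity |
|-------|--------------|-----|-------------------|
| NN1 | (1, 0) | 13 mm | superficial (scalp) |
| NN2 | (2, 1) | 13 sqrt(5) ~ 29.1 mm | cortical |
| NN3 | (3, 0) | 39 mm | cortical, but photon-starved |

NN3 channels are enumerated and then discarded (SDS > 30 mm), as their
photon counts are below PMT dynamic range in practice. NN2 channels are
split by orientation (horizontal when |dx| > |dy|). Channel position is the
source-detector midpoint, which always lands on the half-pitch (6.5 mm)
lattice. A geometric fact worth knowing: the two diagonal NN2 directions
(2, 1) and (2, -1) are both "horizontal" and can produce two distinct
channels with the *same* midpoint; such co-located, equal-SDS channels
measure essentially the same tissue volume and are averaged when imaged
(see Block below). Classification tolerance is 0.5 mm; a pair within
tolerance of two reference distances is an error, not a guess.

## Synthetic data

The study's recordings are not publicly deposited, so the simulator is the
test substrate, and its defaults define the conditions every end-to-end
test runs under: 7 subjects x 5 runs of the 460 s paradigm (30 s rest,
16 blocks of 10 s task + 15 s rest, 8 left / 8 right pseudo-randomised
with first block left and at most 3 consecutive same-hand blocks, 30 s
final rest), sampled at 39 Hz at 690/830 nm with 141 MHz modulation. The
`simulate_study_cohort` variant contaminates two randomly chosen runs so
channel QC rejects them, reproducing the 33-accepted-run / 1023-example
bookkeeping of the acquisition it emulates.

Physics: baseline amplitude and phase per channel come from the analytic
frequency-domain photon-diffusion solution for a homogeneous semi-infinite
medium with extrapolated-zero boundary (mua = 0.01 mm^-1, mus' = 1.0 mm^-1,
n = 1.4 - typical head-tissue values). Absorption perturbations map to
intensity through the effective pathlength L = -d ln A / d mua of the same
model (~81 mm at 13 mm SDS, ~207 mm at 29 mm), and to phase through
d(phase)/d(mua). A finite-element head model is deliberately out of scope;
the semi-infinite solution supplies realistic distance scaling at a tiny
fraction of the cost.

Haemodynamics: the task response is a double-gamma HbO kernel (peak at the
subject's latency, late undershoot, Hb = -HbO/3), convolved with the task
boxcar. Per-subject parameters are drawn once per cohort: peak amplitude
~N(1.0, 0.25) uM clipped to [0.4, 2.0], latency ~N(6.0, 0.5) s, spatial
extent sigma ~N(12, 2) mm, and - the key variable for this study - a
probe-placement offset of the activation locus per hemisphere,
~N(0, 10 mm) per axis, clipped at +-20 mm. Depth weights give NN2 channels
full cortical sensitivity and NN1 channels 0.3 of it; superficial weights
are reversed (NN1 = 1.0, NN2 = 0.6).

Realism mechanisms that make the task hard in the way real fNIRS is hard:

* per-trial response gain ~N(1, 0.35) and onset-latency jitter (sd 0.5 s) -
  single trials vary; block averages do not classify single windows;
* global systemic sinusoids (cardiac 1.1 Hz - removed by the band-pass -
  respiratory 0.25 Hz, Mayer 0.1 Hz) with run-random phases, entering
  through the superficial weight;
* band-limited (< 0.35 Hz) local scalp fluctuations, independent per
  channel, at 8e-5 mm^-1 RMS - comparable to the task-induced absorption
  change (~1.7e-4 mm^-1 peak at 830 nm), inside the analysis band, and the
  main reason a single channel is unreliable;
* multiplicative intensity noise whose relative level scales as
  1/sqrt(baseline amplitude), so dim NN2 channels are ~9x noisier than NN1;
* per-channel coupling factors (log-normal, sd 0.1) emulating hair/contact
  variation; heavy log-normal flicker (sd 2.5) for injected bad channels,
  which reliably exceeds the CV >= 7.5 quality threshold.

What the simulator does *not* model - and what passing tests therefore do
not show about real data: motion artefacts, anatomical variation in
cortical folding, wavelength-dependent coupling, extra-cerebral layered
physiology (scalp vs skull), instrument drift, and any nonlinearity of the
real FD electronics. Real between-subject variation is also richer than a
2D offset of a Gaussian locus; the simulated subject-independent problem
is easier than the real one, and absolute F1 values here sit above the
published range for comparable human experiments. The comparisons the
package makes (model orderings, scheme orderings) are meaningful; the
absolute scores are optimistic.

## Preprocessing

Stage order is fixed and channel-indexing-preserving:

1. difference measures against the run mean: dOD = -ln(i / mean(i))
   (natural log; the base is immaterial once z-scored), dph = ph - mean(ph);
2. channel QC on *raw* intensity: CV = std/mean per channel (max over the
   two wavelengths); CV >= 7.5 marks a channel poor (inclusive threshold);
   a run with strictly more than 30% of its short (SDS < 30 mm) channels
   poor is rejected outright (mis-seated cap);
3. discard SDS > 30 mm channels (NN3);
4. zero-phase 3rd-order Butterworth band-pass, 0.01-0.5 Hz
   (forward-backward, so no phase distortion of the response shape);
5. chromophore conversion: solve the 2x2 modified Beer-Lambert system
   dOD_lambda = L_lambda (eps_HbO dHbO + eps_Hb dHb) per channel and
   time-step, with L_lambda from the semi-infinite model at the channel's
   SDS and extinction coefficients from the standard tabulation (690 nm:
   HbO 276, Hb 2052; 830 nm: HbO 974, Hb 693 cm^-1/M, converted to
   natural-log mm^-1 uM^-1). A pass-through mode forwards dOD and dph
   unconverted (4 components instead of 2), reflecting the observation
   that classification hardly depends on this linear, invertible step;
6. polyphase anti-aliased resampling 39 Hz -> 2 Hz (up 2 / down 39,
   line-extension padding so run edges are not distorted);
7. population z-score per channel-component over the whole run (constant
   series map to zero with a warning). This removes per-channel gain -
   a per-channel affine rescaling of raw intensity provably cannot leak
   subject "markers" through this stage (tested);
8. interpolation of poor channels: unweighted mean of the up-to-8 good
   adjoining/diagonal channels of the same class and orientation (plus a
   co-located channel when one exists); an isolated poor channel is an
   error, not a silent zero;
9. windowing: one 20-frame (10 s) example per task block, labelled by
   hand, and one per inter-task rest interval, aligned to the rest onset.
   The rest after the 16th block merges into the closing 30 s rest and is
   not windowed - the unique reading under which 33 runs yield exactly
   33 x 31 = 1023 examples.

## Data structures

* **Block**: each (component, channel-group) pair - HbO/Hb x {NN1, NN2-h,
  NN2-v} - becomes an image layer; channels sit at their midpoint voxels
  in a common 7 x 33 half-pitch frame spanning both pads (midline at the
  centre column), zero-filled outside the validity mask; co-located
  channels are averaged into their shared voxel. Axis order is
  [layer, time, height, width].
* **Flat**: (channel x component) rows by 20 time columns, in canonical
  channel order; lossless.
* **S-by-D**: component x time x source-index x detector-index; valid
  cells are exactly the retained channels. Grid adjacency deliberately
  does not track spatial adjacency (tested), so this structure isolates
  "3D CNN" from "3D CNN + spatial arrangement".

Mirror-flip augmentation: every left/right training example gains a
width-reversed copy with the opposite label (contralateral dominance makes
the mirrored image a plausible opposite-hand trial); rest examples are not
duplicated. The whole two-pad frame is flipped (hemisphere swap), which is
well-defined because the layout is mirror-symmetric; NN2 orientations are
mirror-invariant. Augmentation refuses to run on anything not tagged as a
training split - a hard leakage guard, not a convention.

## Models

Both classifiers are scikit-learn estimators over a small NumPy engine
(im2col + GEMM convolutions, Adam, inverted dropout, softmax
cross-entropy); one integer seed drives initialisation, shuffling and
dropout, so fits are bit-reproducible. Grid-search-selected defaults:

| | 3D CNN (Block, S-by-D) | 1D CNN (Flat) |
|---|---|---|
| conv stage | 1 layer, 16 filters, kernel 4x3x3 (time x h x w), valid | 1 layer, 8 filters, temporal kernel 4, shared across rows |
| head | flatten -> dropout -> 2 x Dense(100, ReLU) -> Dense(3) | same, dropout 0.8 |
| dropout | 0.4 | 0.8 |
| training | batch 50, 60 epochs, Adam lr 0.01, cross-entropy | same |

Choices the hyperparameter table does not pin down, fixed here as package
defaults: ReLU activations, Adam, He initialisation, no pooling (the
frame is only 7 x 33), spatial kernel 3 x 3, per-input-layer filter banks
summed as in standard convolution, zero-fill masking of invalid voxels.
Dropout is applied once, to the flattened convolutional features, rather
than inside the 100-unit head: at the selected 1D rate of 0.8, dropout
after each hidden layer leaves ~20 active units per layer and an x25
inverted-dropout variance amplification, which empirically prevents the 1D
model from fitting even its training set; on the flatten layer (which
holds ~90% of the parameters) both selected rates train properly.

The 1D model applies the same temporal filters to every row but flattens
per-row features into the classifier, so its decision function is tied to
specific channels; the 3D model's convolution computes the same spatial-
temporal features at every position. This is exactly the mechanism the
subject-independent comparison probes: when the response locus moves
between subjects (probe placement), per-channel features transfer poorly.

## Evaluation

* **mixed**: train on all subjects, test on each subject's last collection
  session. **subject-independent**: leave-one-subject-out.
* Session leakage is a hard assertion on every fold; augmentation applies
  only to Block training folds.
* Scores are macro-F1 over {left, right, rest}; a class absent from both
  truth and prediction contributes 0 (ties the average down rather than
  silently dropping the class).
* Grid search is class-stratified, session-grouped 5-fold CV
  (`StratifiedGroupKFold`), run only on data that excludes the held-out
  test sessions.
* Statistics: Shapiro-Wilk per (model, subject) cell; two-way
  fixed-effects ANOVA (model + subject, balanced design enforced) on
  repeated-seed F1 samples; when the model effect is significant,
  post-hoc paired t-tests per model pair (paired on subject x repeat),
  reported with both t and t^2, p-values uncorrected. "Sampled F1" means
  repeated training with different seeds (default 10 repeats).

## Problem sizes in the test-suite and acceptance script

End-to-end classification checks train at reduced epoch counts instead of
the selected 60: on the synthetic cohorts the loss plateaus within a few
epochs, and the properties being checked are orderings and thresholds,
not converged maxima. The full 7 x 5 study cohort trains for 4 epochs
(~140 optimiser steps); the 3-subject x 3-run cohort used for the
scheme-ordering comparison trains for 12 epochs to keep the optimiser
step count comparable (it has only ~4 mini-batches per epoch). The
subject-independent block-vs-flat comparison and the F1 >= 0.8 recovery
check run on the full study cohort. `scripts/acceptance.py` re-simulates everything from scratch at
these same sizes from the given seed.

## Known limitations

* The NumPy engine is single-core and eager; it is sized for this probe
  (a few million parameters), not for general deep learning.
* The S-by-D model's flattened feature vector is ~5x larger than Block's,
  so it trains slowest despite being the "uninformative" control.
* The semi-infinite forward model ignores curvature and layered tissue;
  effective pathlengths are therefore approximate (DPF ~6-7, in the
  plausible range for adult heads).
* Phase is simulated and carried through I/O and pass-through mode, but
  the default chromophore conversion uses amplitude only.
* With zero probe jitter and zero noise the left/right classes are exact
  mirror images in expectation; tests exploiting this symmetry would pass
  trivially, which is why jitter is on by default.
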