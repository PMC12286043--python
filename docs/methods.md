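# Methods

This note documents the model, the parameter defaults and why they are
set as they are, the scope of the synthetic generator, and the numerical
choices that differ from the textbook formulation.

## 1. Task and pipeline

Input: a fixation table (id, start timestamp, duration, normalized gaze
position, scene-frame index, optional phase tag), a frame source, and an
AOI schema of K class names plus one background name. Output: one label
per fixation, produced semi-automatically — the classifier suggests, the
annotator confirms or corrects, feedback retrains the classifier.

Normalized gaze coordinates have the origin at the bottom-left
(`y_origin="bottom"`, configurable); pixel mapping rounds half-away-from
zero. Patches are cropped around the gaze pixel with edge padding, so
fixations near the frame border still yield full-size patches.

## 2. Few-shot reconstruction classifier

### Feature extraction

A 4-block convolutional backbone (channels 16→32→48→48, 3×3 kernels,
strides 2,2,2,1, ReLU) maps a `patch_size²×3` patch to a feature map
`Q ∈ R^{r×d}` with r = 16 spatial positions and d = 48 channels at the
32 px study scale; rows are L2-normalized. ~55k parameters total,
sized so that a full 30-epoch refit takes ~4–5 s on one CPU, which keeps
an 870-fixation session with ~40 retrains within minutes.

### Reconstruction scoring

For class k with support matrix `S_k ∈ R^{N·r×d}`, the score is the ridge
reconstruction residual of the query rows from the support rows:

    W* = Q S_kᵀ (S_k S_kᵀ + λI)⁻¹,     err_k = ||Q − W* S_k||²_F / r.

`reconstruct(Q, S, λ)` exposes exactly this (an `(N·r)×(N·r)` solve;
pseudo-inverse fallback at λ=0 with duplicated rows). The classifier's
hot path uses the algebraically identical dual form
`Q̂ = Q G (G + λI)⁻¹` with the `d×d` Gram matrix `G = SᵀS`, since
`N·r ≫ d`; both forms are tested to agree to machine precision.

Class probabilities are `softmax(−err/γ)` over the K AOI classes; the
background never has its own score (see §4).

### Training

Episodic training on the labeled pool: per epoch, each class contributes
3 support and 3 query patches (sampled with replacement if a class has
fewer than 6). The loss is cross-entropy over the episode's query
probabilities plus an auxiliary cross-class overlap penalty (§3). λ and
γ are learned in log space alongside the weights. Optimizer: plain SGD,
learning rate 1e-4, 30 epochs; interactive retrains warm-start from the
current weights. All gradients come from `fixmap.autodiff`, a small
reverse-mode tape over NumPy (matmul, conv via im2col, matrix inverse,
broadcasting ops), gradient-checked against central finite differences.

### Numerical deviations from the textbook formulation

Three deliberate deviations, each forced by analysis rather than tuning:

1. **Ridge scale.** A flat λ (e.g. 0.1) is negligible once a class's
   support rows (N·r = 160 unit rows at study scale) over-span the
   d = 48 dimensional feature space: every class reconstructs every
   query almost perfectly and probabilities collapse to uniform.
   Internally the penalty is applied as `λ_eff = λ·(N·r)/d` — scaled to
   the Gram spectrum, so its strength is invariant to support size —
   with λ initialized at 1.0 and learned. The public
   `reconstruct(Q, S, λ)` applies λ literally, as its hand examples
   require.
2. **Softmax temperature.** With unit-normalized feature rows the
   reconstruction errors lie in [0, 1], so at γ = 1 the winning
   probability can never exceed `1/(1+(K−1)e⁻¹)` ≈ 0.31 for K = 7 —
   below any useful background threshold, forcing every suggestion to
   background. γ is initialized at 0.02 (and learned), which spreads
   the error range over the softmax.
3. **Auxiliary-loss normalization.** The literal overlap penalty
   `Σ_{i≠j} ||S_i S_jᵀ||²_F` grows with the square of the support count;
   at study scale it is ~1e5 times the cross-entropy and destroys
   training. The training objective uses the *per-element mean* of the
   cross-class Gram blocks (same zero set, same gradient direction,
   size-invariant magnitude), scaled by 0.03. The public `aux_loss`
   computes the literal sum.

## 3. Auxiliary loss

`aux_loss(supports)` returns `Σ_{i≠j} ||S_i S_jᵀ||²_F`: zero iff all
cross-class feature rows are orthogonal; homogeneous of degree 4;
equals 2 for two identical one-row unit supports. It pushes class
subspaces apart, which matters precisely for twin AOIs whose supports
would otherwise be nearly identical.

## 4. Selective suggestion rule

With winning probability `p_max` and thresholds `t_BG ≤ t_AOI`
(defaults 0.4/0.4):

* `p_max < t_BG` → suggest background (rejection, not a learned class);
* `p_max ≥ t_AOI` → suggest the argmax AOI (ties to lowest index);
* otherwise → abstain (reachable only when `t_BG < t_AOI`).

A trust slider τ ∈ [0,1] sets confidence cut points
`c_high = 0.9 − 0.3τ`, `c_mid = 0.6 − 0.2τ`; background suggestions are
scored on `1 − p_max` (confidence in the *absence* of AOI evidence).

Feedback: non-background final labels enter the pool (re-annotation
replaces, background removes); every 10 newly pooled samples a retrain
launches. At most one retrain runs at a time; triggers that fire
meanwhile coalesce into a single pending retrain, so the number of
launches never exceeds `⌊new/10⌋ + 1`.

Retrains are *anchored*: each refit warm-starts from the weights the
session began with, not from the previous refit's output. The episodic
loss contains no background signal, and class patches cropped near AOI
borders contain background strips, so every refit slightly improves
background reconstruction inside class subspaces. Chained over ~40
retrains (~1200 cumulative epochs) this erodes rejection — measured on
the synthetic study, the background winning-probability mass above the
0.4 threshold grows from ~11% to ~79%, collapsing suggestions onto one
class — while anchored refits are stable under repetition. Anchoring
bounds drift to a single 30-epoch refit; the session's learning curve
is carried by the growing support set, which is unaffected.

## 5. Metrics

Classification scores wrap scikit-learn (`zero_division=0`; classes
never predicted are additionally flagged); multi-rater chance-corrected
agreement wraps statsmodels' Fleiss kappa, with the degenerate
`P̄e = 1 ∧ P̄ = 1` case defined as 1.0. Efficiency statistics
(mean completion time, seconds-per-fixation annotation rate) round
half-up via `decimal` so reported values are reproducible exactly.
Threshold sweeps evaluate precomputed probability vectors: a background
ROC over `t = t_BG = t_AOI`, and an accuracy/annotation-ratio sweep over
`t_aoi` at fixed `t_BG` (at `t_aoi = 1` the accuracy equals the
background precision, a test oracle). `collapse_classes` merges twin
labels into summary classes; accuracy can only rise under any such
many-to-one relabeling.

## 6. Synthetic scene generator

Scope: a dependency-free stand-in for scene-camera video that preserves
the properties the pipeline is sensitive to, not a photorealistic
renderer.

* **Scene**: 480×360 canvas (a deliberate desk-scale choice; all sizes
  are configuration), 7 AOIs = 1 single + 3 twin pairs. Twins share one
  texture and sit on the left/right flanks — the generator's model of
  the hardest real-world confusion. Textures are flat color + Gaussian
  noise (σ = 8) + optional stripe/checker pattern; a `similarity` dial
  pulls non-twin textures together.
* **Rendering**: the noise field is a function of the seed only; a
  per-frame jitter offset (≤ 2 px) simulates head movement, so zero
  jitter yields identical frames.
* **Fixation streams**: geometric dwell runs (mean 3) alternate between
  background and AOIs so multi-fixation dwells exist; background share
  0.6; durations uniform 200–400 ms; background points stay ≥ 8 px from
  any AOI so ground truth is unambiguous. Every label agrees with the
  point-in-region oracle by construction.
* **Benchmark**: pool of 10 interior patches per class, task stream of
  870 fixations tagged into phases (646 + 224), disjoint held-out
  evaluation stream, patch size 32 at this scene scale. Archives are
  plain files (`frames/*.png`, `fixations.csv`, `labels.csv`,
  `pool/<class>/*.png`, `scene.json`) and byte-reproducible from the
  seed; fixation CSVs round-trip floats exactly (`repr` on write,
  `float_precision="round_trip"` on read).

Non-goals: saccade dynamics, smooth pursuit, camera distortion.

## 7. Limitations

* The backbone is intentionally small; it resolves distinct textures
  easily but twins only via their (jittered) surroundings, so absolute
  accuracies on the synthetic study should be read as pipeline checks,
  not vision benchmarks.
* With the conservative refit recipe (30 epochs, lr 1e-4) the backbone
  stays close to its random initialization, so background-rejection
  quality inherits the luck of the init draw: across init seeds on one
  benchmark the fraction of background fixations scoring above the 0.4
  threshold ranged from under 1% to over 80%. Study results should
  therefore be aggregated over seeds, as the test suite does.
* Retraining is synchronous in the simulated session; the asynchronous
  path (launch / coalesce / swap) is exercised with stub trainers.
* The simulated annotator always answers correctly; annotator noise and
  inter-rater disagreement enter only through the reliability metrics,
  not the session loop.
* Background rejection depends on calibrated probabilities; thresholds
  other than the 0.4/0.4 defaults may suit other backbones or scenes,
  and the sweep tooling exists to choose them.
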