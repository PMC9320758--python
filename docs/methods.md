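# Methods

## Problem and model

Screening mammography produces four images per examination: craniocaudal
(CC) and mediolateral-oblique (MLO) projections of the left and right
breasts (LCC, RCC, LMLO, RMLO). Radiologists read the four together,
because malignancy shows up *relationally*: a real mass appears in both
ipsilateral views of one breast, and a malignant case is typically
asymmetric between the two breasts, whereas benign anatomy tends to be
bilaterally similar. The four views are never registered to each other.

`mvtmammo` implements a multi-view vision transformer (MVT) that ingests
the four unregistered views directly:

1. **Shared embeddings.** Each 224×224×3 view is cut into P×P patches
   (P = 16, so N = 196 patches) and projected to d_embed dimensions by a
   single patch projection E (a conv with kernel = stride = P, expressed
   here as a linear map on flattened patches). One learnable class token
   x_class is prepended and one learnable position table E_pos (N+1 rows)
   is added. E, x_class and E_pos are one copy shared by all four views.
2. **Local blocks.** L_local standard pre-LN transformer blocks
   (z̃ = MSA(LN(z)) + z; z' = MLP(LN(z̃)) + z̃, GELU MLP with expansion
   ratio r = 4) are applied to each view's sequence independently, with
   the *same* weights for all views. They model within-image patch
   relations.
3. **Global blocks.** The four output sequences are concatenated in the
   fixed order LCC, RCC, LMLO, RMLO into one sequence of length 4N+4, and
   L_global identical blocks attend over it jointly, modelling bilateral
   and ipsilateral relations. L_local + L_global = 12 in the `tiny`
   (d = 192, h = 3) and `small` (d = 384, h = 6) presets, which carry
   5.5 M and 21.7 M trainable parameters respectively.
4. **Head.** The class-token representation of the last global block
   (after a final layer norm) feeds a one-layer head with two outputs
   (benign / malignant). A case is called malignant when its softmax
   probability strictly exceeds the benign probability; ties go to
   benign.

Because local and global blocks are architecturally identical to a
single-stack ViT/DeiT of the same total depth, the parameter count is
invariant to the L_local/L_global split, and a standard DeiT checkpoint
imports directly: source blocks 0..L_local−1 become the local stack, the
remainder the global stack, embeddings map one-to-one and the head is
re-initialized for two classes.

### Head-token choice

After concatenation the sequence contains four class-token slots (one per
view). The default readout is position 0 (the LCC-slot token), the
conventional choice; `head_token="mean"` averages the four slots. With
L_global = 0 the views never mix, so the mean is forced — it is the
minimal symmetric fusion rule.

No view-identity embedding is added after concatenation: views are
distinguishable only by content (and by their shared position table
repeating four times). This mirrors the sharing of x_class/E_pos across
views and keeps checkpoints import-compatible.

## Numerical core

No GPU framework is assumed: the forward and backward passes run on a
small reverse-mode autodiff engine over float32 numpy arrays
(`mvtmammo._tensor`). The softmax and log-softmax subtract a detached row
maximum (gradient-exact, numerically stable); GELU uses the exact
erf form; layer norm uses ε = 1e-6. Gradients of the composed block are
validated against central finite differences in the test suite, and the
vectorized multi-head attention against a per-head, per-query loop
oracle, both at tolerance 1e-5 (float32; bit equality is never asserted
across platforms).

Training uses AdamW (β = 0.9/0.999, decoupled weight decay 0.05 on
matrices only) with cosine decay and linear warmup. The default base
learning rate follows the batch-scaled transformer-finetuning rule
5e-4 × batch/512 with batch 8 and 500 epochs; these defaults describe
the full-scale protocol, while the desk-scale experiments below pass an
absolute rate (1e-3) because the batch-scaled rule collapses to ~8e-6 at
batch 8, far too small for from-scratch toy training.

## Preprocessing

Raw views are 12-bit (4096-level) grids at 70 μm pitch, in two canvas
sizes (2558×3327 and 3327×4091). The pipeline: (i) pixel-average
subsampling with a 5×5 kernel — edge windows are truncated and output
dims are ⌈H/5⌉×⌈W/5⌉, the only convention consistent with the target
sizes 512×666 and 666×819 — giving 0.35 mm pitch; (ii) fixed-range
normalization v ↦ v·255/4095 (not per-image min–max, to preserve
absolute intensity comparability across the four views, which the
bilateral signal relies on); (iii) duplication across three RGB channels;
(iv) direct anisotropic bilinear resize to 224×224 (no padding or
cropping; aspect ratio deliberately not preserved); (v) optional
per-channel ImageNet standardization, default on, matching a pretrained
backbone's input statistics. Whether stacking precedes resizing is
mathematically irrelevant; stacking-then-resize is used.

## Synthetic cohort

The generator emulates the *structure* of a private FFDM screening
cohort, not its appearance: four views per case, two canvas geometries,
12-bit intensities, and a cohort preset of 949 cases (470 malignant /
479 benign, 3796 images). Canvases default to 1/8 of native scale for
desk-scale work; full scale is a flag.

Each breast gets a smooth gaussian-blob texture rendered in a breast
coordinate system and projected per view (identity for CC, a 28° rotation
for MLO, horizontal mirroring for the right side), so ipsilateral views
of one breast are geometrically consistent. Every case carries exactly
one soft-edged elliptical focal finding per breast. Class structure:

* **benign** — left/right textures correlated (same blob geometry,
  amplitudes jittered by 15%); one finding contrast drawn from the
  mixture c ± g/2 (c ~ U(900, 1600), g ~ U(600, 1000), random sign) and
  used for *both* breasts at mirrored positions.
* **malignant** — textures drawn independently per breast; a lesion at
  contrast c + s·g/2 in a random breast (rendered consistently in its CC
  and MLO views, with ground-truth masks), and an independent distractor
  at contrast c − s·g/2 in the other breast.

Because both classes draw per-image finding contrasts from the identical
c ± g/2 mixture, and positions/shapes from identical marginals, *no
single image carries class information* — the test suite asserts that a
pixel-mean classifier on individual images stays within 0.5 ± 0.1 AUC.
The signal is strictly relational (bilateral contrast gap, position
mismatch, texture decorrelation), which is the property the global
blocks exist to exploit. What the generator does **not** emulate:
anatomy (skin line, pectoral muscle, density gradings),
microcalcifications, scanner artifacts. Passing desk-scale tests
therefore demonstrates that the architecture can learn cross-view
relational signals end-to-end — not that it reaches any particular
clinical accuracy.

Randomness is keyed by numpy SeedSequences on (seed, case_index) and
(seed, case_index, view), so any case regenerates bit-identically in
isolation.

## Evaluation protocol

Stratified five-fold cross-validation at case level (all four views of a
case share a fold; per-class fold counts differ by ≤ 1; fold seed
defaults to 20220625). Per fold: confusion matrix under the strict
p(malignant) > 0.5 rule, then accuracy, precision, recall, specificity
and F1 (undefined ratios are NaN with a warning, never silent zeros).
Fold accuracies are summarized by their mean and *both* spread variants —
population (÷n) and sample (÷n−1) — because fold tables in the
literature are conventionally printed with the sample form; the sweep
report uses the sample variant. AUC is the empirical Mann-Whitney /
trapezoidal area (ties = 1/2), with fold-to-fold dispersion reported;
maximum-likelihood binormal ROC fitting (and its p-values) is a
different methodology and is intentionally out of scope. The block-sweep
harness evaluates every (L_local, L_global) split over one shared fold
assignment and renders columns by descending L_global.

## Desk-scale experiment sizes

All tests run on one CPU. The overfit sanity check trains the `toy`
preset (d = 32, h = 2, depth 4 split 1 local / 3 global, 32×32 inputs,
8×8 patches) on 16 cases for 200 epochs at lr 1e-3 and must reach 100%
training accuracy. The fusion-benefit experiment uses 400 cases at 1/8
scale per seed and an 80/20 stratified split; both arms share the toy
core widened to d = 48 with 3 heads and train for 60 epochs at lr 2e-3
(10 warmup epochs, batch 8). The width and learning rate were chosen so
that from-scratch training escapes its early loss plateau reliably
across seeds; the narrower d = 32 core learns the same task but takes
off only for some initializations. The single-image ablation is the same
core with n_views = 1, trained on each view with its case label (so it
sees four times as many samples per epoch under identical
hyperparameters); its case score is the mean of the four per-view
probabilities. The four-view model must win in held-out AUC for every
seed. These sizes are the package's chosen desk-scale study conditions;
clinical-scale magnitudes require the private cohort and are not
reproduced.

## Known limitations

* The relational difficulty of the synthetic task is tuned for
  learnability by a 4-block, 32-dimensional toy model; it is far easier
  than real mammographic malignancy classification.
* From-scratch training of small transformers on small relational tasks
  exhibits a takeoff plateau; runs that matter should use the documented
  learning-rate settings or a pretrained checkpoint.
* The engine is CPU-only float32 and unoptimized for large models; the
  tiny/small presets are instantiable (for counting, import and
  inference) but full 500-epoch training at 224×224 is outside its
  intended envelope.
* `n_views` supports only 1 and 4; two-view (single-side) variants are
  not implemented.
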