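# Methods

## Problem and model

`adaptaug` learns an image-conditional augmentation policy for binary
segmentation of rust spots on leaves. The decision process is a finite-horizon
MDP. A state is the 12-vector of geometric and pixel indicators of one image
(leaf centroid x, y; leaf area; leaf mean R, G, B; the same six for the rust
region), all normalized to [0, 1]: centroids by image width/height minus one,
area by pixel count, colours by 255. An empty region (e.g. a spot-free leaf)
contributes all-zero features; the normalization keeps the Q-network's input
well-scaled regardless of image resolution. The action set is eight classical
augmentations (identity; vertical, horizontal and double flip; 30° clockwise
rotation; shear x′ = x + 0.2 y; crop of the first 25 rows and columns with
resize back; additive Gaussian noise). The reward of a step is 100 times the
change of the Dice ratio d = (2/n) Σ P_IoU of a segmentation model that is
restored from its pre-trained snapshot and fine-tuned on the union of the
original training images and the current augmented vector, evaluated on a
fixed test set. Within an episode the augmented vector is cumulative — step t
augments the already-augmented images of step t−1 — and at episode reset the
original vector and the pre-trained Dice are restored. Because each step
restores the same snapshot, d_t is a function of the current retrain set only,
and the per-step rewards telescope: their episode sum is 100 (d_T − d_0).

Replay transitions are stored per image: the Q-function scores a single
image's state against the eight actions, so each step of an m-image vector
contributes m transitions that share the step's scalar reward (uniform credit
assignment; only a step-level reward exists). The TD loss is the squared
error [r + γ max_a Q₂(s′, a) − Q₁(s, a)]², averaged over a uniformly sampled
batch; gradients reach Q₁ only, and Q₂ is a bit-exact copy of Q₁ refreshed
every C gradient updates. γ defaults to 1.0, matching a loss stated without a
discount; the horizon cutoff at episode end is not treated as an absorbing
state. Ties in the greedy argmax break to the lowest action id.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| episode length T | 3 steps | the reported per-step (≈3.16 min) and per-episode (≈9.48 min) wall times of the GPU-scale study imply three steps |
| split rounding | round-half-up | 438 images at 0.2 → 88 test, 350 train |
| Q-network | 12→64→64→8, ReLU, He init | smallest standard shape for 12 features |
| agent learning rate | 1e-2 (Adam) | desk scale performs one gradient update per environment step, so only L·T updates happen in total; a conventional 1e-3 leaves the network untrained at that budget |
| target sync period C | 5 gradient updates | same budget argument |
| replay capacity / batch | 10 000 / 64 | conventional |
| ε schedule | linear 1.0 → 0.05 over the first half of training | standard |
| noise σ (action 7) | 35 (8-bit scale) | must exceed the generator's per-pixel jitter (±30) to change the colour statistics a pixel classifier sees; a small σ makes the action an exact no-op for such a model |
| fine-tune | 15 epochs at rate 0.8 | "fast fine-tuning": strong enough that the retrain-set composition moves the model measurably, cheap enough for seconds-per-episode |
| surrogate pre-train | 300 epochs at rate 2.0 | trains to convergence, so fine-tuning on an un-augmented duplicate of the training set is reward-neutral — rewards then measure augmentation, not leftover training |
| dice factor | 2 | the Dice ratio is implemented literally as 2× the mean per-image IoU, so d ∈ [0, 2]; the reward uses differences only, so the factor rescales rewards uniformly. Configurable (`dice_factor`) |

All segmentation metrics define 0/0 terms as 1 (an absent class predicted
absent is a perfect prediction); this keeps every index defined on spot-free
images. Both pooled (confusion counts summed over the test set) and per-image
(mean IoU inside the Dice ratio) aggregations are reported, labelled
distinctly.

## The synthetic data generator

Each scene is one elliptical leaf (random centre, axes 0.28–0.45 of the image
side, orientation) on a darker background, with 0–4 rust spots rendered as
discs of radius 1.5–4 px fully inside the leaf; the masks are exact. Colour
is hierarchical: region base hues (leaf green, rust orange-red, dark
background) receive a per-image offset uniform in ±45 per channel (scene
lighting / variety variation) and a per-pixel jitter uniform in ±30
(texture). These ranges are deliberately wide: with them the default
surrogate reaches a mean test IoU around 0.85–0.95 rather than 1.0, so
fine-tuning on augmented data has measurable effect in both directions, which
is the regime the framework is about. Images default to 64×64 for desk-scale
runs; 512×512 mirrors field imagery. One root seed spawns an independent
stream per image, so generation is order-independent and bit-reproducible.

What the generator does *not* emulate: real leaf shape and venation, multiple
leaves or occlusion, illumination gradients within an image, lesion texture
and staged disease progression, camera noise and compression. Consequently,
passing desk-scale results demonstrate that the framework's mechanics work —
per-image action selection, reward propagation, learning of state-dependent
rules — not that any particular augmentation ranking transfers to real rust
photographs.

## The surrogate segmentation backend

The default backend is a pixel-wise logistic classifier over the 9 quadratic
colour features (r, g, b, r², g², b², rg, rb, gb), trained by full-batch
gradient descent on a class-balanced pixel sample (up to 256 pixels per class
per image). It is deliberately minimal: deterministic under a seed,
millisecond-scale to fine-tune, and sensitive to exactly the statistics the
augmentation actions change (colour distributions, interpolation blends,
noise). Snapshots are versioned JSON blobs carrying the backend name and
hex-encoded float64 parameters, so restore is bit-exact and artifacts stay
text-friendly; restore refuses a mismatched backend name. A `deeplabv3plus`
backend name is registered as an adapter slot but intentionally not
implemented — heavy encoder–decoder networks are outside this package's
scope, and any object honouring the pretrain / snapshot / restore / finetune
/ predict / evaluate contract can replace the surrogate.

A known consequence of a colour-statistics model: augmentations that permute
pixels (flips, identity) cannot change what it learns, so their rewards are
exactly zero once pre-training has converged; rotation, shear and crop help
through interpolation blends that broaden the colour distributions, and noise
hurts. The learning problem the agent faces at desk scale is therefore
primarily to prefer resampling actions and avoid noise — a coarser task than
with a spatial model, but one with an unambiguous ground truth.

## The planted-rule control

Because the real environment's reward surface is a property of the backend,
the agent machinery is additionally validated on a contextual bandit with a
known optimum: states are genuine 12-feature states of generated images, but
the reward is +1/−1 for matching a planted rule ("action 1 if the rust
centroid is in the top half, else action 2"). The canonical experiment uses a
pool of 200 states, 96 episodes of 50 single-state steps (4 800 transitions),
γ = 0 (rewards are history-free), batch 128, and scores the final greedy
policy on 40 held-out states. Accuracy ≥ 0.9 demonstrates state-conditional
learning end to end.

## Numerical and design choices

- Geometry: x = column, y = row, origin top-left. The shear matrix is the
  forward map, applied about the origin; rotation is about the exact image
  centre ((W−1)/2, (H−1)/2); output pixels are found by inverse mapping.
  Images resample bilinearly, masks with nearest neighbour (preserving the
  {0,1} alphabet); out-of-frame regions fill with 0 in image and masks.
- Crop semantics: delete rows and columns 0–24, resize the remainder back to
  the original size (bilinear image / nearest-neighbour masks).
- The noise generator stream is derived from (environment seed, episode,
  step), so runs are reproducible while noise varies across steps.
- A fine-tune with 0 epochs is a defined no-op returning an unchanged model;
  this makes the all-identity step's reward exactly zero under a frozen
  fine-tune, a useful environment sanity check.
- Non-finite rewards abort training with an error rather than being logged
  and skipped.
- One global seed fans out via named SeedSequence-derived sub-seeds (data,
  split, pretrain, env, agent, baseline); every CLI run writes its resolved
  configuration next to its outputs.

## Known limitations

- The 12-feature state cannot express augmentation history (e.g. how many
  times an image has already been rotated), so cumulative-degradation effects
  are only partially observable; with the small step budget (L·T = 30 update
  steps in the desk-scale loop) the learned policy is closer to a
  state-modulated action ranking than to a deep sequential strategy, and the
  reward-trend outcome varies with the data seed.
- The step reward is shared by all images of a vector, so per-image credit
  assignment is statistical, emerging only across many steps.
- The Dice ratio on a small test set is coarsely quantized; the desk-scale
  experiments use 5–20 test images and inherit that granularity.
- Single-class (rust vs background) segmentation only; the leaf target is
  supported by every backend operation but unused in the reward loop.
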