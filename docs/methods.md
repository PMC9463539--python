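# Methods

`readernet` studies a question that arises whenever a medical-imaging
dataset is labelled by a panel of human readers: is it better to train a
classifier on the panel's *final* (adjudicated) label, or to train it to
predict *each reader's* annotation and aggregate the per-reader
predictions at inference time?  The package implements both strategies
around a shared convolutional trunk, a simulator that generates
panel-annotated radiograph-like data with known ground truth, and the
machinery (training, evaluation, saliency, hyper-parameter search) to
compare them end to end.

## The classifier

Both variants share the trunk

    image -> convolutional backbone -> global average pooling (GAP)
          -> dropout -> linear layer -> softmax over 5 classes

The GAP output `h ∈ R^D` is the *image embedding*.  The reader-embedding
variant additionally maps a reader index `r` through an entity-embedding
table `E ∈ R^{n_readers × 32}`, an affine projection `R^32 -> R^D`, and an
activation `σ`, producing a *modulation vector* `m_r = σ(W E_r + b)`.  The
classifier then operates on the element-wise product `h ⊙ m_r`: each
reader re-weights the image features before the shared softmax head.  With
`σ = identity`, `W = 0`, `b = 1` the modulation is all ones and the model
is *exactly* the baseline — a property the test suite asserts to 1e-6.

The activation choice is scientifically meaningful: ReLU and sigmoid keep
`m_r ≥ 0`, so the direction of association between an image feature and a
class is shared by all readers; identity and tanh let readers flip signs.

Classes follow a fixed canonical order (consolidation, other infiltrate,
both, normal, uninterpretable) used for confusion-matrix axes, softmax
outputs and argmax tie-breaks (ties go to the lowest index).

Backbones: `TOY_CNN` (three stride-2 conv–BatchNorm–ReLU blocks, default
widths 8/16/32, so a 64×64 input yields an 8×8 final feature map and
D = 32) is the desk-scale workhorse; ResNet-18/34/50 are available at
D = 512/512/2048 with He-initialized weights.  All layers, backprop, and
SGD-with-momentum (0.9) are implemented in NumPy; gradients of every layer
are verified against central finite differences in the test suite.

Initialization of the reader branch: the projection bias starts at 1 and
the table rows at Gaussian noise with σ = 0.1 (projection weights
σ ≈ 0.05), so training starts near the baseline-equivalent point.  The
scale matters: the branch is a product of two small factors, and with both
near zero its gradients vanish quadratically — at desk scale (30 epochs) a
σ = 0.01 start leaves readers undifferentiated, while σ = 0.1 escapes the
saddle without measurably perturbing the starting point.

## Training

- `FINAL_LABEL` target (baseline): every training image is paired with its
  arbitrated final label.
- `READER_LABEL` target: each epoch samples, per image, one annotation
  uniformly among all of that image's records (initial, arbitration,
  consensus, QC) and feeds `(image, reader, label)`.  Both variants thus
  perform identical numbers of weight updates per epoch.

Optimizer: SGD with momentum 0.9, per-parameter-group learning rates and
coupled L2 weight decay (groups: convolutional trunk, classifier head,
reader projection, embedding table; the table gets no weight decay — the
max-norm constraint bounds it instead, by projecting rows onto the L2 ball
after every step).  The learning rate is halved at epochs 50 and 100.
Desk defaults (chosen by desk-scale search, the package's analogue of a
tuned configuration): lr 0.05 (trunk/head/projection), 0.3 (table), weight
decay 1e-4, dropout 0.1 on the (modulated) embedding before the head,
max-norm 4, batch 32.

Augmentation: random resized crop (area 0.6–1.0, toy profile 0.7–1.0),
horizontal flip (p = 0.5), optional rotation/shear and brightness/contrast
jitter applied with probabilities `p_affine`/`p_color` (desk default 0.3),
channel replication and per-channel normalization.  The full-scale profile
resizes to 300×300 and crops 224×224 with ImageNet statistics; the toy
profile stays at the native 64×64 with mean 0.5 / std 0.25.

Validation: a fold of 20% of *training* patients (the test split is never
touched).  Both variants are scored against final labels so their curves
are comparable epoch by epoch; the reader-label model predicts
conditionally on a fixed per-image reader sampled once from the image's
annotators, so its curve reflects the noisier per-reader task — the
training-time cost the aggregation later repays.

## Inference

A reader-embedding model produces one probability vector per reader —
every reader, including those who never saw the image — and the final
prediction is the unweighted column mean of those rows (learned
aggregation weights are deliberately out of scope).  The mean of simplex
rows stays on the simplex; aggregation is permutation-invariant.

## The panel simulator

Images (64×64 by default, any size ≥ 32): a bright thorax with two darker
elliptical lung fields plus pixel noise.  Consolidation adds one dense
bright elliptical lesion (radius 0.11–0.15 × image size — lobar scale; at
much smaller radii the lesion contributes so little to the
globally-averaged features that no GAP-headed classifier can detect it,
and the class would be unseparable by construction); other infiltrate adds
diffuse smoothed texture across the lung fields; both adds both; normal
neither; uninterpretable applies heavy blur, contrast collapse and
occluding bands.  The lesion and lung-field masks are returned with the
image and serve as ground-truth regions of interest for saliency scoring.

Class prevalence defaults to (0.15, 0.24, 0.11, 0.40, 0.10).  Patients get
a site (default seven country-coded sites; optionally the last two receive
a ~30% lower NORMAL share, to support grouped-accuracy analyses) and an
age drawn uniformly from 1–60 months; ~4% of patients contribute a second
image, and splits are by patient so both images stay on one side.

Readers are confusion matrices: `confusion[t][o]` is the probability of
reporting `o` given truth `t`.  Each reader has one Dirichlet-drawn
(α = 0.25) *bias direction* governing where its error mass goes; within a
generated panel the directions are kept nearly orthogonal (pairwise cosine
≤ 0.1), so readers err in characteristic, mutually distinguishable ways —
the situation multi-site panels actually exhibit (site-specific
sensitivity/specificity patterns).  Per-class diagonal accuracies are
drawn from 0.40–0.74 for initial readers and 0.59–0.77 for arbitrators,
matching the reported accuracy ranges of first-line readers and
experienced adjudicators in large paediatric CXR panels.  The two initial
readers of a site share a site-level skill band (±0.06) but keep their
contrasting biases.  The low end of the initial range matters: readers
below ~0.5 have confusion rows that are *not* diagonal-dominant, so
conditioning on such a reader genuinely costs accuracy against final
labels — the mechanism behind the reader-label model's lower validation
accuracy during training.

Age effect: off-diagonal mass is scaled by `max(0.3, 1 − slope·age/120)`
and the freed mass returned to the diagonal, so agreement improves
monotonically with patient age.

Arbitration: two initial readers per image (the site's pair).  Concordant
reads stand (with a 10% quality-control re-read by a random arbitrator
that never changes the label).  Discordant reads go to two distinct
randomly chosen arbitrators; if they also disagree, the consensus
discussion is simulated as a single draw from the average of the two
arbitrators' age-adjusted rows — the simplest stochastic surrogate for a
human discussion — recorded as a CONSENSUS annotation for each of the two
arbitrators (and usable as ordinary reader labels in training).  All
randomness flows through per-image substreams of a root seed, so datasets
are bit-reproducible.

## Evaluation

Multi-class accuracy; one-vs-rest AUC per class with midrank tie handling
(`P(score+ > score−) + 0.5·P(tie)`), undefined classes reported as NaN and
excluded from the unweighted mean with a warning; row-proportion confusion
matrices (empty rows all-zero); grouped accuracy by site and by age bins
(default split at 12 months).  AUC is checked exactly against an
exhaustive pairwise oracle and against an independent reference
implementation.

Grad-CAM: because the head is GAP → (modulation) → linear, the gradient of
a class logit with respect to the final feature map is spatially constant
and the channel weights are `W[c] ⊙ m_r / (hw)`; the rectified weighted
channel sum is bilinearly upsampled to the input grid and max-normalized
(all-zero maps stay zero).  Localization is scored against the generator's
lesion masks: mean heat inside vs outside.

Reader identifiability: to ask whether the conditional streams carry
reader identity, we pick the same-site initial pair maximizing the smaller
of the two directed Bayes margins `Σ_t π_t r_a[t]·(r_a[t] − r_b[t])`
(positive margins in both directions are required for the readers to be
distinguishable from labels at all — readers differing mainly in accuracy
have one negative margin), restrict to shared held-out images where the
two readers *disagreed* (concordant reads carry only truth-confidence, no
reader-specific signal), and compare, on those same images, the
probability each stream assigns to the observed labels.  Same-site pairs
are essential: a stream is only row-faithful on image material it
trained on; on another site's images it extrapolates toward generic
behaviour.  Hard-argmax agreement is uninformative here — for
diagonal-dominant rows the Bayes-optimal conditional argmax is the truth
regardless of reader.

## Hyper-parameter search

Synchronous successive halving over random draws (log-uniform learning
rates and weight decays, uniform dropout/augmentation proportions,
categorical batch size, activation and max-norm): all `n` samples train to
the first rung, the top `1/η` by validation accuracy are promoted through
rungs (default 10/20/40/80 epochs, η = 2), survivors of the last rung
train to the full budget, ties break by earlier-rung metric then draw
order, and failed trials are excluded.  Trials resume rather than restart,
so total epoch consumption is exactly accountable (asserted in tests).
The synchronous variant replaces asynchronous scheduling deliberately:
determinism and exact accounting matter more at desk scale than cluster
throughput.  Desk profile: 16 samples, rungs 2/4/8, budget 12; the
full-scale profile (300 samples, rungs 10/20/40/80, budget 150) is a named
preset.

## The desk experiment

`readernet.experiments.run_desk_trial(seed)` is the standard comparison:
1,440 patients (≈1,500 images, 64×64), six initial readers + two
arbitrators with the confusion model above, uniform site priors, 20%
patient-level test split, both variants trained 30 epochs with the desk
defaults, identical training seeds.  Reported per trial: both test
accuracies and mean AUCs, per-reader-conditional accuracies, full
validation curves, the identifiability report, and Grad-CAM localization
over correctly classified consolidation images.  These problem sizes are
the package's desk-scale operating point: large enough for the directional
claims to be stable over seeds, small enough to iterate on a single CPU.

## What the synthetic data does and does not show

The simulator reproduces the *structure* of a multi-reader study — class
mix, heterogeneous biased readers, age-dependent agreement, site pairing,
arbitration and its selection effects — with image classes that a small
CNN can learn almost perfectly.  Consequently both model variants sit near
the ceiling set by final-label noise, and the experiment demonstrates the
*relationships* (aggregation ≥ individual streams; reader-label training
costs validation accuracy but aggregation repays it; streams carry reader
identity; saliency lands on the lesion), not the absolute accuracy levels
of real radiographs, where image ambiguity, acquisition variation between
sites, and anatomy make the image-recognition task itself hard.  Transfer
of the directional conclusions to real data therefore rests on the reader
model (confusion matrices), which is the component the simulation controls
exactly.

## Numerical choices and degenerate inputs

- float32 throughout the network; probability/statistics code in float64.
- Softmax is max-shifted; cross-entropy clips probabilities at 1e-12.
- BatchNorm eps 1e-5, running-stat momentum 0.1; batch variance computed
  in one pass and floored at 0.
- Argmax ties break to the lowest class index everywhere.
- Empty confusion rows and degenerate AUC classes are reported, not
  errors; an all-zero Grad-CAM map stays zero rather than normalizing.
- Non-finite training loss aborts with the epoch and step in the message.
- Confusion rows must sum to 1 within 1e-9; embedding-row norms are
  re-projected after every optimizer step when a max-norm is set.

## Known limitations

- No GPU path; residual backbones run but are impractical to train here.
- No pretrained backbone weights; `TOY_CNN` results do not speak to
  transfer-learning effects.
- The consensus-discussion surrogate (mean of two confusion rows) ignores
  persuasion dynamics; QC reads are assumed never to overturn a label.
- Unweighted-mean aggregation only; learned (stacked) weights are out of
  scope by design.
- Intra-reader variability is implicit (independent draws per read), not
  modelled as drift over time.
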