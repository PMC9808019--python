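# Methods

`duomil` implements a weakly supervised pipeline for classifying
duodenal-biopsy whole-slide images (WSIs) as *normal* or *coeliac disease*.
Only slide-level diagnoses are assumed to exist; the pipeline learns
patch-level evidence through multiple-instance learning (MIL) and maps patch
predictions back to slide decisions and localisation heatmaps. This note
records the model, its assumptions, the parameters that matter, and the
design choices made where the design was genuinely open.

## Preprocessing

**Tiling.** Slides are processed at a working resolution of roughly
10 µm/pixel. A sliding window enumerates 256 × 256 tiles at stride 128
(row-major); edge remainders that cannot hold a full tile are dropped, so
every patch entering the model has identical geometry. Foreground detection
uses Otsu's threshold on an 8-bit luminance histogram
(0.299 R + 0.587 G + 0.114 B) of a thumbnail block-averaged by the stride;
background is the class *brighter* than the threshold (H&E background is
white). One global threshold is computed per slide rather than per tile:
near-empty tiles do not contain enough signal to support a stable per-tile
threshold. A tile is kept when at most 75% of its pixels are background
(the rule is inclusive at exactly 75%, because only tiles with *more than*
75% background are discarded). `compute_otsu` is an exhaustive, vectorised
search over all 256 split points with ties resolved to the lowest level, so
it is deterministic and exactly reproducible.

**Stain normalisation (Macenko).** Colour formation is modelled by
Beer–Lambert: optical density `od = -log10(I / I0)` is linear in the two
stain concentrations, `od = M c`, with `M` a 3 × 2 matrix of unit OD
columns (haematoxylin, then eosin) and `c ≥ 0`. The basis of an image is
estimated by discarding pixels with OD magnitude below 0.15, taking the
top-2 right singular vectors of the remaining OD cloud, and reading the
stain directions off the 1st/99th percentiles of the projection angle in
that plane; the haematoxylin column is identified as the one with the
larger blue-channel OD component. Robust per-stain maxima are the 99th
percentile of the unmixed concentrations. Constants (white point 255,
OD cut-off 0.15, angle percentile 1, concentration percentile 99) are the
conventional Macenko defaults, exposed in `StainNormConfig`. A pixel
subsample cap (deterministic grid subsampling) bounds the SVD cost; it is a
runtime knob, not a statistical parameter.

Normalisation re-renders concentrations through a fixed reference basis
(`REFERENCE_PROFILE`): the classical H&E OD vectors with concentration
maxima frozen to match the synthetic generator's canonical rendering
regime. The estimation granularity matters and was a genuinely open design
point; weak supervision makes it surprisingly delicate, because any
normalisation statistic correlated with the diagnosis becomes a shortcut a
MIL learner will exploit. Three granularities are implemented, and
full-scale experiments motivated the default:

* **per-source** (cohort default): one profile estimated from pixels
  pooled over every slide sharing a manifest source (scanner) tag. This
  is the most stable estimate of exactly the thing normalisation exists to
  remove — scanner-level colour drift — it applies one identical linear
  map to all slides of a source (so any unmixing distortion is shared,
  preserving between-slide comparability), and source pools contain both
  classes, so the robust maxima used for rescaling carry no label
  information.
* **per-slide**: one profile per slide, applied with *basis correction
  only*. A slide's robust concentration maxima are shifted by disease
  itself — dense nuclear dots raise the slide-wide haematoxylin
  percentile — so rescaling by them renders the lesion-free tissue of
  positive slides systematically paler than normal slides' tissue,
  imprinting the slide label onto every tile; in experiments this produced
  perfect slide classification with systematically *inverted*
  localisation. Basis-only correction avoids the leak; residual per-slide
  estimation noise remains the cost of this mode.
* **per-patch** (the conventional formulation): independent estimation and
  rescaling per tile. Rescaling every tile to the same robust maxima
  equalises — and on dot-dense lesion tiles inverts — the between-tile
  haematoxylin contrast the MIL ranking feeds on; it destroyed
  within-slide localisation while leaving slide-level AUC deceptively
  high.

A related negative result: per-slide *feature* standardisation (centering
each slide's tile features) is not label-neutral either — after
centering, a nucleus-dense tile of a normal slide deviates from its slide
mean the way a lesion tile deviates within a positive slide, and the class
signal collapses. Absolute, consistently rendered features are the signal
here.

Known estimation bias: the percentile angle extremes sit slightly inside
the true stain wedge, so stain vectors are recovered to well under 2° but
not exactly; re-normalising an image already in the reference basis moves
near-pure, high-concentration pixels by a few grey levels (bulk of pixels
within ±2, mean ≈ 1).

## Multiple-instance training

Each training step visits one slide: a bag of `B = 100` tile indices is
drawn uniformly *with replacement* from the slide's kept tiles, the model
infers two sigmoid head probabilities (normal, coeliac) per patch, and
proxy labels are manufactured from the slide diagnosis:

* normal slide — every patch is labelled `(1, 0)` and active;
* coeliac slide — patches are ranked by the *normal*-head probability
  ascending (ties broken by bag index); the `α = 10` least-normal get
  `(0, 1)`, the `β = 0` most-normal get `(1, 0)`, and all other patches are
  masked out of the loss entirely, so exactly zero gradient flows from
  them (asserted by finite differences in the tests).

The loss is binary cross-entropy with logits averaged over active label
entries. One Adam step is taken per slide visit (learning rate 1e-4,
weight decay 1e-4 added to the gradient, β = (0.9, 0.999), ε = 1e-8);
training runs 10 epochs, each visiting all slides in a fresh shuffled
order with a fresh bag per slide. Everything is driven by a single seed
and is bit-for-bit reproducible on CPU.

"Least normal" could alternatively mean ranking by the coeliac head
descending; the two agree only when the heads are anticorrelated. Ranking
on the normal head was chosen because the phrase names the normal axis;
this is recorded as an open interpretation, not an established fact.

## The patch classifier

The trainable backbone is deliberately small so the full pipeline trains
from random initialisation on one CPU in minutes. Each 256 × 256 RGB patch
is reduced to a 32 × 32 × 4 feature map — per-8×8-block mean R, G, B
(stain/colour signal) and block grey-level standard deviation
(high-frequency texture such as dense nuclear dots) — followed by three
3×3 conv blocks (8, 16, 32 channels, ReLU, 2×2 max pool), global average
pooling and a dense layer to 2 logits. Convolutions, pooling, backprop and
Adam are implemented in numpy; gradients are verified against finite
differences in the test suite.

Two head details are load-bearing given the small fixed learning rate and
short schedule:

* the logit head is **zero-initialised**, so every freshly initialised
  model starts at probability exactly 0.5 on both heads — scores from
  models trained in different CV folds are calibrated identically at the
  start, which keeps pooled cross-fold score comparisons meaningful;
* the head output is multiplied by a fixed, non-trainable **gain**
  (default 100). Adam's update moves each weight by at most roughly the
  learning rate per step, so with lr = 1e-4 and a few hundred slide visits
  the reachable weight displacement is ~0.05; the gain maps that reachable
  ball onto the full logit range so the sigmoid can saturate within the
  training budget. This is an architectural scale choice, equivalent to a
  temperature, not an optimiser modification.

Any object with the same `prepare`/`forward`/`backward`/`parameters`
surface can replace `TinyConvNet`, e.g. an adapter around a large
pretrained backbone for real-scale runs.

## Slide-level evaluation

A slide's score per head is the arithmetic mean of its per-tile
probabilities over *all* kept tiles (no sampling at inference). Each class
is decided independently by a strict threshold on its own mean (defaults
0.905 normal / 0.096 coeliac); slides passing both or neither threshold are
reported as *discordant*, not resolved.

Threshold selection: the published rule reads "minimise the difference
between the true- and false-positive rates", which taken literally is
optimised on the chance diagonal of ROC space (TPR = FPR). The implemented
default is the sensitivity = specificity balance point — minimise
|TPR − TNR| over candidate thresholds (midpoints between consecutive
distinct scores plus infinite endpoints), averaged over CV folds when fold
ids are supplied, ties to the lowest candidate. The literal variant is
retained behind `rule="tpr-fpr"`.

ROC and PR curves and ROC AUC go through scikit-learn; PR AUC is the
trapezoid over the recall-ordered curve. The test suite cross-checks ROC
AUC against an independent pairwise Mann–Whitney oracle.

Cross-validation folds are assigned at the **case** level: all scans of a
patient sample share a fold. Cases are stratified by class, shuffled
within strata, and dealt round-robin with a running position, which keeps
per-fold class counts within one case of perfect stratification and fold
sizes balanced. Metrics with a zero denominator are reported as NaN with a
warning, never silently as 0.

## Heatmaps

Per-tile coeliac predictions are composited onto a raster downsampled 32×
(heatmaps are review aids; full resolution adds nothing): where
overlapping tiles disagree, the **maximum** prediction is displayed.
Regions covered by no kept tile carry an out-of-band sentinel (a mask
channel, not value 0) and render black, so "confidently normal" and "no
tissue" remain visually distinct. Compositing is order-independent.

## Synthetic cohorts

The generator emulates the coarse optical structure of H&E duodenal WSIs
at working resolution: bright background (mean grey ≥ 240), smooth tissue
blobs occupying 45–60% of the slide, concentrations rendered through the
canonical stain matrix rotated per "scanner" source by up to 10°
(emulating cross-scanner colour drift), and fine concentration speckle
plus sensor noise. Tissue carries cell-scale composition variation —
nucleus-dense, haematoxylin-dominated patches and eosin-dominated stromal
patches with identical statistics in both classes: real H&E spans the full
stain wedge this way, and Macenko estimation is only well-conditioned when
the wedge is spanned (an earlier all-pixels-one-blend tissue model made
per-slide basis estimates ill-conditioned). Positive slides contain **one
compact lesion** grown
around a random tissue point (a distance field modulated by smooth noise,
thresholded to a target fraction of the tissue drawn from [0.15, 0.5]);
inside the lesion the haematoxylin concentration is multiplied by 1.6 and
dense dark dots (radius 3 px, 2.5 × 10⁻³ per lesion pixel, amplitude 1.0)
emulate raised intra-epithelial lymphocyte density. The lesion is
deliberately compact so that every positive slide also contains clearly
lesion-free tissue — the localisation property is only well-posed when
both kinds of tile exist — and the signal is deliberately two-scale
(colour shift + texture) so both a hand-crafted statistic and a small CNN
can detect it. Slides of one case share tissue-shape statistics (blob
scale, coverage); one diagnosis per case.

`separability_check` certifies a cohort before any training: the sum of
z-scored mean haematoxylin concentration and z-scored block texture per
kept tile must separate majority-lesion tiles from normal-slide tiles
(ROC AUC ≥ 0.9 under defaults).

**What passing on synthetic data does and does not show.** The generator
reproduces the *pipeline-relevant* properties of real WSIs — weak labels,
per-scanner colour drift, background-dominated area, spatially localised
two-scale lesion signal, case grouping — so green tests demonstrate the
machinery (tiling, normalisation, MIL credit assignment, aggregation,
fold hygiene, localisation) is correct. It does not reproduce villous/
crypt morphology, scanner blur, pyramid I/O or the subtlety of borderline
histology, so nothing here is evidence of clinical performance.

## Problem sizes and numerical choices

The bundled end-to-end study uses 60 slides (30 normal / 30 coeliac,
30 cases, 3 sources) at 1536 × 1536 — 121 grid tiles per slide — with
5-fold case-grouped CV under the full training recipe; it completes in
roughly ten minutes on one CPU, and smaller cohorts are used for unit
tests. Degenerate inputs raise explicit errors: single-level histograms,
patches with no stainable tissue, rank-1 (single-stain) OD clouds, empty
bags, all-masked label sets, one-class ROC inputs, all-identical scores at
threshold selection, and manifests with fewer cases than folds. Slides
with no kept tiles are skipped with a warning at training time and yield
an all-sentinel heatmap at rendering time.

## Known limitations

* The numpy backbone is CPU-bound and small; it is not intended to match
  a pretrained ResNet50 on clinical data.
* Per-slide stain profiles assume a slide's staining is homogeneous;
  strongly heterogeneous slides would need regional profiles.
* The generator's lesions are geometric, not histological; transfer of
  measured numbers to clinical WSIs is out of scope.
* Blur/artefact quality control is not implemented.
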