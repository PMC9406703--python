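# Methods

## The model

The diagnostic question is binary: given one cystic lesion on a panoramic
radiograph, is it odontogenic (caused by dental pathology, e.g. a radicular
cyst around a tooth apex) or non-odontogenic? The pipeline answers it the
way a clinician reasons: locate the lesion, recognize the neighbouring
anatomy, and classify from the spatial relationship alone.

Formally, a lesion is an axis-aligned box *B* (0-based, half-open pixel
coordinates; areas are whole-pixel counts). Each anatomical structure *s* is
a binary mask *M_s*. The classifier input is the overlap-share vector

    x_s = |B ∩ M_s| / |B|,  s ∈ {maxilla, mandible, mandibular_canal,
                                  maxillary_sinus, dentition,
                                  tooth_11 … tooth_48},

37 ratios in a fixed order. Left/right canals and sinuses are merged into a
single mask each before the share is computed, so each contributes one
feature. The tooth block always has 32 slots in FDI order; an absent tooth
has an all-zero mask and hence a zero feature. Dentition is defined as the
union of the individual tooth masks, which gives the vector the invariant
`x_dentition ≥ max_t x_tooth_t` (enforced with tolerance 1e-9).

Classification is a Random Forest written from first principles: each of
`n_trees` trees is grown on a bootstrap resample of the training set; at
every node `m_try` features are drawn uniformly without replacement and the
split maximizing the Gini-impurity decrease is taken, with candidate
thresholds at midpoints between consecutive distinct feature values and ties
broken toward the lowest feature index, then the lowest threshold. A node
becomes a leaf when it is pure, smaller than `min_samples_split`, at
`max_depth`, or when no split has positive gain. Prediction is a majority
vote; an exact tie goes to the odontogenic class (the majority class in the
clinical case mix). Defaults: `n_trees=1000`, `m_try=floor(sqrt(37))=6`,
`min_samples_split=2`, unlimited depth. Hyperparameter tuning is an
exhaustive grid search (`n_trees` ∈ {100, 500, 1000} × `m_try` ∈ {3, 6, 12}
× `min_samples_split` ∈ {2, 5}) scored by 5-fold cross-validated macro-F1
with seeded fold assignment; the evaluation protocol is a stratified 80/20
split with `|train| = round(0.8 n)`.

## The synthetic scene generator

Only spatial-overlap topology matters downstream, so anatomy is drawn as a
parametric 2-D cartoon on a 512×256 grid (any size; the layout scales):
maxilla as a central upper band, mandible as a lower band plus two rami at
the image edges, two sinus ellipses inside the maxilla, two slanted canal
strips inside the mandible, and 32 teeth as crown-to-apex tapering
trapezoids along the occlusal plane, upper roots pointing up, lower roots
down. Image left is the patient's right, so the upper row runs FDI
18…11|21…28 and the lower 48…41|31…38.

The class structure is planted to operationalize the radiological
definitions: an odontogenic lesion is a box centered near a uniformly chosen
present tooth's apex (nudged toward the root) and accepted only if ≥10% of
its area lies over that tooth's mask; a non-odontogenic lesion is
rejection-sampled with its center in jaw bone or sinus and accepted only
with exactly zero overlap with every tooth mask. Placement failing its rule
within `max_attempts` (default 200) raises a placement error naming the
scene. On noise-free scenes the rule "odontogenic ⇔ any tooth share > 0" is
therefore exact — and, because dentition is the tooth union, the single
dentition feature separates the classes perfectly too. Passing tests on this
generator show the pipeline's mechanics are correct; they do not show that
real radiographs are this separable (real lesions are ambiguous precisely
when tooth involvement is unclear).

Demographics (age ≈ N(53.5, 16) clipped to 18–90; 41% female) mirror the
published cohort and exist only so annotation files round-trip. The default
scene mix is 37.5% lesion-carrying scenes (the published evaluation-set
prevalence) with a 72% odontogenic share among lesions (the published case
mix). Negative scenes flow through detection evaluation only; the
classification stage, like the original protocol, sees lesion-carrying
samples.

## Imperfection model

The simulated detector perturbs both box corners with i.i.d. Gaussian noise
(`jitter_sd`, default 3 px, clipped to the frame), drops each lesion with
probability `fn_rate` (default 0.1), and with probability `fp_rate` (default
0.1) adds one spurious box per scene. Confidences are Beta-distributed —
true positives Beta(8, 2), false positives Beta(2, 5) — so true detections
are stochastically more confident and threshold sweeps behave realistically.

The simulated segmenter degrades each mask to a target Dice by a
boundary-ordered pixel exchange: with n foreground pixels and target d,
the k = round(n(1−d)) shallowest foreground pixels (distance-transform
order, seeded tie-break) are removed and the k nearest background pixels are
added, giving Dice = (n−k)/n exactly up to rounding — an erosion-plus-smear
pattern resembling how a segmentation network misses boundaries. Targets
default to the published per-structure Dice scores (maxilla 0.465, mandible
0.978, mandibular canal 0.794, maxillary sinus 0.644, individual teeth
0.870). The dentition mask is *not* degraded independently: it is rebuilt as
the union of the degraded teeth so the data-model invariant (dentition =
union of teeth) survives; its achieved Dice is emergent (~0.87–0.90 rather
than the published 0.945 of the independent dentition network). Computation
is restricted to the mask's bounding box plus a margin wide enough to hold
the k added pixels, which keeps degradation cheap for sparse structures.

## Evaluation protocol

Detection: greedy confidence-ordered one-to-one matching at an IoU
threshold (each ground truth claimable once; a duplicate hit is a false
positive), 101-point interpolated average precision pooled over images, and
AP/AR averaged over IoU 0.50:0.05:0.95 with at most 100 detections per image.
The 101-point interpolation is an explicit convention choice; the protocol
this mirrors reports COCO-style headline numbers without naming the
interpolation. Image-level translation: an image is called positive iff it
has a detection at or above the confidence threshold; accuracy, precision,
sensitivity, specificity and F1 are reported per threshold, and specificity
is flagged undefined (NaN, never 0) when no negative images exist.

Classification: the forest is trained on features of *annotated*
(ground-truth) boxes and evaluated both on that branch and on features of
the top-confidence *predicted* box. Because the top detection per scene does
not depend on the threshold, raising the confidence threshold only removes
samples whose best detection falls below it — the retained-sample count in
the sweep is non-increasing by construction, while the annotated branch
retains every sample at every threshold.

Rater agreement: Fleiss' κ from the vote-count matrix, with
P̄ₑ = Σ p_j² and per-subject agreement (Σ n_ij² − n)/(n(n−1)). If every
vote falls in one category, κ is undefined and flagged. The confidence
interval is a percentile bootstrap over subjects (default 2000 resamples,
seeded); degenerate resamples are dropped. Human-panel summaries average
per-rater metrics (mean ± SD) rather than pooling counts, the convention
for heterogeneous panels whose pooled harmonic means are not recoverable
from the averaged ones. Empty-vs-empty Dice is 1.0 (perfect agreement that
a structure is absent).

## Numerical and design choices

- Coordinates 0-based and half-open; all overlap quantities are exact
  integer-pixel ratios, so the geometry code is tested by literal pixel
  enumeration on small grids.
- Boxes are clipped to the image before share computation (jittered boxes
  can exit the frame); a box clipping to zero area is a degenerate-input
  error rather than a silent 0.
- Top-box ties break by larger area, then lowest (x, y); greedy matching
  ties break toward the lowest ground-truth index; split ties toward the
  lowest feature/threshold; vote ties toward odontogenic. Every tie rule is
  deterministic so identical configs reproduce identical bytes.
- Undefined metric cells (zero denominators, all-votes-one-category κ) are
  NaN with a warning, never 0.
- All generators are pure functions of (config, seed); experiment stages
  derive child seeds from one experiment seed via seed sequences.
- The one deliberate deviation in the property suite: a permutation-
  importance check destroys the whole tooth-information block (dentition +
  32 tooth features) rather than the tooth features alone, because dentition
  is derived from the teeth and carries the same information — permuting
  only the redundant copies leaves the ensemble's accuracy untouched.

## Problem sizes

The test and acceptance runs use deliberately desk-scale conditions: unit
and property tests run on quarter-size (256×128) scenes and forests of
tens-to-hundreds of trees; the recovery experiment uses 500 full-size
noise-free scenes with a 1000-tree forest; the noisy directional experiment
pools held-out predictions over five 250-scene runs with 300-tree forests.
These sizes were chosen so the whole suite exercises every stage in a few
minutes while keeping held-out sets large enough (~50–100 samples per run)
for stable metric estimates.

## Known limitations

- The cartoon anatomy has no projection artifacts, density texture, or
  overlapping-structure ambiguity, which is exactly what makes the real
  maxilla hard to segment; difficulty here is injected only through the
  Dice-targeted degradation.
- The planted rule makes class separability essentially perfect at zero
  noise, so absolute classification metrics from this harness say nothing
  about clinical accuracy; only protocol behaviour (attrition, metric
  arithmetic, branch differences, directional effects of noise) transfers.
- One lesion per positive scene by default; multi-lesion scenes are
  supported by the generator but the classification stage follows the
  top-box-per-image convention.
- The false-positive model emits at most one spurious box per scene
  (Bernoulli, not Poisson), adequate for threshold-sweep behaviour but not
  for heavy-clutter detector regimes.
- Fixed adult dentition (no mixed/pediatric layouts); missing teeth are
  supported but default to none.
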