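# Methods

## Problem and scope

`finprint` re-identifies individual Risso's dolphins (*Grampus griseus*)
from cropped photographs of their dorsal fins.  Adults of this species
accumulate long-lasting white scarring on the fin, which acts as a natural
barcode; photo-identification compares a new photograph against a gallery of
enrolled *fin models* (one per dolphin side) and returns the best-matching
identity with explicit reliability warnings.  Around the matcher the package
provides the catalogue data model (dolphin, image paths, date, GPS,
campaign codename), sighting-graph analytics for site-fidelity analysis, an
evaluation harness, and a synthetic fin-image generator used as the test
bed.

## Identification pipeline

For a query image `I` with feature set `S`, compared against models
`(I_1, S_1) … (I_m, S_m)`:

1. **Segmentation.**  `I` is converted from sRGB to CIE-Lab (D65).  Grey fin
   and blue sea separate along the opponent axes, so Otsu's threshold
   (maximising between-class variance on a 256-bin histogram) is applied to
   a single opponent channel.  Which channel (a\* or b\*) is an open design
   point; we threshold whichever attains the larger between-class variance
   at its own optimum, per image (`channel="auto"`, overridable).  Otsu
   yields a split but not a polarity: the foreground is taken to be the
   class in the minority on the 1-px image border, since cropped fin photos
   have sea at their edges.  Binary opening then closing with a disk of
   radius `max(1, round(0.005·min(H, W)))` removes speckle, and the largest
   8-connected component (ties: lexicographically smallest top-left
   foreground pixel) becomes the fin mask.
2. **Sharpness.**  The std of the response to the 3×3 four-neighbour
   Laplacian `[[0,1,0],[1,−4,1],[0,1,0]]` over the fin region, computed on
   the L\* plane rescaled to [0, 255] (reflect padding).  Constant regions
   score 0; blur shrinks the score.  A whole-frame mode exists for
   comparison, but the masked statistic is the default since blur matters
   where the features are.
3. **Admission filter.**  Width ≥ 200 px AND height ≥ 200 px AND ≥ 5
   in-fin features AND sharpness ≥ σ_s (all inclusive; σ_s defaults to 0 =
   off).  Failing queries are returned as structured rejections listing
   every violated rule — never a forced guess.
4. **Features.**  A scale/rotation-invariant detector runs on the full
   frame; keypoints outside the mask are deleted.  The backend is pluggable
   (`detect → positions, scales, orientations, descriptors`); the default is
   scikit-image's SIFT, which is deterministic, free, and meets the
   invariance contract.  Correctness tests run through the interface, so the
   logic is backend-agnostic.
5. **Matching.**  Mutual-nearest-neighbour matching under descriptor-space
   L2 distance, which is one-to-one by construction.  Per model the match
   arrays `P_i` (coordinate pairs), `D_i` (distances) and `O_i`
   (orientation pairs) are retained.  An optional Lowe ratio test is off by
   default.  "Distance" is read as descriptor distance (match quality);
   image-plane distance is kept as a diagnostic.
6. **Trimmed median distance d\*.**  The median of the `D_i` values lying
   inside the closed [25th, 75th]-percentile interval (linear-interpolation
   percentiles).  With two distinct values this interval can be empty; the
   plain median is used then.
7. **Equal-orientation filter.**  Matches are kept iff
   `ω = round(o_query − o_model) = 0` after wrapping the difference to the
   symmetric interval.  The rounding unit sets the agreement window and is
   configurable.  The **default is radians** (±0.5 rad ≈ ±28.6°): on
   synthetic galleries the degree reading (a ±0.5° window) annihilates even
   same-identity matches — orientation estimates of genuinely corresponding
   keypoints scatter by a few degrees between two photographs — and collapses
   rank-1 accuracy to chance-like levels, whereas the radian window removes
   misaligned matches while keeping true ones (and matches the convention of
   the MATLAB-family SURF tooling this method descends from, where keypoint
   orientations are radians).  `k*_i` is the retained count.
8. **Decision.**  Winner = argmax `k*_i`; ties break on minimum `d*_i`; a
   residual tie keeps the first model in enrollment order and raises
   `ambiguous_tie`.  A winner with `k* ≤ 4` raises `low_support`.  If no
   model yields even one raw match the query is rejected rather than
   guessed.

Enrollment (`build_fin_models`) applies steps 1–4 to catalogue images and
keeps, per (dolphin, side), the passing image with the highest sharpness
(ties: lexicographically smallest path), so `m = d + b` where `d` is the
number of enrolled dolphins and `b` the number with both sides enrolled.
Dolphins with no passing image are reported as un-enrollable.

## Sighting analytics

* **Dolphin–date graph**: bipartite, one edge per distinct (dolphin, date)
  pair; connected components partition the survey into disjoint
  dolphin/date clusters.
* **Co-sighting graph**: dolphins linked iff they share a sighting date;
  edge weight = number of shared dates, rendered dashed iff the weight is
  exactly 1.  Node depth class (`shallow_only` / `deep_only` / `both`) comes
  from the strata of the dolphin's sightings; the stratum boundary is the
  800 m isobath, with exactly-800 m classified deep (the boundary case is
  unspecified in the field convention this follows).
* **Sighting frequency**: per dolphin and stratum, sightings of the dolphin
  in the stratum divided by the stratum's total sightings.  Only individuals
  sighted more than once overall are reported — a dolphin's inclusion counts
  sightings across both strata.
* **Right-tailed Wilcoxon rank-sum**: exact p by enumeration of all
  `C(n_x+n_y, n_x)` rank assignments when the combined n ≤ 12 and there are
  no ties; otherwise midranks with the tie-corrected normal approximation
  and continuity correction.  A fully tied, zero-variance sample returns
  p = 0.5 at the null mean (scipy's asymptotic path errors there, hence the
  in-package implementation; scipy is the cross-check on non-degenerate
  inputs).

## Synthetic data

The generator emulates the study conditions rather than photorealism: a
grey (128, 128, 128) dorsal-fin-shaped polygon on blue (20, 60, 140) sea —
colours far apart on the b\* axis, so the opponent-channel separability the
segmentation relies on holds by construction — carrying 8 near-white scar
strokes drawn from a per-identity seed.  Renders add in-plane rotation,
uniform scale, Gaussian blur (σ, px) and i.i.d. pixel noise (sd 2 by
default), and return the exact polygon support as ground truth.  The default
canvas is 400×400 px so defaults clear the 200-px admission gate.
`generate_gallery` renders one clean model per identity plus perturbed,
labelled queries; `generate_catalogue` simulates a multi-date survey across
the two depth strata (depths uniform on [436, 800) m and [800, 1000] m,
matching a continental-slope survey area; GPS inside a Gulf-of-Taranto
bounding box; per-date presence i.i.d. Bernoulli with at least one sighting
per dolphin).

What the synthetic bed does **not** capture: water reflections and exposure
artefacts, out-of-plane (roll/yaw) rotation — rotation invariance is tested
via in-plane proxies only — partial occlusion by waves, and, importantly,
fin-outline variation: all identities share one silhouette template with
small jitter, so outline keypoints are a confusable background shared
across identities and discrimination rests on scar patterns.  Passing tests
therefore show the pipeline's logic and invariances, not field accuracy.

## Study sizes and numerical choices

The bundled evaluation (tests and `scripts/acceptance.py`) uses a
20-identity gallery, 3 clean queries per identity (rotation uniform in
±15°, scale in [0.9, 1.1]) and a 200-query mixed-blur set (blur σ drawn
from {0, 1, 2, 4}); segmentation and sharpness studies use 50 fins each;
the analytics study simulates 60 dolphins over 11 survey dates.  These are
the package's desk-scale defaults.  Other conventions: coordinates are
0-based (x = column, y = row); orientations are stored in degrees in
[0, 360); rounding is half-to-even throughout; Otsu ties across runs of
empty histogram bins are resolved to the first maximum (all such cuts
induce the same partition); undefined `d*` (zero matches) sorts as +∞ in
tie-breaks.

## Known limitations

* Absolute sharpness values depend on the intensity plane convention
  (L\* × 255/100 here); comparability with other implementations' scales is
  not claimed.
* One fin per frame; no multi-animal scenes, no video.
* Left/right sides are independent models; no symmetry inference.
* The equal-orientation filter assumes near-upright queries in spirit: a
  query rotated beyond the ±0.5 rad window survives only through the
  `d*` tie-break among all-zero `k*` scores (with a `low_support` warning).
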