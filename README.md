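# finprint

Automated photo-identification of Risso's dolphin (*Grampus griseus*)
dorsal fins, with a sighting catalogue and site-fidelity analytics.

Risso's dolphins accumulate long-lasting white scarring on the dorsal fin,
which field biologists use to recognise individuals across years of
surveys.  `finprint` automates that recognition: a query photograph is
segmented (the fin separates from blue water in CIE-Lab opponent space via
an Otsu threshold), quality-gated (minimum 200 px width/height, ≥ 5 in-fin
keypoints, optional Laplacian-sharpness threshold σ_s), described with
scale/rotation-invariant keypoints restricted to the fin, and matched
one-to-one (mutual nearest neighbours in descriptor space) against each
enrolled fin model *(I_i, S_i)*.  Each comparison is summarised by

* **k\*_i** — the number of matches with equal orientation,
  `ω_j = round(o_j^(query) − o_j^(i)) = 0`, and
* **d\*_i** — the median descriptor distance inside the 25th–75th
  percentile interval of the match distances,

and the predicted identity is `argmax_i k*_i`, ties broken by minimum
`d*_i`.  Predictions with `k* ≤ 4` or unresolved ties carry explicit
reliability warnings; inadmissible images are rejected, never guessed.

Alongside the matcher the package provides the catalogue data model
(dolphin name, image paths, observation date, GPS, campaign codename),
dolphin–date and co-sighting graphs, the per-stratum sighting-frequency
descriptor (shallower vs. deeper than 800 m) with a right-tailed Wilcoxon
rank-sum comparison, an evaluation harness (accuracy over admitted queries,
accuracy vs. σ_s curves, sharpness distributions), and a synthetic
fin-image generator with exact ground-truth masks, so everything is testable
without field imagery.  See `docs/methods.md` for the full method
description and design choices.

## Worked example

```python
import finprint as fp

# a tiny synthetic study: 5 identities, 1 perturbed query each
sim = fp.generate_gallery(5, seed=42, n_queries=1, rotation_max_deg=10.0)

models = []
for r in sim.models:
    mask = fp.extract_fin_mask(r.image)
    models.append(fp.FinModel(dolphin_name=r.name, side="right", image=r.image,
                              features=fp.detect_features(r.image, mask)))

query = sim.queries[0]
pred = fp.identify(query.image, models)
print(f"true={query.name} rotation={query.params.rotation_deg:+.1f} deg")
print(f"predicted={pred.dolphin_name} k={pred.winning_score.k} "
      f"k*={pred.winning_score.k_star} d*={pred.winning_score.d_star:.1f} "
      f"sharpness={pred.sharpness:.1f} warnings={sorted(pred.warnings)}")
```

prints

```
true=synth-000 rotation=+3.9 deg
predicted=synth-000 k=48 k*=31 d*=82.3 sharpness=34.8 warnings=[]
```

The query — the same individual re-rendered with a 3.9° rotation, a scale
change and fresh pixel noise — produced 48 one-to-one descriptor matches
against its own model, of which 31 were equally oriented (k\*), with a
trimmed median descriptor distance d\* of 82.3; the image's
Laplacian-sharpness score was 34.8 and the prediction carried no
reliability warnings.

The same pipeline is scriptable from the shell:

```sh
finprint --seed 7 simulate --identities 20 --queries 3 --out simdata/
finprint enroll --catalogue simdata/catalogue.json --out gallery/
finprint identify --gallery gallery/ --images simdata/queries/*.png --report report.csv
finprint evaluate --gallery gallery/ --queries simdata/queries --labels simdata/labels.csv --out eval/
finprint stats --catalogue simdata/catalogue.json --sightings simdata/sightings.json --out reports/
```

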