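# memcult

Cross-group analysis of image memorability from old/new recognition
confidence data.

Memorability research asks whether some images are intrinsically easier to
remember than others, for everyone.  If memorability were purely a stimulus
property, two groups of observers raised in very different visual
environments should agree on which images are memorable.  `memcult`
implements the full analysis pipeline for testing that question with two
participant groups (by default labelled `CN` and `US`):

1. **Scoring** — per-stimulus memorability: the mean reverse-coded 6-point
   recognition response when the image was *old* minus the mean when it was
   *new*, `m = mean(old) − mean(new)` on the confidence scale 1–6 (range
   −5…5).  Encoding-phase "will I remember this?" predictions and
   confidence-level distributions are computed alongside.
2. **Cross-group consistency** — Pearson correlation of the two groups'
   scores; a within-group median split classifies every stimulus into the
   2×2 quadrants (memorable in both / group A only / neither / group B
   only); Welch one-tailed t tests compare object-dimension scores between
   the two disagreement quadrants.
3. **Dimension transfer** — one elastic-net regression per object dimension
   maps stimulus embeddings to reference dimension scores (hyperparameters
   by 10-fold CV maximizing validation Pearson r), so new stimuli can be
   placed in an interpretable 49-dimension object space.
4. **SVM-RFE** — recursive feature elimination around a linear hinge-loss
   SVM: 6×10-fold CV accuracy per step, elimination of the dimension with
   the smallest mean |w|, a 7-point moving average over the accuracy trace,
   and selection of the dimensions surviving at the smoothed peak.
5. **Culture-specific models** — each group's scores are residualized on
   the other group's (OLS), isolating the non-shared component; the top-6
   Life and top-6 Non-life dimensions most correlated with those residuals
   feed multiple regressions reported as R², F, p and residual SE.

Because trial-level human data of this kind are rarely shareable, the
package ships a first-class synthetic generator (`memcult.synthetic`) that
reproduces the study design — 120 participants per group, 600 stimuli in 4
counterbalanced subsets (each subset old for 30 and new for 30
participants), 150 encoding + 300 recognition trials per participant —
from a latent-Gaussian ordinal response model with configurable planted
shared and group-specific dimension effects.  Every downstream stage can
therefore be validated against a known ground truth.  See
`docs/methods.md` for the model and its assumptions.

## Worked example

```python
import memcult

# a full synthetic study with the default planted effects:
# group CN carries extra weight on life dimensions, US on nonlife ones
ds = memcult.default_dataset(seed=1)

tab = memcult.memorability_table(ds.trials)
wide = tab.pivot(index="stimulus", columns="group", values="memorability")
r, p, n = memcult.cross_group_correlation(wide["CN"], wide["US"])
print(f"cross-group r = {r:.3f} (n = {n})")

quad = memcult.assign_quadrants(wide["CN"], wide["US"])
print("quadrant counts:", quad.counts)

models = memcult.run_culture_models(
    wide["CN"], wide["US"], ds.dimensions.scores, ds.dimensions.categories,
    group_names=("CN", "US"),
)
print(models[["group", "model", "r2", "p"]])
```

Output:

```
cross-group r = 0.624 (n = 600)
quadrant counts: {1: 217, 2: 81, 3: 220, 4: 82}
  group     model        r2             p
0    CN      Life  0.240978  8.242235e-33
1    CN  Non-life  0.116194  7.848713e-14
2    US      Life  0.162653  1.684111e-20
3    US  Non-life  0.164411  9.225510e-21
```

The two groups agree substantially (r ≈ 0.62) but not perfectly; ~27% of
stimuli fall in the disagreement quadrants.  The planted CN-specific life
effect surfaces exactly where it should: the Life model explains more
CN-specific variance (R² = 0.24) than US-specific variance (R² = 0.16),
while the Non-life models are closer together.

The same stages are available from a shell:

```bash
memcult simulate --out run/ --seed 1
memcult score --trials run/trials.csv --out run/mem.tsv
memcult compare --mem run/mem.tsv --dims run/dimensions.tsv --out run/
memcult run-all --out run/ --seed 1      # everything, with a manifest
```

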