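# attspace

Attitudinal spaces and distance-based attitude-diversity metrics for
survey data.

Debates about opinion polarization usually compare *mean attitude
positions* of social groups along a single dimension. That one number
cannot distinguish two very different societies: one where groups have
merely drifted apart while each remains internally diverse, and one where
groups have collapsed into tight, aligned camps at the extremes. This
package ports the multidimensional trait-space toolkit of functional
ecology to survey research: respondents become points in a low-dimensional
**attitudinal space** built from their answers, and the shape of each
group's point cloud — not just its centre — is quantified and tested.

It is aimed at quantitative social scientists and social-ecological
researchers working with ordinal (Likert) and continuous (0–100 feeling
thermometer) survey items, grouped by party, region, time, or any other
label.

## The model

**Space construction.** Items are validated, respondents with more than
10% missing answers are dropped, and residual gaps are median-imputed.
Dimensionality *d* is chosen by the eigenvalue-greater-than-1 rule applied
to the mixed-type correlation matrix (polychoric for ordinal–ordinal
pairs, polyserial for mixed pairs, Pearson otherwise). The space itself is
a PCA of the z-scored item codes, with the *d* retained components rotated
for interpretability — varimax (orthogonal) or promax (oblique, reported
with its interfactor correlation Φ); `rotation="auto"` keeps promax when
|Φ₁₂| ≥ 0.3. For tables with categorical items or unimputed missing cells
an alternative builder uses Gower dissimilarity and principal coordinates
(Lingoes-corrected PCoA).

**Metrics.** Axes are min–max scaled over the pooled sample and every
distance is divided by √d, so all metrics live on a common 0–1 scale. For
a group *g* with (optionally weighted) members xᵢ, pooled centroid **C**
and own centroid **c**_g:

| metric | definition |
|---|---|
| position | weighted mean coordinate of *g* on one axis |
| extremization | mean ‖xᵢ − **C**‖ / √d (distance to the *pooled* centroid) |
| dispersion | mean ‖xᵢ − **c**_g‖ / √d (distance to the *own* centroid) |
| richness | convex-hull volume of *g* ÷ pooled hull volume |
| TOP index | summed areas of successively peeled hulls (d = 2) |
| originality | mean nearest-neighbour distance within *g* / √d |
| distance | ‖**c**_a − **c**_b‖ / √d between two groups |
| entities | distinct response vectors (vs. the theoretical maximum) |
| evenness | regularity of minimum-spanning-tree branch lengths ∈ [0, 1] |

**Inference.** Uncertainty comes from a subsampling bootstrap: B draws of
n_sub respondents without replacement inside each group, coordinates and
scaling held fixed from the full sample. Two groups (or two time points)
are compared by the paired-difference p-value
p = 2·min(#(D ≤ 0)+1, #(D ≥ 0)+1)/(B+1). The polarization diagnosis then
reads three contrasts: no significant position difference → **none**;
with a significant position difference, extremization significantly up
*and* dispersion significantly down → **strong**, exactly one of those
signals → **moderate**, neither → **weak**.

A synthetic-survey generator (latent two-factor respondents, Likert
discretization by fixed instrument thresholds, MCAR missingness) with
named scenarios (`null`, `weak`, `strong`, `case1_like`) makes the whole
pipeline testable without any data download.

## Worked example

```python
import attspace as asf

cfg = asf.preset_scenario("strong", n_per_group=400, seed=42)
table, _ = asf.generate_survey(cfg)

res = asf.AttitudinalSpaceModel(table, d=2, rotation="varimax").fit()
print(res.summary())

rep = res.classify("A@t2", "A@t1", B=1000, seed=42)
print(rep.label, rep.extremization.percent_change, rep.dispersion.percent_change)
```

prints (abridged):

```
Attitudinal space
=================
respondents: 1600    items: 12    axes: 2
method: pca    rotation: varimax
variance explained: axis 1: 40.9%, axis 2: 15.8%
cumulative (unrotated): 56.7%

         n  position_axis_1  position_axis_2  ...  evenness
A@t1   400            0.448            0.489  ...     0.662
B@t1   400            0.532            0.485  ...     0.674
A@t2   400            0.035            0.499  ...     0.543
B@t2   400            0.961            0.498  ...     0.514

classification: strong
position axis 1: delta=-0.413 p=0.0040
extremization: +112.2% p=0.0020
dispersion:    -45.9% p=0.0020
```

Between t1 and t2 group A's mean position shifts to the end of axis 1
(0.448 → 0.035), its members move away from the population centre
(extremization more than doubles) while closing ranks around their own
centre (dispersion −46%): the signature of strong polarization, and the
classifier says so.

The same workflow runs from the shell:

```sh
attspace simulate --scenario strong --outdir data/
attspace all --config run.yaml --seed 7 --outdir out/
```

writing `coordinates.csv`, `loadings.csv`, `metrics.csv`, `contrasts.csv`,
`report.json` and a `run.log` under `out/`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full workflow from scratch on the bundled synthetic scenarios
— survey generation, space construction, scaled metrics, bootstrap
contrasts and polarization classification — printing the classification
summary to stderr and writing the results JSON to `--out`. The published
benchmark surveys live in an external data deposit that is not bundled, so
the script carries no dataset-reproduction targets.

See `docs/methods.md` for the statistical details, parameter defaults and
known limitations.
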