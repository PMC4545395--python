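# cardiofuse

Tools for combining independent left-ventricle (LV) segmentations of
short-axis cine cardiac MRI and for deciding — with or without a gold
standard — which segmentation method estimates cardiac function best.

Automated LV segmentation algorithms disagree: some over-delineate the
endocardial border, some under-delineate it, some exclude the papillary
muscles from the blood pool. Those disagreements propagate into the
clinical numbers that matter (end-diastolic and end-systolic volumes,
ejection fraction, myocardial mass). `cardiofuse` implements a complete
evaluation pipeline around two statistical ideas:

1. **STAPLE label fusion.** Several binary segmentations of the same slice
   are fused by expectation-maximization into a probabilistic consensus
   while estimating each rater's sensitivity *p<sub>j</sub>* and
   specificity *q<sub>j</sub>*. Fusion runs per 2D slice (short-axis stacks
   are strongly anisotropic) inside the union bounding box of the rater
   masks, so results do not depend on how much background surrounds the
   ventricle.
2. **Extended Regression Without Truth (eRWT).** To rank methods without a
   reference, the true biomarker value Θ<sub>p</sub> of subject *p* is
   modeled as a latent draw from a Beta(μ, ν) distribution, observed by
   method *k* through a linear model
   θ<sub>pk</sub> = a<sub>k</sub>Θ<sub>p</sub> + b<sub>k</sub> + ε<sub>pk</sub>
   with ε<sub>pk</sub> ~ N(0, σ<sub>k</sub>²). Maximizing the marginal
   likelihood needs no true values, only their distribution. Each method is
   scored by its figure of merit — the expected squared error against the
   truth — which is analytic under a Beta truth:

   F<sub>k</sub> = (a<sub>k</sub>−1)² μ(μ+1)/((μ+ν)(μ+ν+1)) + 2(a<sub>k</sub>−1)b<sub>k</sub> μ/(μ+ν) + b<sub>k</sub>² + σ<sub>k</sub>²

   Rankings come from a subject-level bootstrap of the figures of merit
   with a Kruskal-Wallis omnibus test and Bonferroni-corrected pairwise
   comparisons that merge statistically indistinguishable methods into tie
   groups.

Around these two cores the package provides slice-summation volumetry and
the six clinical indices (EDV, ESV, SV = EDV − ESV, LVEF = SV/EDV, EpV,
MM = 1.05 × (EpV − EDV)), supervised comparison against a reference rater
(bias β, spread *s*, limits of agreement β ± 1.96 *s*), a synthetic-cohort
generator (four clinical subgroups, rendered LV mask stacks, raters with
controllable boundary bias and jitter), and a pipeline that fuses every
subset of automated methods and ranks each fusion candidate against the
original raters.

## Worked example

Rank three simulated measurement methods without ground truth:

```python
import cardiofuse as cf
from cardiofuse.types import MethodProfile

truths = cf.simulate_true_values(45, cf.BetaShape(2.85, 3.40), seed=7)
methods = [
    MethodProfile(1.00, 0.00, 0.02, "expert"),
    MethodProfile(0.92, 0.06, 0.04, "atlas"),
    MethodProfile(1.05, -0.03, 0.07, "threshold"),
]
estimates = cf.simulate_estimates(truths, methods, seed=8)

model = cf.ErwtModel(mu=2.85, nu=3.40, seed=0).fit(estimates)
print(model.figure_of_merit_frame().round(4))

foms = cf.bootstrap_foms(estimates, model=model, n_draws=200, seed=1)
table = cf.pairwise_ranking(foms, alpha=0.05)
for g, members in enumerate(table.groups, 1):
    print(f"rank {g}: {'-'.join(members)}")
```

prints

```
                a       b   sigma     fom
method
expert     0.8743  0.0583  0.0185  0.0009
atlas      0.8517  0.0801  0.0481  0.0032
threshold  0.8998  0.0439  0.0722  0.0056
rank 1: expert
rank 2: atlas
rank 3: threshold
```

The fitted noise levels track the generating ones (0.02 < 0.04 < 0.07;
at P = 45 the slope/intercept estimates still carry visible sampling
error), the figures of merit order the methods correctly, and the
bootstrap declares all three pairwise differences significant — three
singleton tie groups, best first.

The same machinery runs end to end from mask stacks via the CLI:

```bash
cardiofuse simulate --seed 1 --out cohort/
cardiofuse fuse --inputs cohort/manifest.csv --subject CTRL-01 --phase ED \
    --methods A1,A2,A3 --out fused/
cardiofuse rank --estimates indices.csv --n-boot 1000 --seed 1 --out ranking.json
cardiofuse run --config run.yaml --out results/
```

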