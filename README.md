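# fishssf

Integrated step-selection analysis of fine-scale acoustic telemetry from
fish approaching a river barrier and its fish pass.

Upstream-migrating fish (e.g. barbel *Barbus barbus* and grayling
*Thymallus thymallus*) must locate a fish pass entrance inside the highly
altered hydraulic field below a hydropower plant. Given 2D positions every
second or two and hydraulic covariate rasters (flow velocity, depth,
spatial velocity gradient and their directions on a 0.5 m grid), this
package asks: *which hydraulic conditions do individual fish select as they
approach the pass, and do those preferences generalise to the population?*

It is written for movement ecologists and fish-passage researchers who want
a tested, scriptable version of this analysis — including a synthetic-river
generator with known selection coefficients, so every stage can be
validated against ground truth.

## The model

Each regularized 20 s step of a fish is compared with 10 random alternative
steps sharing its start point (drawn from gamma step-length and von Mises
turning-angle distributions — an integrated step-selection function). With
standardized covariates *x* the probability that the observed step *i* was
taken from its matched set *S* is the conditional logit

```
P(i | S) = exp(beta' x_i) / sum_{j in S} exp(beta' x_j)
```

maximized per fish by Newton iteration, followed by backward stepwise AIC
selection (a more complex model is retained only when its AIC is at least
2 units lower). Population inference is two-step: per-fish coefficients
(zero for terms a fish's model dropped) are averaged per species with SD,
SE, CV = SD/mean, a 95% t-interval and a one-sample t-test; a term has a
*cohesive* population effect only when the CI excludes zero and p < 0.05.
Selection is visualised as log relative selection strength, log-RSS(v) =
beta·z(v), per covariate and for interactions at three moderator values.

## Worked example

```python
from fishssf.config import DetectionModel, PipelineConfig, SimulationConfig
from fishssf.pipeline import run_pipeline
from fishssf.synthetic import generate_scenario

sim = SimulationConfig(
    channel_length=300.0, channel_width=40.0,
    pass_xy=(14.0, 20.0), release_xy=(280.0, 20.0),
    n_fish=4, n_steps=220, seed=20180510, discharges=(50,),
    detection=DetectionModel(mean_interval_s=2.5, dropout_prob=0.1,
                             noise_sd_m=0.3))
sim.approach_bias = 0.7

bundle = generate_scenario(sim)           # rasters, detections, truth
result = run_pipeline(
    PipelineConfig(pass_xy=sim.pass_xy, release_xy=sim.release_xy,
                   regularization_method="linear", seed=3),
    bundle=bundle)

for m in result.models:
    print(m.fish_id, len(m.terms), round(m.concordance, 3))
print(result.population_summaries["grayling"]
      [["term", "mean", "se", "p", "cohesive"]].head(4))
```

prints (four simulated fish released 260 m downstream; three produced a
retained approach track; the generator's true habitat coefficients were
WV 0.6, D 0.4, DiffVang 0.25, log(SL) 1.0, log(SL):WV(start) −0.5):

```
B001 7 0.725
G002 4 0.713
G004 5 0.758
                 term      mean        se         p  cohesive
0            WV (end)  0.546755  0.055432  0.064323     False
1             D (end)  0.337725  0.043330  0.081235     False
2      DiffVang (end) -0.365953  0.017833  0.030998      True
3  log(SL):WV (start) -0.322804  0.069100  0.134249     False
```

Concordance ~0.72 means the fitted score ranks the observed step above a
random alternative about 72% of the time. Velocity and depth means land
near their generating values, but with only two grayling the t-intervals
are wide and neither is cohesive — exactly the individual-variation problem
the two-step summary quantifies. Note DiffVang: its generating value is
+0.25, yet the fitted effect is strongly negative, because these fish carry
an unmodelled migration drive toward the pass — upstream, against the flow
— which the flow-alignment term absorbs. Apparent flow-angle selection in
approach tracks is confounded with the migration goal; the recovery studies
in `scripts/acceptance.py` therefore simulate goal-free movement when
validating estimator correctness.

The same pipeline runs from the shell:

```
fishssf simulate --out scenario/ --seed 1
fishssf all --inputs scenario/ --out results/ --seed 1
```

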