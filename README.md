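# stereocoupling

Simulation and analysis of **perceptual coupling** experiments with
structure-from-motion (SFM) cylinders, for vision scientists studying how
stereoscopic and stereovision-impaired observers disambiguate bistable
stimuli.

Two random-dot cylinders rotate coaxially: a disparity-defined *inducer* half
cylinder (convex/near or concave/far) and a fully ambiguous test cylinder
whose front-plane rotation direction the observer reports.  The analysis
chain answers two questions: **who can use disparity at all**, and **how does
the inducer's depth couple to the ambiguous percept** in each group.

## The model

Baseline judgements (convex vs concave at signed disparity *d*, in arcmin)
follow a logistic psychometric function

```
P(convex | d) = 1 / (1 + exp(-(4.39/ω) · (d − θ)))
```

with location θ (disparity of 50% convex reports; a bias measure) and width ω
(the disparity range over which the probability sweeps between its tails;
4.39 ≈ 2·ln 9 makes θ ± ω/2 the 10%/90% points).  Per subject, the posterior
over (θ, ω) is sampled with an adaptive random-walk Metropolis sampler
(4 chains, split-R̂ convergence checks); a Gibbs-within-Metropolis
hierarchical fit provides group-level means and spreads.

Subjects are classified from the **steepness** s = 1/ω.  The point null
H0: s = s₀ (s₀ = 0.0076 arcmin⁻¹, the smallest credible steepness a human
cohort produced) is nested in the alternative, so the Bayes factor is the
Savage–Dickey density ratio

```
BF10 = p_prior(s₀) / p_posterior(s₀)
```

with the prior density analytic and the posterior density estimated by KDE on
the log-steepness scale.  BF10 ≥ 3 ⇒ stereoscopic, BF10 ≤ 1/3 ⇒
stereovision-impaired, otherwise undecided; Jeffreys-style evidence bands at
3/10/30/100 and their reciprocals.

Group-level frequentist statistics mirror the standard battery: one-way ANOVA
of %convex over the five disparity levels, t tests against chance, a paired
near-vs-far coupling test, and an OLS fit of far coupling (0–1 fraction)
against the depth-perception score (%convex at +4.6 minus −4.6 arcmin).

## Worked example

The numbered scripts under `analysis/` run the study on the packaged
18-subject synthetic cohort (8 stereoscopic archetypes, 10 impaired):

```
python analysis/01_simulate.py      # results/responses.csv, truth.json
python analysis/02_fit.py           # results/posteriors.json, posterior_draws.csv
python analysis/03_classify.py      # results/classification.csv
python analysis/04_group_stats.py   # results/group_stats.json, subject_summaries.csv
```

With the default seed, classification prints (abridged):

```
 S01  BF10      1e+12       decisive (H1)  stereoscopic
 ...
 S09  BF10     0.0481         strong (H0)  stereovision-impaired
 S13  BF10    0.00799       decisive (H0)  stereovision-impaired
 ...
group counts: {'stereovision-impaired': 10, 'stereoscopic': 8}
```

i.e. every steep-curve archetype earns decisive evidence against the
negligible-steepness null and every flat-curve archetype earns substantial to
decisive evidence for it.  The group statistics then show the signature
pattern:

```
== stereoscopic (n=8) ==
ANOVA over disparity: F(4, 35) = 18.91, p = 2.33e-08
coupling_near_vs_chance: t(7) = -0.45, p = 0.668
coupling_far_vs_chance: t(7) = 6.44, p = 0.000354
far coupling vs depth perception: r = 0.81, SSE = 0.06, df = 6

== stereovision-impaired (n=10) ==
ANOVA over disparity: F(4, 45) = 0.72, p = 0.58
```

— disparity strongly drives the stereoscopic group's convexity reports and
their far (but not near) coupling, while the impaired group is at chance
everywhere.

The same pipeline is available as one call (`stereocoupling run --seed 1
--outdir results`) or via `stereocoupling.pipeline.run_pipeline`, and each
stage as a CLI subcommand (`simulate-cohort`, `stimulus-preview`, `fit`,
`classify`, `group-stats`, `report`).

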