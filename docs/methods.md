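# Methods

## Stimulus model

The stimulus is a random-dot SFM cylinder: a 3 × 3 visual-degree aperture,
radius 1.5° (= width/2), rotating about a horizontal axis once per 3 s
(120 deg/s).  Dots are sampled uniformly in the projected aperture and mapped
onto the cylinder surface (phase φ with projected vertical position
y = r·sin φ); layers alternate so the full two-layer cylinder splits evenly.
The aggregate density of 12 dots/deg² over both layers yields 108 dots for the
full cylinder and 54 for the one-layer half cylinder; overlapping dots are
permitted.  Projected dot speed is |ω·r·cos φ| and its time average over one
rotation is 4r/T = 2 deg/s for the default geometry — the per-dot average,
which is sampling-independent, rather than an ensemble average at one instant.

Disparity: depth of the cylinder apex is d = D·tan(r) at viewing distance
D = 100 cm; under the small-angle convention the peak disparity is
δ = IOD·d/D² radians.  With an interocular distance of 6.3 cm this gives
5.7 arcmin for the 1.5° radius.  The IOD is a configurable assumption (it is
rarely reported with stimulus geometry); 6.3 cm is adopted because it makes
the printed 5.7 arcmin exact under the small-angle formula.  The disparity
gradient across the cylinder follows the circular cross-section,
δ(y) = δ_max·√(1 − (y/r)²), positive for convex (near), negative for concave
(far) — a sign convention enforced pipeline-wide.

Baseline blocks contain 20 repeats × unsigned levels {0, 2.3, 4.6} arcmin ×
{convex, concave} = 120 trials (1 s stimulus + 1.5 s ISI = 5 min); the two
0-arcmin conditions are physically identical flat stimuli and are pooled in
analysis.  Trial order and per-trial pattern direction are drawn from the
schedule seed.

## Synthetic observers

Baseline responses are Bernoulli draws from

P(convex | d) = λ/2 + (1 − λ)·(1 + exp(−(4.39/ω)(d − θ)))⁻¹,

where the slope is 4.39/ω.  Writing the exponent with ω in the numerator (as
compact notations sometimes do) would make wider curves steeper, contradicting
the width interpretation, so the width parametrization is used; 4.39 ≈ 2·ln 9
places θ ± ω/2 at the 10%/90% points (a 5%–95% reading would only rescale ω
by ln 19/ln 9 ≈ 1.34).  The lapse rate λ defaults to 0 so the fitted and
generating models coincide; it exists for robustness experiments only.

Coupling responses mix three pathways per trial: with probability *m* the
front-plane percept follows the inducer pattern's motion direction; otherwise
with probability *g* (condition-specific g_near/g_far) it couples
depth-appropriately — with the inducer dots for a near inducer, opposite for a
far inducer; otherwise a fair coin.  Correctness is depth-referenced: near ⇒
correct = same direction as the inducer, far ⇒ correct = opposite.  A pure
motion-coupling observer (m = 1) therefore scores 100% in the near condition
and 0% in the far condition, the limiting prediction for observers with no
usable disparity signal; the perfect depth-coupler (g = 1) scores 100% in
both.  The mixture evaluates the motion pathway first; only the m = 1 and
g = 1 limits are externally constrained, so the ordering is a documented
modelling choice.

The packaged cohort has 18 subjects.  Eight stereoscopic archetypes: ω from 3
to 10 arcmin, θ evenly spread over −2.4…+4.4 arcmin, no motion coupling,
g_near = 0, and g_far mostly 0.85–0.95 with two weak members (0.4 and 0.0)
mirroring the within-group spread real cohorts show.  Ten impaired archetypes:
ω from 105 to 300 arcmin, θ evenly spread over ±40 arcmin, g = m = 0.  These
are fixed study conditions, not tuning knobs.  Features of real data the
generator does *not* emulate: percept hysteresis across trials (trials are
independent), reaction times, lapse behaviour, and the occasional impaired
observer with genuinely elevated near coupling.  Passing tests therefore
demonstrate that the estimators and classifiers behave correctly under the
stated generative model, not that any particular human cohort must split
8/10.

A global seed expands through `numpy.random.SeedSequence` into per-subject,
per-stage substreams, so any subject regenerates in isolation and artifacts
are byte-reproducible.

## Inference

Per-subject likelihood: Bernoulli over trials, evaluated from per-level
(n, k) counts.  Priors: θ ~ Normal(0, 20 arcmin) — wide enough to cover the
±40 arcmin bias range flat observers show; ω supported on [0.5, 500] arcmin
with two options:

* **uniform-steepness** (default): s = 1/ω ~ Uniform(1/500, 2).  Flat data
  concentrate the steepness posterior near zero *relative to this prior*, so
  flat observers earn strong-to-decisive null evidence (BF10 ~ 0.005–0.05 at
  n = 120), the behaviour expected of a steepness-based classifier: under a
  log-uniform ω prior the same observers hover at BF10 ≈ 0.2–1.5 and the
  classifier cannot separate the groups at this sample size.
* **log-uniform** ω, retained as a configurable alternative.

Both give an analytic steepness prior density at the null, which the
Savage–Dickey ratio requires.

Sampler: random-walk Metropolis on (θ, log ω), 4 chains vectorized, 5000
draws after 1000 burn-in by default.  During burn-in a per-chain scalar scale
targets ~30% acceptance and, from iteration 300 on, the proposal covariance
is re-estimated from the chain history every 100 iterations (adaptive
Metropolis); this is what makes the strongly correlated θ–ω ridge of flat
observers mix (split-R̂ ≤ 1.01 in practice, threshold 1.05).  Adaptation
freezes at the end of burn-in.  Non-convergence is flagged and propagated
into reports, never fatal.  With zero responses the "posterior" is the prior,
returned as direct prior draws flagged `prior_only`.

HDI: shortest contiguous window of ⌈mass·n⌉ sorted draws (cross-checked
against arviz).  R̂/ESS: split-R̂ implemented locally and verified against
arviz; ESS via arviz.

Hierarchical model: θᵢ ~ N(μ_θ, σ_θ), log ωᵢ ~ N(μ_w, σ_w), with conjugate
normal/inverse-gamma hyperpriors (μ_θ ~ N(0, 20); μ_w ~ N(midpoint of the
log-ω range, 3); variances ~ InvGamma(1, 1)).  Sampling is
Gibbs-within-Metropolis: vectorized per-subject random-walk updates
conditional on the hypers, conjugate draws for the hypers.  Savage–Dickey
classification deliberately uses the *independent, fixed-prior* per-subject
posteriors — the hierarchical prior at the null point is not analytic — and
the hierarchical fit is reported separately.

## Classification

Steepness draws are reciprocals of the ω draws.  The null s₀ is the fixed
constant 0.0076 arcmin⁻¹ by default (so partial runs reproduce the reference
null); setting `null_steepness: cohort` derives it as the cohort minimum of
the lower 95%-HDI steepness bounds.  The posterior density at s₀ is a
Gaussian KDE on log-steepness (Silverman bandwidth, log-sum-exp evaluation)
transformed back by the 1/s₀ Jacobian — stable near zero, and validated
against the closed-form Bayes factor of a conjugate normal-mean toy problem
to within 10%.  Reported BF10 values are clamped to [10⁻¹², 10¹²]: beyond
that the KDE underflows and the evidence is decisive either way.  Group
thresholds are symmetric (3 and 1/3) with an explicit undecided zone, since
borderline observers (substantial-but-not-decisive null evidence) are a real
phenomenon.

## Group statistics

Implemented over scipy.stats with dfs and sums of squares assembled
explicitly.  The ANOVA treats each subject × level percentage as an
independent observation, giving df (4, N·5 − 5) = (4, 45) or (4, 35) for
groups of 10 and 8 — the design the printed degrees of freedom imply, though a
repeated-measures model would be more orthodox.  t tests are two-sided.  The
depth-perception score is %convex(+4.6) − %convex(−4.6), oriented so
disparity-sensitive subjects score high.  The coupling-vs-depth regression
computes SSE with coupling on the 0–1 fraction scale (on the percent scale
the SSE would be 10⁴ times larger and incomparable to reference values).
Degenerate inputs (zero variance, constant regressor, missing levels) raise
typed errors rather than returning NaN, and incomplete subjects are excluded
from group tests with a report warning.

## Problem sizes and numerical choices

Default analyses use the study design exactly: 120 baseline trials/subject,
20 coupling trials/condition, 18 subjects.  Parameter-recovery checks run 50
replicates at 2 chains × 2000 draws; the hierarchical recovery test uses 10
subjects.  Tolerances in tests: binomial checks at 3 SE; Savage–Dickey vs
conjugate closed form at 10% (Monte-Carlo + KDE error); classical statistics
vs formula oracles at 1e-10; quadrature vs closed-form speed at 1e-9.

## Known limitations

* The Bayes-factor magnitudes depend on the ω prior by construction
  (Lindley–Bartlett sensitivity); the uniform-steepness default is a choice,
  argued above, not a theorem.
* The KDE posterior-density estimate degrades when the null lies at the edge
  of the posterior support; with the cohort-derived null and very flat
  cohorts this inflates BF10 somewhat (the fixed default null avoids this).
* No lapse-rate estimation, link-function comparison, or per-eye modelling;
  no reaction times or percept-switching dynamics.
* The coupling observer is memoryless; sequential effects in real coupling
  data are out of scope.
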