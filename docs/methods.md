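# Methods

## Decision-analytic model

A triage test is judged against the decision it informs: refer a symptomatic
patient for urgent cancer workup, or not. A risk threshold t ∈ (0, 1) —
here the 3% encoded in UK suspected-cancer referral guidance — defines the
probability of cancer at which referral and non-referral are equally
acceptable, and hence the relative costs of the two errors: one false
negative costs (1 − t)/t true negatives (32.3 at t = 3%); one false positive
costs t/(1 − t) true positives. Net benefit discounts a strategy's
desirable outcomes by its weighted errors, on two equivalent scales:

* unreferred (net TNs per patient): `Sp(1−p) − (1−t)/t · p(1−Se)`
* referred (net TPs per patient): `Se·p − t/(1−t) · (1−p)(1−Sp)`

The scales obey the exact identity
`NB_unref(test) = (NB_ref(test) − NB_ref(refer_all)) · (1−t)/t`, so the
strategy maximizing one maximizes the other; the package computes both and
tests assert the identity draw by draw. "Clinically useful" means strictly
greater net benefit than both refer-all and refer-none; ties count as not
useful (a conservative convention applied consistently in `prob_useful`
and the region boundaries). Net benefit may be negative and is reported
as-is. Internally all rates are per patient; reporting multiplies by a
scale factor, 100,000 by default, purely at the presentation layer.
Thresholds of exactly 0 or 1 are rejected (infinite error weights), never
clamped.

## Count reconstruction from published summaries

When a study prints only (N, prevalence or D, Se, Sp, optionally P, PPV,
NPV), integer counts are recovered as D = round(prev·N),
TP = round(Se·D), TN = round(Sp·(N−D)), FP and FN by subtraction; rounding
is half-away-from-zero, the convention under which published proportions
are usually produced from counts. An alternative TN = floor(NPV·(N−P)) is
available for sources that define it that way; it requires NPV and P and
never yields TN > N − P. Reconstructions implying a negative cell raise an
explicit inconsistency error.

Reconstruction is exact when the inputs are exact (the round-trip property
is tested over random integer-consistent matrices). From *rounded* printed
values it carries ±1-count ambiguity: with the packaged fixture,
D = round(0.067 · 5461) = 366 gives plug-in sensitivity 243/366 = 66.4%
against the printed 66.3% (the study's unprinted D was evidently ≈368).
This ambiguity shifts posterior net-benefit summaries by well under the
Monte-Carlo standard error at 10,000 draws and is documented rather than
corrected. Fixture rows whose printed information cannot support
reconstruction (pathway specificities reported only as "above 96%") are
stored with those fields absent and skipped with a logged reason — never
imputed.

## Bayesian inference

Sensitivity, specificity and prevalence get independent Beta priors,
Beta(1, 1) by default, conjugate to the three binomial margins:
Se ~ Beta(a₁+TP, a₂+FN), Sp ~ Beta(b₁+TN, b₂+FP), p ~ Beta(c₁+D, c₂+N−D).
No MCMC is involved. Independence mirrors the binomial factorization of
the likelihood; it ignores any correlation induced by the same individuals
contributing to several margins, a second-order effect at study scale.

Monte-Carlo summaries use 10,000 draws by default. One draw set is shared
across all thresholds of a decision curve — (Se, Sp, p) do not depend on
t — which makes curves smooth in t and minimizes the variance of
between-threshold differences; per-threshold resampling is available as a
flag (`shared_draws=False`), each threshold drawing from its own substream.
Credible intervals are equal-tailed percentile intervals (2.5%/97.5% for
mass 0.95) using linear interpolation between order statistics, numpy's
default quantile rule; percentile endpoints differ slightly across
conventions, so the rule is fixed here. P(useful) is the fraction of draws
whose referred-scale net benefit strictly exceeds max(NB(refer_all), 0),
the comparator evaluated on the same prevalence draw; the unreferred-scale
comparison is identical by the scale identity and both are exposed.

Per-pathway reproducibility: each pathway's seed derives from the master
seed and a CRC-32 of its label, so adding or reordering rows never changes
another pathway's draws.

The default decision-curve grid is t = 0.005 to 0.075 in steps of 0.0025,
covering the 1%–7% range relevant to referral preferences, with 3%
highlighted.

## Clinical-utility regions

For fixed (p, t) the usefulness condition is linear in (Se, Sp), giving
closed-form boundaries: beating refer-all requires
`Se > 1 − t·Sp(1−p)/((1−t)p)`; beating refer-none requires
`Sp > 1 − Se·p(1−t)/(t(1−p))`. The region is the intersection; when p > t
the first constraint binds, when p < t the second, and the code evaluates
both without branching on prevalence. A requirement no value in [0, 1] can
strictly satisfy is returned as infinity (`UNATTAINABLE`) — a meaningful
answer (e.g. no test with zero specificity can beat referring everyone),
not an exception. Boundaries are traced on a uniform specificity grid;
slices with no attainable sensitivity are omitted.

## Cutoff optimization

A continuous classifier score binarized at cutoff c (positive iff
score ≥ c; ties positive) yields a step-function net benefit in c that only
changes where a score is crossed, so midpoints between consecutive distinct
scores plus all-positive/all-negative sentinels form an exact candidate
set. The optimizer maximizes plug-in net TNs per 100,000 at fixed t; ties
at the maximum break toward the fewest positives (highest specificity) —
fewer referrals at equal net benefit. Because the all-positive sentinel
reproduces refer-all at exactly zero net TNs, the reported maximum is never
negative; a maximum of zero is flagged `no_useful_cutoff`. Selection over
many cutoffs optimistically biases the apparent net benefit (a property
test documents the mean selection–validation gap being nonnegative), which
is why Bayesian evaluation of the *chosen* cutoff is a separate step and
ideally done on independent data.

## Synthetic data

`generate_counts` draws confusion matrices from the same binomial hierarchy
the inference assumes (D ~ Bin(n, p), TP ~ Bin(D, Se), TN ~ Bin(n−D, Sp));
it is therefore a calibration oracle, not a stress test of model
misspecification. `generate_cohort` draws patient-level scores from a
binormal model — Gaussian components for cases and controls, the standard
diagnostic-marker idealization — with closed-form implied (Se, Sp) at any
cutoff for exact oracles. Defaults emulate the motivating study's scale:
n = 5,461, prevalence 6.7%; controls N(0, 1) and cases N(2.56, 1), placed
so the cutoff 2.14 operates near 66% sensitivity / 98% specificity.
Passing tests on these cohorts demonstrate correctness of the machinery
under the assumed model; they say nothing about non-Gaussian score shapes,
verification bias, or within-patient correlation in real data.

## Problem sizes and numerical choices

Calibration checks use 400 replicate cohorts of n = 2,000 with 2,000 draws
each (coverage asserted within [91%, 99%] for the 95% intervals); the
consistency check against plug-in rates uses one simulated cohort of 10⁶;
the P(useful) quadrature oracle uses a 200³ midpoint grid at N = 4. These
sizes give Monte-Carlo noise comfortably below the asserted tolerances
while keeping the default suite fast. All generators are numpy
`default_rng` streams fully determined by explicit seeds; derived seeds
stay below 2³¹.

## Known limitations

* The three-Beta independence assumption (above) is an approximation.
* Reconstruction inherits printed-value rounding; results from summaries
  are accurate only to that granularity (±1 count in D, TP, TN).
* The binary-test case only: no continuous-marker decision curves beyond
  scanning binarization cutoffs.
* Changing the risk threshold changes the referral-eligible population in
  practice; the model holds (Se, Sp, p) fixed across t, as decision-curve
  analysis conventionally does.
* No cost-effectiveness conversion to monetary units, and no modelling of
  test price or turnaround time.
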