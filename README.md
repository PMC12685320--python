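# triagedca

Bayesian decision-curve analysis (DCA) for diagnostic **triage** tests —
tests used to decide which symptomatic patients to refer for urgent
workup — evaluated directly from published summary statistics.

The motivating application is a multicancer detection (MCD) blood test
offered to patients referred from primary care under suspicion of cancer.
UK referral guidelines encode a **risk threshold** of t = 3%: refer anyone
whose cancer probability is at least 3%. That threshold fixes the exchange
rate between decision errors — each missed cancer (FN) costs
(1 − t)/t = 32.3 avoided referrals — and makes *clinical utility* a
computable quantity rather than a judgement about sensitivity being
"high enough".

## The model

For a binary test with sensitivity Se, specificity Sp, and disease
prevalence p, net benefit at threshold t is

* unreferred scale (net true negatives per patient — unnecessary referrals
  avoided): `NB_unref = Sp·(1−p) − (1−t)/t · p·(1−Se)`
* referred scale (net true positives per patient):
  `NB_ref = Se·p − t/(1−t) · (1−p)·(1−Sp)`

The two scales rank strategies identically. A test is **clinically useful**
when its net benefit strictly exceeds both default strategies, refer-all
(Se = 1, Sp = 0) and refer-none (Se = 0, Sp = 1).

Uncertainty is handled with a conjugate Beta-Binomial model: with uniform
Beta(1, 1) priors, Se ~ Beta(1 + TP, 1 + FN), Sp ~ Beta(1 + TN, 1 + FP),
p ~ Beta(1 + D, 1 + N − D), sampled independently (10,000 draws by
default). Pushing draws through the formulas above yields posterior
decision curves and **P(useful)** — the posterior probability of beating
both comparators. When only summary statistics were published, integer
counts are first reconstructed (TP = round(Se·D), TN = round(Sp·(N−D)),
remainder by subtraction).

Two further tools come for free from the algebra:

* **clinical-utility regions**: closed-form minimum sensitivity/specificity
  a test must exceed for given (p, t), e.g.
  `Se_min = 1 − t·Sp·(1−p) / ((1−t)·p)`;
* a **cutoff optimizer** that re-binarizes a continuous classifier score at
  the cutoff maximizing net true negatives per 100,000 patients — improving
  a classifier's clinical utility without retraining it.

## Worked example

The packaged fixture (`triagedca.packaged_fixture_path()`) carries the
printed figures of a 5,461-patient prospective UK triage cohort: overall
prevalence 6.7%, sensitivity 66.3%, specificity 98.4%.

```python
from triagedca import (parse_performance_table, reconstruct_counts,
                       dca_curve_from_counts, packaged_fixture_path)

records = parse_performance_table(packaged_fixture_path())
counts = reconstruct_counts(next(r for r in records if r.pathway_label == "overall"))
curve = dca_curve_from_counts(counts, thresholds=[0.03], n_draws=10_000, seed=1)
print(curve[["nb_unreferred_mean", "nb_unreferred_lo", "nb_unreferred_hi",
             "p_useful_referred"]].round(1))
```

prints

```
   nb_unreferred_mean  nb_unreferred_lo  nb_unreferred_hi  p_useful_referred
0             18556.2            4738.9           31232.3                1.0
```

i.e. at the 3% threshold the test avoids ≈18,600 (95% CrI 4,700–31,200)
unnecessary referrals per 100,000 symptomatic patients, with a posterior
probability of clinical utility above 99.4% — even after pricing every
missed cancer at 32.3 avoided referrals. The same workflow from the shell:

```sh
triagedca dca --seed 1 --output-dir out/       # per-pathway curves + JSON
triagedca regions                              # minimum-performance tables
triagedca cutoff --seed 1 --output-dir out/    # cutoff optimization
```

The `examples/` directory has one short narrative script per capability:
count reconstruction and plug-in net benefit, the Bayesian decision curve,
utility regions (why a 30%-prevalence lung pathway needs > 92.8% sensitivity
even from a perfectly specific test, while a 3.7%-prevalence gynecologic
pathway needs < 20%), and cutoff optimization on a synthetic cohort.

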