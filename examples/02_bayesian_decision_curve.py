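"""Bayesian decision curve and probability of clinical utility.

Samples 10,000 draws from the conjugate Beta-Binomial posterior of
(sensitivity, specificity, prevalence) and summarizes net benefit across
risk thresholds, including P(useful): the posterior probability that the
test beats both referring everyone and referring no one.
"""

from triagedca import (
    dca_curve_from_counts,
    packaged_fixture_path,
    parse_performance_table,
    reconstruct_counts,
)

records = parse_performance_table(packaged_fixture_path())
counts = reconstruct_counts(next(r for r in records if r.pathway_label == "overall"))

curve = dca_curve_from_counts(counts, thresholds=[0.01, 0.02, 0.03, 0.05, 0.07],
                              n_draws=10_000, seed=1)
table = curve[["threshold", "nb_unreferred_mean", "nb_unreferred_lo",
               "nb_unreferred_hi", "p_useful_referred"]]
print(table.round({"nb_unreferred_mean": 0, "nb_unreferred_lo": 0,
                   "nb_unreferred_hi": 0, "p_useful_referred": 3})
      .to_string(index=False))

row = curve[curve["threshold"] == 0.03].iloc[0]
print(f"\nAt the 3% threshold the test avoids {row['nb_unreferred_mean']:,.0f} "
      f"(95% CrI {row['nb_unreferred_lo']:,.0f}-{row['nb_unreferred_hi']:,.0f}) "
      "unnecessary referrals per 100,000 symptomatic patients,")
print(f"with P(useful) = {100 * row['p_useful_referred']:.1f}% — near-certain "
      "clinical utility. Below ~2% the weight on missed cancers grows and "
      "referring everyone becomes the better strategy.")
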