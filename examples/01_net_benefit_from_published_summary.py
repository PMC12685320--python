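"""Reconstruct confusion counts from a published summary and compute plug-in
net benefit at the guideline risk threshold.

The packaged fixture carries the printed accuracy figures of a large UK
triage study of a multicancer detection blood test (5,461 symptomatic
patients, 6.7% cancer prevalence, sensitivity 66.3%, specificity 98.4%).
"""

from triagedca import (
    RiskThreshold,
    net_true_negatives,
    net_true_positives,
    packaged_fixture_path,
    parse_performance_table,
    reconstruct_counts,
)

records = parse_performance_table(packaged_fixture_path())
overall = next(r for r in records if r.pathway_label == "overall")
counts = reconstruct_counts(overall)
print(f"reconstructed counts: TP={counts.tp} FP={counts.fp} "
      f"TN={counts.tn} FN={counts.fn} (N={counts.n_total}, D={counts.n_cancer})")

t = RiskThreshold(0.03)  # the 3% suspected-cancer referral threshold
print(f"each missed cancer is priced at {t.fn_weight:.1f} avoided referrals")

net_tn = net_true_negatives(counts, t)
net_tp = net_true_positives(counts, t)
print(f"net TNs = {net_tn:,.0f}  ->  {net_tn / counts.n_total * 1e5:,.0f} "
      "unnecessary referrals avoided per 100,000 patients (plug-in)")
print(f"net TPs = {net_tp:,.1f} per {counts.n_total} patients")
# A positive net-TN count means the test beats referring every patient even
# after charging 32.3 avoided referrals for each cancer it misses.
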