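"""Minimum test performance required for clinical utility.

Prevalence and risk threshold alone define, in closed form, the set of
(sensitivity, specificity) pairs that beat both default referral strategies.
High-prevalence pathways demand sensitivity; low-prevalence pathways demand
specificity.
"""

from triagedca import RegionSpec, RiskThreshold, min_sensitivity, region_membership

t = RiskThreshold(0.03)

lung = RegionSpec(prev=0.30, threshold=t)          # highest-prevalence pathway
gyn = RegionSpec(prev=0.037, threshold=t)          # lowest-prevalence pathway

for name, spec in [("lung (30% prevalence)", lung), ("gynecologic (3.7%)", gyn)]:
    req = min_sensitivity(1.0, spec)
    print(f"{name}: even a perfectly specific test needs sensitivity "
          f"> {100 * req:.1f}% to be clinically useful")

# The observed lung operating point (Se 70.8%, Sp ~97%) falls far short:
inside = region_membership(0.708, 0.97, RegionSpec(prev=0.298, threshold=t))
print(f"observed lung operating point inside utility region: {inside}")
# ... while in the gynecologic pathway even ~49% sensitivity clears the bar:
inside = region_membership(0.491, 0.984, gyn)
print(f"observed gynecologic operating point inside utility region: {inside}")
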