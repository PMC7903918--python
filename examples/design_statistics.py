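"""Closed-form study-design statistics.

Two-group power under the normal approximation, and the Mendelian
genotype-ratio summary used to check homozygote viability in a
heterozygote intercross (expected 25%).
"""

from corenet import PowerDesign, RatioObservation, power_two_group_z, ratio_summary

# synapse-count design: difference of 7 synapses, sd 2.5, 4 mice per group
p = power_two_group_z(PowerDesign(delta=7, sd1=2.5, sd2=2.5, n1=4, n2=4))
print(f"synapse design power: {100 * p:.1f}%")

# relative-expression design: 40% difference, unequal sds from the ddCt scale
p = power_two_group_z(PowerDesign(delta=0.4, sd1=0.01, sd2=0.2, n1=4, n2=4))
print(f"expression design power: {100 * p:.1f}%")

# 43 homozygotes out of 242 pups vs the expected 25%
res = ratio_summary(RatioObservation(k=43, n=242))
print(f"homozygotes: {res['percent']}% (chi2={res['chi2']:.2f}, p={res['p']:.4f})")
# A percentage well below 25% with a small p suggests reduced viability
# of homozygous pups.
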