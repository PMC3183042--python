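"""Sex-specific F1 hybrid inviability as an effective sex-biased migration.

In taxa with heterogametic females (birds, butterflies), Haldane's rule
makes hybrid females preferentially inviable or sterile.  Killing half the
F1 females filters each marker's migrant copies differently, which is
equivalent to a sex-biased migration model and can be tested the same way.
"""

from sexmig import MarkerClass, effective_rates_from_f1_viability

m = 0.001  # per-capita migration rate of both sexes
rates = effective_rates_from_f1_viability(m, m, female_survival=0.5, male_survival=1.0)

print(f"equal migration m = {m} with half the F1 females inviable:")
for mk in MarkerClass:
    print(f"  {mk.value:2s} effective rate = {rates[mk]:.6f}  ({rates[mk]/m:.4g} x m)")
print()
print("The mitochondrial rate halves and the autosomal rate drops to 3/4 —")
print("identical to a 2:1 male:female migration ratio, so hybrid-viability")
print("hypotheses can be folded into effective migration rates and tested")
print("with the same likelihood machinery.")
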