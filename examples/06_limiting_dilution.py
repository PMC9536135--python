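"""Estimate sphere-initiating cell frequency from a limiting-dilution assay.

Cells are plated at decreasing densities (100/50/25/12 cells per well,
24 wells each); a well with no sphere is 'negative'.  Under the single-hit
Poisson model P(negative) = exp(-f * dose), so f is estimated by a
complementary log-log binomial regression with unit slope in log dose.
"""

from pathstrat import lda_frequency

doses = [100, 50, 25, 12]
wells = [24, 24, 24, 24]
negatives = [8, 15, 20, 22]

res = lda_frequency(doses, wells, negatives)
print(f"estimated frequency: 1 in {1 / res.frequency:.1f} cells")
print(f"95% CI: 1/{1 / res.ci_high:.1f} to 1/{1 / res.ci_low:.1f}")
print()
print("One in ~{:.0f} plated cells initiates a sphere; a treatment that".format(
    1 / res.frequency))
print("lowers this frequency depletes the self-renewing compartment.")
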