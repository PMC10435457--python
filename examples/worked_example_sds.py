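"""Evaluate the published CMC correlations at the sodium dodecyl sulfate record.

This is the one fully printed input/output pair shipped with the package:
physical conditions plus the five anion descriptors, the experimental
log10(CMC), and the three model estimates.
"""

from cmcqspr import absolute_error, gp_cmc_2023, linear_cmc_2023, sds_fixture
from cmcqspr.published import GP_READINGS

record, desc, expected = sds_fixture()
print(f"compound: {record.compound_id}")
print(f"conditions: T = {record.T} K, pH = {record.pH}, S_eq = {record.S_eq} ppm")
print(f"experimental log10(CMC) = {record.log_cmc}")

linear = linear_cmc_2023(record, desc)
print(f"\nlinear correlation: {linear:.3f}  (AE = {absolute_error(record.log_cmc, linear):.3f})")
print("  -> matches the published estimate 0.516 / AE 0.289")

print("\nGP closed form (ambiguously typeset; both faithful readings):")
for reading in GP_READINGS:
    value = gp_cmc_2023(record, desc, reading)
    print(f"  {reading:12s}: {value:+.3f}  "
          f"(printed reference 0.729; deviation {abs(value - 0.729):.3f})")
print("  neither reading reproduces the printed value — the formula's")
print("  junction operators are ambiguous in the source typesetting.")
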