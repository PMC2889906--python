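"""Strain comparison tables from published phenotype values.

Expresses each mutant's induction phenotypes as a percentage of the
wild-type reference, and the change between first induction and reinduction
as a percent change — the two standard views for judging induction defects
and transcriptional memory.
"""

from galinduce.datasets import published_rows
from galinduce.phenotypes import percent_change, relative_to_reference

rows = published_rows(strains=("HTZ1", "htz1D", "htz1-K3,8,10,14R"),
                      conditions=("primary",))
rel = relative_to_reference(rows, "HTZ1")
print("time to half-steady-state, relative to wild type (primary induction):")
for strain in ("HTZ1", "htz1D", "htz1-K3,8,10,14R"):
    print(f"  {strain:20s} {rel.value(strain, 'time_to_half'):6.1f} %")

print()
print("percent change, first induction -> reinduction:")
for strain in ("HTZ1", "htz1D", "htz1-K3,8,10,14R"):
    by_cond = {r.condition: r for r in published_rows(strains=(strain,))}
    t = percent_change(by_cond["primary"], by_cond["secondary"])
    print(f"  {strain:20s} time-to-half {t.value(strain, 'time_to_half'):7.1f} %,"
          f"  onset {t.value(strain, 'activation_time'):7.1f} %")

print()
print("Values above 100% mean slower than wild type; large negative percent")
print("changes on reinduction are the signature of transcriptional memory.")
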