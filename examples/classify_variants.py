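"""Classify EGFR exon 19 variant descriptors into TKI-sensitivity profiles.

Profile 1 (net beta3/alphaC loop shortening <= 3 residues) predicts primary
resistance to erlotinib and osimertinib; profile 2 (>= 4) predicts
sensitivity.  Afatinib sensitivity is similar in both groups.
"""

from egfr19 import classify_descriptor, parse_variant, apply_variant
from egfr19.variants import ReferenceContext

descriptors = [
    "ΔE746-A750",        # the most common exon 19 deletion (5 residues)
    "ΔL747-A750InsP",    # 4 deleted, 1 proline inserted -> net 3
    "ΔL747-T751InsP",    # one more residue deleted -> net 4
    "L747P",             # proline substitution, no shortening
    "ΔL747-E749",        # 3-residue deletion, no proline
    "E746_S752delinsV",  # HGVS-style spelling of ΔE746-S752InsV
]

ctx = ReferenceContext()
print(f"reference {ctx.reference_start}-{ctx.reference_end}: "
      f"{ctx.reference_sequence}")
print(f"{'descriptor':<18} {'mutant loop':<18} net  proline  profile  activated?")
for d in descriptors:
    v = parse_variant(d, ctx)
    call = classify_descriptor(d)
    print(f"{d:<18} {apply_variant(v, ctx):<18} "
          f"{call.net_loop_shortening:>3}  {str(call.proline_introduced):<7} "
          f"{call.profile:^7}  {call.activation_predicted}")

# The net column is deleted-minus-inserted residues; variants with net <= 3
# keep wild-type-like ATP affinity (profile 1, TKI-resistant), net >= 4 raises
# K_M,ATP and sensitises to erlotinib/osimertinib (profile 2).
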