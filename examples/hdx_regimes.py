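"""HDX-MS analysis on synthetic envelopes: percent exchange, residue mapping
and EX1/EX2 regime detection.

In the EX2 limit a peptide's mass envelope drifts up progressively; in the
EX1 limit two envelopes with fixed positions trade area as a long-lived
locally-unfolded population grows — the behaviour seen in catalytic-loop
peptides of TKI-sensitive (profile 2) EGFR variants.
"""

from egfr19.hdx import (
    classify_exchange_regime,
    comb_smoothing_points,
    fit_envelope,
    ligand_occupancy,
    map_to_residues,
    percent_exchange,
)
from egfr19.simulate import HDXScenario, gen_hdx_series

# An HRD-motif-like peptide in EX1 (opening rate 0.005 1/s) vs EX2 kinetics
for label, k_open in (("EX1", 0.005), ("EX2", None)):
    scenario = HDXScenario(sequence="HRDLAARNVLV", start_res=835,
                           ex1_opening_rate=k_open, noise=0.01, seed=1)
    truth = gen_hdx_series(scenario)
    rec = percent_exchange(truth.series)
    fits = [fit_envelope(env, smooth_sigma_points=comb_smoothing_points(env))
            for env in truth.envelopes]
    call = classify_exchange_regime(fits)
    ex = ", ".join(f"{t:.0f}s:{p:.0f}%" for t, p in
                   zip(rec.timepoints_s, rec.percent_exchange))
    print(f"generated {label}: %Ex [{ex}] -> classified {call}")
    if call == "EX1":
        fracs = ", ".join(f"{f.folded_fraction:.2f}" for f in fits
                          if len(f.components) == 2)
        print(f"  folded fraction over time: {fracs} "
              "(area of the low-mass envelope)")

# Residue-level assignment: the shortest covering peptide wins; ties go to
# the peptide retaining the overlap at its C-terminus.
long_pep = gen_hdx_series(HDXScenario(sequence="QHVKITDFGLA", start_res=825,
                                      rate_per_s=2e-3, seed=2))
short_pep = gen_hdx_series(HDXScenario(sequence="VKITDFG", start_res=827,
                                       rate_per_s=8e-3, seed=3))
rmap = map_to_residues([percent_exchange(long_pep.series),
                        percent_exchange(short_pep.series)])
a = rmap.assignments[830]
print(f"residue 830 takes %Ex from peptide {a.source_span} "
      f"(shortest covering peptide): {a.percent_exchange[1]:.0f}% at 60 s")

# Erlotinib occupancy under labelling conditions (binding equilibrium)
frac = ligand_occupancy(protein_uM=0.39, ligand_uM=0.78, kd_uM=0.005)
print(f"inhibitor occupancy after 20-fold labelling dilution: {frac:.1%} "
      "(>90%: exchange reflects the drug-bound kinase)")
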