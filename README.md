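# egfr19

Quantitative analysis of EGFR exon 19 variants and their sensitivity to
tyrosine kinase inhibitors (TKIs), for kinase biochemists and translational
researchers working on EGFR-driven non-small cell lung cancer.

In-frame deletions and indels in EGFR exon 19 remove residues from the loop
connecting kinase strand β3 to the regulatory αC helix. The package
implements a simple classification of these variants with predictive value
for TKI response, together with the biochemical analysis chain that supports
it:

* **Variant parsing and classification** — descriptors in Δ-notation
  (`ΔL747-A750InsP`), HGVS-like protein notation (`E746_A750del`,
  `L747_A750delinsP`) or substitutions (`L747P`) are parsed against the
  β3/αC reference sequence (UniProt P00533 precursor numbering; mature-chain
  numbers are 24 lower). The net loop shortening
  `net = deleted − inserted` assigns **profile 1** (net ≤ 3; wild-type-like
  ATP affinity, primary resistance to erlotinib and osimertinib) or
  **profile 2** (net ≥ 4; raised *K*<sub>M,ATP</sub>, TKI-sensitive).
  Afatinib sensitivity is similar in both profiles.
* **Steady-state kinetics** — initial velocities from progress curves,
  Michaelis–Menten fits (*v* = *V*<sub>max</sub>[S]/(*K*<sub>M</sub>+[S])),
  one-parameter IC50 fits (Rate = 100/(1+[TKI]/IC50)), the Cheng–Prusoff
  relation IC50 = *K*<sub>I</sub>(1+[ATP]/*K*<sub>M,ATP</sub>), and an
  endpoint-titration correction of the turnover number
  (*k*<sub>cat,corr</sub> = *k*<sub>cat,app</sub>·[TKD]/(2·IC50<sub>afatinib</sub>)).
* **HDX-MS** — percent exchange
  %Ex = (*m*<sub>t</sub>−*m*<sub>0</sub>)/(*m*<sub>f</sub>−*m*<sub>0</sub>)·100
  from peptide centroid masses, residue-level mapping by the
  shortest-covering-peptide rule, two-Gaussian envelope deconvolution and
  EX1 / EX2 / fused-bimodal regime calls.
* **Survival** — Kaplan–Meier estimation, median survival and the log-rank
  (Mantel–Cox) test comparing profile-stratified patient cohorts
  (via `lifelines`).
* **Synthetic data** — seeded generators for progress curves under
  competitive inhibition with substrate depletion, dose–response tables,
  binomial/two-population isotope envelopes, and exponential survival
  cohorts, so the whole chain is testable without any instrument data.

## Worked example

```python
from egfr19 import classify_descriptor, correct_kcat, predict_ic50

call = classify_descriptor("ΔL747-A750InsP")
print(call.profile, call.net_loop_shortening, call.proline_introduced)
# 1 3 True   — 4 residues deleted, 1 inserted: net 3 -> profile 1

print(round(predict_ic50(5.3, 23.0, 1000.0), 1))
# 235.7      — erlotinib IC50 (nM) predicted at 1 mM ATP from K_I = 5.3 nM
#              and K_M,ATP = 23 uM, close to the measured 232 ± 48 nM

corr = correct_kcat(0.91, tkd_conc_nM=100.0, afatinib_ic50_nM=36.0)
print(round(corr.corrected_kcat, 2), round(corr.active_fraction, 2))
# 1.26 0.72  — only 72% of the enzyme is active, so per-active-molecule
#              turnover rises from 0.91 to 1.26 1/s
```

The `examples/` directory contains one short narrative script per
capability (`classify_variants.py`, `kinetics_pipeline.py`,
`hdx_regimes.py`, `survival_comparison.py`); each builds a small input, runs
the method and prints what the numbers mean. A thin CLI (`egfr19 classify
--input variants.csv --output out/` etc.) wraps the same functions for
shell use.

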