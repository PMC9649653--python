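"""Profile-stratified survival comparison on a simulated erlotinib cohort.

Cohort sizes (6 profile 1 vs 70 profile 2) and median progression-free
survival (2.3 vs 8.5 months) follow published erlotinib-treated cohorts;
event times are exponential with 20% uniform independent censoring, and each
patient carries a variant descriptor drawn from the published frequency
tables, re-classified on the fly.
"""

from egfr19.simulate import CohortScenario, gen_cohort
from egfr19.survival import compare_profiles

scenario = CohortScenario(censoring_fraction=0.2, seed=2024)
records = gen_cohort(scenario)

result = compare_profiles(records)
print(f"profile 1: n={result['n_profile1']}, "
      f"median PFS = {result['median_profile1']:.1f} months")
print(f"profile 2: n={result['n_profile2']}, "
      f"median PFS = {result['median_profile2']:.1f} months")
lr = result["logrank"]
print(f"log-rank (Mantel-Cox): chi2 = {lr.statistic:.2f}, p = {lr.p_value:.4f}")

# A small p-value supports the classification rule: patients whose variant
# shortens the beta3/alphaC loop by <= 3 residues (profile 1) progress
# earlier on erlotinib than profile 2 patients.
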