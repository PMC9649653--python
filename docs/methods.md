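# Methods

This note records the models, conventions and design choices behind
`egfr19`, and what the synthetic-data generators do and do not emulate.

## Variant model and profile classification

Variants are protein-level edits of the EGFR β3/αC loop region, parsed
against a reference window of the precursor sequence (UniProt P00533
numbering; mature-chain indices are 24 lower). The default reference spans
K745–E762 (`KELREATSPKANKEILDE`), which covers the catalytic lysine (K745),
the loop itself, and the αC glutamate (E762); the classification window
defaults to E746–I759 and is configurable. Stated reference residues in a
descriptor must match the reference sequence, which catches transcription
errors in variant lists.

The classifier uses a single quantity, the net loop shortening
`net = deleted_count − len(inserted)`:

* `net ≤ 3` → **profile 1**: the shortened loop can still bridge β3 and αC
  without major distortion; ATP affinity stays wild-type-like (low
  *K*<sub>M,ATP</sub>) and ATP-competitive TKIs (erlotinib, osimertinib)
  are outcompeted — primary resistance.
* `net ≥ 4` → **profile 2**: bridging requires unwinding αC and disorders
  the ATP pocket, raising *K*<sub>M,ATP</sub> and sensitising the kinase to
  those TKIs.

Insertions count at face value regardless of composition; substitutions are
net 0. A proline introduced anywhere in the edit (insertion containing P,
or substitution to P) sets `proline_introduced`, and
`activation_predicted = (profile 2) or proline_introduced`: short deletions
generally activate the kinase only when a proline rigidifies the loop
(e.g. `L747P`, `ΔL747-A750InsP`), whereas the proline-free 3-residue
deletion `ΔL747-E749` is classified profile 1 and not predicted active.
Net insertions (inserted > deleted) are outside the rule's domain and raise
an error rather than receiving a speculative label. Deletions extending
beyond the configured window are still classified (with a warning) as long
as they overlap it.

## Kinetics estimator chain

Units: enzyme and inhibitor concentrations in nM, substrates in μM,
velocities in μM/s.

* **Calibration** — ordinary least squares of fluorescence counts against
  known phosphopeptide concentrations; the inverse map converts progress
  curves to product concentrations.
* **Initial velocity** — the published procedure is manual inspection of
  the steady-state phase; here the policy is automatic and reproducible:
  the longest prefix window with linear-fit r² ≥ 0.99 (minimum 4 points),
  capped where product exceeds 10% of the peptide concentration. Flat
  blank curves are reported as zero rate rather than rejected. Thresholds
  are arguments with these defaults.
* **Michaelis–Menten** — `scipy.optimize.curve_fit` on
  *v* = *V*<sub>max</sub>[S]/(*K*<sub>M</sub>+[S]), initialised at the
  median substrate concentration and the maximum observed rate, positivity
  enforced by bounds. A warning is raised when the fitted *K*<sub>M</sub>
  falls outside the tested range by more than ten-fold. The apparent
  *k*<sub>cat</sub> = *V*<sub>max</sub>/[TKD] refers to the enzyme
  concentration of that titration; at subsaturating peptide it
  underestimates the true turnover by the factor [S]/(K<sub>M,pept</sub>+[S]).
* **IC50** — one-parameter fit of Rate = 100/(1+[TKI]/IC50) on rates
  normalised to the zero-inhibitor mean (top fixed at 100, bottom 0, Hill
  slope 1 — no 4-parameter logistic, matching the reporting convention of
  the source assays). If the top dose inhibits < 50% the estimate is
  flagged censored; if all rates are above 80% (or below 20%) only a bound
  is reported. Censored values are excluded from fold-change statistics.
* **Cheng–Prusoff** — IC50 = *K*<sub>I</sub>(1+[ATP]/*K*<sub>M,ATP</sub>).
  With a known *K*<sub>M,ATP</sub> the single parameter *K*<sub>I</sub> is
  solved in closed form (linear least squares); otherwise an unconstrained
  line gives intercept *K*<sub>I</sub> and slope
  *K*<sub>I</sub>/*K*<sub>M,ATP</sub>. A relative IC50 span < 20% across
  the ATP series, or a non-positive slope, raises a non-competitive flag —
  the qualitative behaviour seen for several profile 2 preparations, where
  no *K*<sub>I</sub> can be quoted. A negative intercept is a fit error.
* **Corrected kcat** — afatinib is treated as an endpoint titrant of active
  enzyme: its IC50 is taken as half the active concentration, so
  *k*<sub>cat,corr</sub> = *k*<sub>cat,app</sub>·[TKD]/(2·IC50<sub>af</sub>).
  The correction uses assay-scale concentrations; the shipped summary table
  stores the IC50-assay enzyme concentration per variant (100 nM for all
  but one variant assayed at 1 μM, whose published IC50s are
  presentation-scaled by 1/10 and are un-scaled before any arithmetic). An
  active fraction above 1 attaches a warning but still reports the value.
* **Fold changes** — ratios of summary means versus a reference variant,
  with the ratio SD by first-order (delta-method) error propagation and
  two-sided unpaired Student's t-tests from summary statistics
  (`scipy.stats.ttest_ind_from_stats`).

One known tension is surfaced rather than reconciled: for `L747P` the
forward Cheng–Prusoff prediction from its *K*<sub>I</sub> (6.2 nM) and
*K*<sub>M,ATP</sub> (21 μM) at 1 mM ATP is ≈ 301 nM, while the directly
measured erlotinib IC50 is 141 ± 17 nM; both numbers are kept.

## HDX-MS

Percent exchange is %Ex = (*m*<sub>t</sub>−*m*<sub>0</sub>)/(*m*<sub>f</sub>−*m*<sub>0</sub>)·100
per peptide and timepoint (default grid 10/60/180/600 s), aggregated over
replicates as mean ± SD. The fully-deuterated reference is expected from
the experiment; a theoretical convenience
*m*<sub>f</sub> = *m*<sub>0</sub> + 0.95·(exchangeable amides)·1.00628 Da is
provided, with exchangeable amides = length − 1 − (prolines after the first
position) — the standard HDX convention, offered as a convention only.

Residue-level maps assign each residue the %Ex of the shortest covering
peptide; among equal-shortest peptides the one whose C-terminus extends
furthest right is used ("retains the overlapping region at its
C-terminus"), with any remaining tie broken towards the later start. The
exact semantics of the C-terminal-retention rule are an interpretation,
pinned by tests. Uncovered residues are flagged, never interpolated.

Envelope deconvolution fits one or two Gaussians to the m/z profile and
selects between them by corrected AIC with a 2-point margin favouring the
simpler model (the source analysis used interactive fitting and states no
criterion). Two components separated by less than 1.5× their pooled width
are labelled fused-bimodal (configurable). Isotope-resolved combs must be
smoothed before fitting; `comb_smoothing_points` returns a Gaussian kernel
of 0.6× the deuterium comb spacing (1.006/charge Th). The series-level
regime call is consensus-based: EX1 requires at least two timepoints with
well-separated components whose positions agree with the median positions
to within 25% of their separation (areas may shift freely); recurring
two-component fits with stable positions but insufficient separation are
fused-bimodal; everything else — including skewed unimodal envelopes that
the two-Gaussian fit over-splits, recognisable by concerted mean drift — is
EX2. The consensus rule makes the call robust to single degenerate
timepoints where one population has nearly vanished.

Differential exchange flags variant peptides whose mean lies outside the
wild-type mean ± SD band; no hypothesis test is attached, since the
underlying workflow defines none. `ligand_occupancy` solves the exact
two-state binding quadratic, e.g. to confirm > 90% inhibitor occupancy
under labelling conditions.

## Survival

Kaplan–Meier estimation and the log-rank (Mantel–Cox) test are delegated to
`lifelines` behind the module's record types; events precede censorings at
tied times (the standard convention). Median survival is the smallest time
with S(t) ≤ 0.5, undefined when S never reaches 0.5. Tests cross-check the
estimator against a brute-force product-limit oracle on exhaustive small
censoring patterns. Cox proportional-hazards adjustment is deliberately out
of scope; `to_dataframe` exposes cohorts for external survival packages.

## Synthetic-data generators

All generators are pure functions of (scenario, seed).

* **Progress curves** — d[P]/dt = *k*<sub>cat</sub>·E<sub>act</sub>·
  ([ATP]/(K<sub>M,ATP</sub>(1+[I]/K<sub>I</sub>)+[ATP]))·
  ([S]₀−[P])/(K<sub>M,pept</sub>+[S]₀−[P]), integrated by fixed-substep RK4
  (0.5 s substeps), ATP in excess, multiplicative Gaussian noise with the
  scenario CV (2% default). Default parameters mirror the published summary
  table for the index profile 1 variant (*k*<sub>cat</sub> 0.91 1/s,
  *K*<sub>M,ATP</sub> 23 μM, *K*<sub>M,pept</sub> 15 μM, erlotinib
  *K*<sub>I</sub> 5.3 nM, 100 nM enzyme).
* **Dose–response** — the inhibition hyperbola with multiplicative noise
  (4% in simulation studies, matching typical plate-reader scatter).
* **HDX envelopes** — deuterium combs at spacing 1.006/charge Th, Gaussian
  peak width 0.08 Th, smoothed at analysis time. EX2: binomial
  incorporation with per-amide probability 0.95·(1−e<sup>−kt</sup>). EX1:
  mixture of the undeuterated and fully-exchanged combs with folded
  fraction e<sup>−k<sub>open</sub>t</sup>. Peptide masses come from
  `pyteomics`; the recorded centroid equals the intensity-weighted mean of
  the emitted envelope to ≤ 10⁻⁶ Da, so generator truth and analysis input
  cannot drift apart.
* **Cohorts** — exponential event times with rate ln2/median per profile
  (defaults 2.3 and 8.5 months, cohort sizes 6 vs 70), censoring by an
  independent uniform time C ~ U(0, b) with b solved numerically so that
  P(C < T) equals the requested fraction in expectation, and descriptors
  drawn from the published cohort frequency tables so that re-classification
  round-trips the generating profile.

What the generators do **not** emulate: instrument drift and pipetting
error structure in plate reads, back-exchange and carbon-isotope fine
structure in mass spectra (combs carry deuterium spacing only), peptide
misidentification, and non-exponential hazards or informative censoring in
cohorts. Passing recovery tests therefore demonstrates correctness of the
estimators under their stated models, not robustness to every failure mode
of real instruments or registries.

## Problem sizes and numerical choices

Simulation studies use 200 replicates for parameter recovery (median
|error| thresholds: 10% for *K*<sub>M</sub>, *V*<sub>max</sub> and
*K*<sub>I</sub>; 15% for IC50) and 500 seeded cohort draws for log-rank
power — sizes at which the Monte-Carlo error is comfortably below the
thresholds while the full suite runs in seconds. Nonlinear fits use
positivity bounds and data-driven initialisation as described above;
degenerate inputs (flat curves, zero events, m_f = m_0, empty peptide sets)
are either handled with a defined convention or rejected with a specific
error type, as pinned by the unit tests.

## Known limitations

* The classification rule's domain is deletions/indels with non-negative
  net shortening inside the β3/αC loop; exon-20-like net insertions are
  rejected, not classified.
* Covalent inhibitors (afatinib, osimertinib) are described only by
  endpoint IC50s; no time-dependent (k<sub>inact</sub>/K<sub>I</sub>)
  modelling, so potencies cannot be compared across inhibitors.
* No global (integrated rate equation) progress-curve fitting; inference
  goes through initial velocities.
* HDX analysis starts from centroid tables or extracted envelopes; peptide
  identification, retention-time alignment and back-exchange correction
  beyond the *m*<sub>f</sub> normalisation are out of scope.
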