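"""Synthetic-data generators for every pipeline stage.

Raw plate-reader, HDX-MS and clinical data are not printed in summary
tables, so these generators produce inputs with the statistical structure
each analysis stage assumes, parameterised by published summary values:

* progress curves under a competitive-inhibition Michaelis–Menten rate law
  with substrate depletion, plus a known fluorescence calibration;
* dose–response tables from the one-parameter inhibition hyperbola;
* HDX-MS centroid series and isotope-comb envelopes with EX2 (binomial
  incorporation) or EX1 (two-population mixing) kinetics;
* exponential survival cohorts with per-profile medians, uniform independent
  censoring and descriptors drawn from published cohort frequency tables.

Every generator is a pure function of its scenario and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pyteomics import mass as _pmass
from scipy.optimize import brentq

from . import presets
from .hdx import (
    PROTON_MASS,
    CentroidSeries,
    DEFAULT_TIMEPOINTS,
    PepticPeptide,
    SpectralEnvelope,
)
from .kinetics import AssayConditions, CalibrationModel, ProgressCurve
from .survival import SurvivalRecord

D_MINUS_H = 1.00628  # Da added per incorporated deuterium


# --- kinetics ---------------------------------------------------------------

@dataclass(frozen=True)
class KineticsScenario:
    """Generating truth for a kinase assay simulation (published-value scale:
    kcat 1/s, K_M μM, K_I nM, enzyme nM)."""

    kcat: float = 0.91
    km_atp_uM: float = 23.0
    km_pept_uM: float = 15.0
    ki_nM: Dict[str, float] = field(
        default_factory=lambda: {"erlotinib": 5.3}
    )
    tkd_conc_nM: float = 100.0
    active_fraction: float = 1.0
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.active_fraction <= 1):
            raise ValueError("active_fraction must be in (0, 1]")
        if min(self.kcat, self.km_atp_uM, self.km_pept_uM, self.tkd_conc_nM) <= 0:
            raise ValueError("scenario parameters must be positive")


def initial_rate(
    scenario: KineticsScenario,
    atp_uM: float,
    pept_uM: float,
    inhibitor: Optional[str] = None,
    inhibitor_nM: float = 0.0,
) -> float:
    """Closed-form rate (μM/s) at zero product under the generating law."""
    km_eff = scenario.km_atp_uM
    if inhibitor is not None and inhibitor_nM > 0:
        km_eff *= 1.0 + inhibitor_nM / scenario.ki_nM[inhibitor]
    e_act_uM = scenario.tkd_conc_nM * scenario.active_fraction * 1e-3
    return (
        scenario.kcat
        * e_act_uM
        * (atp_uM / (km_eff + atp_uM))
        * (pept_uM / (scenario.km_pept_uM + pept_uM))
    )


def gen_progress_curve(
    scenario: KineticsScenario,
    atp_uM: float,
    pept_uM: float,
    inhibitor: Optional[str] = None,
    inhibitor_nM: float = 0.0,
    times_s: Optional[np.ndarray] = None,
    calibration: Optional[CalibrationModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> ProgressCurve:
    """Integrate d[P]/dt under competitive inhibition with substrate depletion.

    The ATP pool is treated as unchanged over the run (ATP in large excess);
    the peptide substrate depletes.  Small-step explicit (RK4) integration
    with internal refinement; multiplicative Gaussian noise of the scenario's
    CV; optionally converted to counts through a known calibration line.
    """
    if times_s is None:
        times_s = np.arange(0.0, 601.0, 15.0)
    times_s = np.asarray(times_s, dtype=float)
    km_eff = scenario.km_atp_uM
    if inhibitor is not None and inhibitor_nM > 0:
        km_eff *= 1.0 + inhibitor_nM / scenario.ki_nM[inhibitor]
    e_act_uM = scenario.tkd_conc_nM * scenario.active_fraction * 1e-3
    vcap = scenario.kcat * e_act_uM * (atp_uM / (km_eff + atp_uM))

    def dpdt(p: float) -> float:
        s = max(pept_uM - p, 0.0)
        return vcap * s / (scenario.km_pept_uM + s)

    # RK4 with fixed sub-steps fine relative to the sampling grid
    product = np.empty_like(times_s)
    p = 0.0
    product[0] = 0.0 if times_s[0] == 0 else np.nan
    t_prev = times_s[0]
    if times_s[0] != 0:  # integrate from zero up to the first sample
        p = _rk4_advance(dpdt, 0.0, 0.0, times_s[0])
        product[0] = p
    for i in range(1, len(times_s)):
        p = _rk4_advance(dpdt, p, t_prev, times_s[i])
        t_prev = times_s[i]
        product[i] = p

    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    if scenario.noise_cv > 0:
        product = product * (1.0 + scenario.noise_cv * rng.standard_normal(product.shape))
        product = np.clip(product, 0.0, pept_uM)
    signal = calibration.to_counts(product) if calibration is not None else product
    return ProgressCurve(
        times_s=times_s,
        signal=signal,
        conditions=AssayConditions(
            tkd_conc_nM=scenario.tkd_conc_nM,
            atp_conc_uM=atp_uM,
            peptide_conc_uM=pept_uM,
            inhibitor_name=inhibitor,
            inhibitor_conc_nM=inhibitor_nM,
        ),
    )


def _rk4_advance(f, p: float, t0: float, t1: float, max_step: float = 0.5) -> float:
    span = t1 - t0
    n = max(1, int(np.ceil(span / max_step)))
    h = span / n
    for _ in range(n):
        k1 = f(p)
        k2 = f(p + 0.5 * h * k1)
        k3 = f(p + 0.5 * h * k2)
        k4 = f(p + h * k3)
        p = p + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return p


def gen_progress_curves(
    scenario: KineticsScenario,
    atp_grid_uM: Sequence[float],
    pept_uM: float = 20.0,
    times_s: Optional[np.ndarray] = None,
    calibration: Optional[CalibrationModel] = None,
) -> List[ProgressCurve]:
    """One progress curve per ATP concentration (K_M,ATP titration layout)."""
    rng = np.random.default_rng(scenario.seed)
    return [
        gen_progress_curve(
            scenario, atp, pept_uM, times_s=times_s, calibration=calibration, rng=rng
        )
        for atp in atp_grid_uM
    ]


def gen_dose_response(
    ic50_nM: float,
    doses_nM: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Dose–response table (dose nM, rate %) from Rate = 100/(1+[TKI]/IC50)."""
    doses = np.asarray(doses_nM, dtype=float)
    rate = 100.0 / (1.0 + doses / ic50_nM)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        rate = rate * (1.0 + noise_cv * rng.standard_normal(rate.shape))
    return np.column_stack([doses, rate])


# --- HDX --------------------------------------------------------------------

@dataclass(frozen=True)
class HDXScenario:
    """Generating truth for one peptide's exchange behaviour.

    ``rate_per_s`` is the common per-amide exchange rate in the EX2 mode.
    ``ex1_opening_rate`` switches the peptide into the EX1 limit: the folded
    population decays as exp(-k_open t) and exchanges all amides at once.
    """

    sequence: str
    start_res: int
    charge: int = 2
    rate_per_s: float = 5e-3
    ex1_opening_rate: Optional[float] = None
    envelope_sigma_mz: float = 0.08
    max_labeling: float = 0.95  # D2O fraction: ceiling of per-amide uptake
    noise: float = 0.0  # additive, fraction of max envelope intensity
    timepoints_s: Tuple[float, ...] = DEFAULT_TIMEPOINTS
    seed: int = 0

    @property
    def peptide(self) -> PepticPeptide:
        end = self.start_res + len(self.sequence) - 1
        m = _pmass.calculate_mass(sequence=self.sequence, charge=0)
        return PepticPeptide(
            sequence=self.sequence,
            start_res=self.start_res,
            end_res=end,
            charge=self.charge,
            mono_mass_mh=m + PROTON_MASS,
        )


@dataclass(frozen=True)
class HDXSeriesTruth:
    peptide: PepticPeptide
    series: CentroidSeries
    envelopes: Tuple[SpectralEnvelope, ...]
    regime: str  # "EX1" or "EX2"
    folded_fraction: Tuple[float, ...]  # per timepoint (1.0 in EX2)


def _comb_envelope(
    m0: float,
    weights: np.ndarray,
    charge: int,
    sigma_mz: float,
    timepoint: float,
    mz_pad: float = 1.5,
    points_per_th: int = 200,
) -> SpectralEnvelope:
    """Gaussian-smoothed deuterium comb: peak j at (m0 + j*dD)/z + proton."""
    n = len(weights) - 1
    mz_lo = (m0) / charge + PROTON_MASS - mz_pad
    mz_hi = (m0 + n * D_MINUS_H) / charge + PROTON_MASS + mz_pad
    mz = np.linspace(mz_lo, mz_hi, int((mz_hi - mz_lo) * points_per_th) + 1)
    it = np.zeros_like(mz)
    for j, wgt in enumerate(weights):
        if wgt <= 0:
            continue
        mu = (m0 + j * D_MINUS_H) / charge + PROTON_MASS
        it += wgt * np.exp(-0.5 * ((mz - mu) / sigma_mz) ** 2)
    return SpectralEnvelope(mz=mz, intensity=it, charge=charge, timepoint_s=timepoint)


def gen_hdx_series(scenario: HDXScenario) -> HDXSeriesTruth:
    """Centroid series plus per-timepoint envelopes for one peptide.

    EX2 mode: each of the N exchangeable amides carries deuterium with
    probability ``max_labeling * (1 - exp(-k t))``; the envelope is the
    binomially weighted deuterium comb.  EX1 mode: a mixture of the t=0
    (folded) comb and the fully-exchanged (unfolded) comb with folded
    fraction exp(-k_open t).  Centroids are intensity-weighted means of the
    emitted envelopes, so generator truth and analysis input agree exactly.
    """
    pep = scenario.peptide
    n_amides = pep.exchangeable_amides
    m0 = pep.mono_mass_mh - PROTON_MASS
    rng = np.random.default_rng(scenario.seed)
    j = np.arange(n_amides + 1)

    def binom_weights(p: float) -> np.ndarray:
        from scipy.stats import binom

        return binom.pmf(j, n_amides, p)

    full = binom_weights(scenario.max_labeling)
    zero = binom_weights(0.0)

    envelopes: List[SpectralEnvelope] = []
    centroids: List[float] = []
    folded: List[float] = []
    for t in scenario.timepoints_s:
        if scenario.ex1_opening_rate is None:
            p = scenario.max_labeling * (1.0 - np.exp(-scenario.rate_per_s * t))
            w = binom_weights(p)
            f = 1.0
        else:
            f = float(np.exp(-scenario.ex1_opening_rate * t))
            w = f * zero + (1.0 - f) * full
        env = _comb_envelope(
            m0, w, pep.charge, scenario.envelope_sigma_mz, t
        )
        if scenario.noise > 0:
            noisy = env.intensity + scenario.noise * env.intensity.max() * rng.standard_normal(
                env.intensity.shape
            )
            env = SpectralEnvelope(
                mz=env.mz,
                intensity=np.clip(noisy, 1e-12, None),
                charge=pep.charge,
                timepoint_s=t,
            )
        envelopes.append(env)
        centroids.append(env.centroid_mass())
        folded.append(f)

    m_f = float(
        _comb_envelope(m0, full, pep.charge, scenario.envelope_sigma_mz, -1.0)
        .centroid_mass()
    )
    m_0 = float(
        _comb_envelope(m0, zero, pep.charge, scenario.envelope_sigma_mz, 0.0)
        .centroid_mass()
    )
    series = CentroidSeries(
        peptide=pep,
        timepoints_s=tuple(scenario.timepoints_s),
        m_t=tuple(centroids),
        m_0=m_0,
        m_f=m_f,
    )
    return HDXSeriesTruth(
        peptide=pep,
        series=series,
        envelopes=tuple(envelopes),
        regime="EX2" if scenario.ex1_opening_rate is None else "EX1",
        folded_fraction=tuple(folded),
    )


# --- survival cohorts -------------------------------------------------------

@dataclass(frozen=True)
class CohortScenario:
    """Exponential PFS cohort with per-profile medians and uniform censoring.

    Defaults follow the published erlotinib-treated cohort: 6 profile 1 vs
    70 profile 2 patients with median PFS 2.3 vs 8.5 months, and variant
    descriptors drawn from the published frequency tables.
    """

    n_per_profile: Dict[int, int] = field(
        default_factory=lambda: dict(presets.YALE_COHORT_SIZES)
    )
    median_months: Dict[int, float] = field(
        default_factory=lambda: dict(presets.GENIE_MEDIAN_PFS_MONTHS)
    )
    censoring_fraction: float = 0.0
    descriptor_freq: Dict[int, Dict[str, int]] = field(
        default_factory=lambda: {
            1: dict(presets.GENIE_COHORT_PROFILE1),
            2: dict(presets.GENIE_COHORT_PROFILE2),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.censoring_fraction < 1):
            raise ValueError("censoring fraction must be in [0, 1)")
        if any(m <= 0 for m in self.median_months.values()):
            raise ValueError("medians must be positive")


def _uniform_censor_bound(rate: float, target: float) -> float:
    """Upper bound b of C ~ U(0, b) with P(C < T) = target for T ~ Exp(rate)."""
    def frac(b: float) -> float:
        return (1.0 - np.exp(-rate * b)) / (rate * b) - target

    # frac -> 1 as b -> 0 and -> 0 as b -> inf; bracket and solve
    lo, hi = 1e-9, 1.0
    while frac(hi) > 0:
        hi *= 2.0
    return brentq(frac, lo, hi)


def gen_cohort(scenario: CohortScenario) -> List[SurvivalRecord]:
    """Simulate survival records; deterministic under the scenario seed."""
    rng = np.random.default_rng(scenario.seed)
    records: List[SurvivalRecord] = []
    for profile, n in sorted(scenario.n_per_profile.items()):
        rate = np.log(2.0) / scenario.median_months[profile]
        times = rng.exponential(1.0 / rate, size=n)
        if scenario.censoring_fraction > 0:
            b = _uniform_censor_bound(rate, scenario.censoring_fraction)
            censor = rng.uniform(0.0, b, size=n)
            event = (times <= censor).astype(int)
            obs = np.minimum(times, censor)
        else:
            event = np.ones(n, dtype=int)
            obs = times
        freq = scenario.descriptor_freq.get(profile, {})
        if freq:
            names = list(freq)
            probs = np.array([freq[k] for k in names], dtype=float)
            probs /= probs.sum()
            descs = rng.choice(names, size=n, p=probs)
        else:
            descs = [None] * n
        for i in range(n):
            records.append(
                SurvivalRecord(
                    id=f"p{profile}_{i:03d}",
                    time_months=float(max(obs[i], 1e-9)),
                    event=int(event[i]),
                    profile=profile,
                    variant_descriptor=None if descs[i] is None else str(descs[i]),
                )
            )
    return records
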