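"""Steady-state kinase kinetics and inhibition-parameter inference.

The estimator chain mirrors a standard continuous fluorescence kinase assay:

1. a calibration line converts fluorescence counts to μM phosphopeptide;
2. initial velocities ``v0`` are read from the linear steady-state phase of
   each progress curve;
3. ``v0`` versus substrate concentration is fit to the Michaelis–Menten
   equation ``v = Vmax [S] / (K_M + [S])``;
4. dose–response data are fit to the one-parameter inhibition hyperbola
   ``Rate = 100 / (1 + [TKI]/IC50)`` (top fixed at 100, Hill slope 1);
5. IC50 values measured at several ATP concentrations yield the inhibition
   constant of a competitive inhibitor through the Cheng–Prusoff relation
   ``IC50 = K_I (1 + [ATP]/K_M,ATP)``;
6. the turnover number is corrected for the active-enzyme fraction by an
   endpoint titration with the tight-binding covalent inhibitor afatinib,
   whose IC50 is taken as half the active enzyme concentration:
   ``kcat_corr = kcat_app * [TKD] / (2 * IC50_afatinib)``.

Units: concentrations of enzyme and inhibitor are nM, substrates μM,
velocities μM/s, turnover numbers 1/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats


class FitError(RuntimeError):
    """A least-squares fit failed or was underdetermined."""


class EstimationError(RuntimeError):
    """No data window satisfied the initial-velocity policy."""


class NonCompetitiveBehaviourWarning(UserWarning):
    """IC50 shows no dependence on [ATP]; competitive model inappropriate."""


class ActiveFractionWarning(UserWarning):
    """Estimated active fraction exceeds 1 (IC50_afatinib > [TKD]/2)."""


# --- calibration ------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from fluorescence counts to μM phosphopeptide."""

    slope: float  # counts per μM
    intercept: float  # counts
    fit_r2: float

    def to_counts(self, conc_uM: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(conc_uM, dtype=float) + self.intercept

    def to_conc(self, counts: np.ndarray) -> np.ndarray:
        return (np.asarray(counts, dtype=float) - self.intercept) / self.slope


def calibrate_fluorescence(
    standards: Sequence[Tuple[float, float]]
) -> CalibrationModel:
    """Fit an OLS line through (known μM, mean counts) standards."""
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise FitError("calibration needs at least two standards")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise FitError("calibration standards have identical concentrations")
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise FitError(f"non-positive calibration slope {res.slope:.3g}")
    r2 = 1.0 if len(x) == 2 else res.rvalue**2
    return CalibrationModel(slope=res.slope, intercept=res.intercept, fit_r2=r2)


# --- progress curves and initial velocities ---------------------------------

@dataclass(frozen=True)
class AssayConditions:
    tkd_conc_nM: float
    atp_conc_uM: float
    peptide_conc_uM: float
    inhibitor_name: Optional[str] = None
    inhibitor_conc_nM: float = 0.0


@dataclass(frozen=True)
class ProgressCurve:
    """Time course of product accumulation under fixed assay conditions."""

    times_s: np.ndarray
    signal: np.ndarray  # μM product (or counts before calibration)
    conditions: AssayConditions

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "signal", y)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class RateEstimate:
    v0: float  # μM/s
    window: Tuple[float, float]  # seconds
    r2: float
    n_points: int


def estimate_initial_velocity(
    curve: ProgressCurve,
    r2_threshold: float = 0.99,
    max_conversion: float = 0.10,
    min_points: int = 4,
) -> RateEstimate:
    """Slope of the longest early linear window of a progress curve.

    The default policy selects the longest prefix window whose linear fit has
    r² >= ``r2_threshold``, capped at the point where product exceeds
    ``max_conversion`` of the peptide concentration (substrate-depletion
    guard).  Flat (blank) curves are accepted: a window with negligible total
    signal change is reported with the fitted slope and r² of 1 by convention.
    """
    t, y = curve.times_s, curve.signal
    cap = curve.conditions.peptide_conc_uM * max_conversion
    within = y - y[0] <= cap
    n_cap = int(np.argmin(within)) if not within.all() else len(y)
    n_cap = max(n_cap, min_points)
    if len(t) < min_points:
        raise EstimationError(
            f"progress curve has {len(t)} points; policy needs >= {min_points}"
        )

    best = None
    for n in range(min_points, min(n_cap, len(t)) + 1):
        res = stats.linregress(t[:n], y[:n])
        flat = np.ptp(y[:n]) <= 1e-12 * max(1.0, abs(y[0]))
        r2 = 1.0 if flat else res.rvalue**2
        if r2 >= r2_threshold:
            best = RateEstimate(
                v0=max(res.slope, 0.0),
                window=(t[0], t[n - 1]),
                r2=r2,
                n_points=n,
            )
    if best is None:
        raise EstimationError(
            "no prefix window satisfied the linearity policy "
            f"(r2 >= {r2_threshold}, >= {min_points} points, "
            f"<= {max_conversion:.0%} conversion)"
        )
    return best


# --- Michaelis-Menten -------------------------------------------------------

@dataclass(frozen=True)
class MMFit:
    km: float  # μM
    vmax: float  # μM/s
    km_se: float
    vmax_se: float
    apparent_kcat: float  # 1/s
    tkd_conc_nM: float

    def rate(self, s_uM: np.ndarray) -> np.ndarray:
        s = np.asarray(s_uM, dtype=float)
        return self.vmax * s / (self.km + s)


def fit_michaelis_menten(
    points: Sequence[Tuple[float, float]], tkd_conc_nM: float
) -> MMFit:
    """Nonlinear least squares of v = Vmax [S] / (K_M + [S]).

    ``points`` are ([S] in μM, v0 in μM/s).  The apparent turnover number is
    Vmax divided by the total enzyme concentration (nM converted to μM).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        warnings.warn(
            "fewer than 4 substrate levels; Michaelis-Menten fit may be "
            "poorly constrained",
            UserWarning,
            stacklevel=2,
        )
    s, v = pts[:, 0], pts[:, 1]
    p0 = (np.median(s), v.max() if v.max() > 0 else 1e-6)
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, km, vmax: vmax * x / (km + x),
            s,
            v,
            p0=p0,
            bounds=([1e-12, 1e-15], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    km, vmax = popt
    se = np.sqrt(np.diag(pcov))
    if km > 10 * s.max() or km < s.min() / 10:
        warnings.warn(
            f"fitted K_M = {km:.3g} μM lies outside the substrate range "
            f"[{s.min():.3g}, {s.max():.3g}] by more than 10x",
            UserWarning,
            stacklevel=2,
        )
    return MMFit(
        km=km,
        vmax=vmax,
        km_se=se[0],
        vmax_se=se[1],
        apparent_kcat=vmax / (tkd_conc_nM * 1e-3),
        tkd_conc_nM=tkd_conc_nM,
    )


# --- IC50 -------------------------------------------------------------------

@dataclass(frozen=True)
class IC50Fit:
    ic50_nM: Optional[float]
    atp_conc_uM: Optional[float]
    inhibitor_name: Optional[str]
    censored: bool
    bound: Optional[str] = None  # e.g. ">40000" when only a bound is known

    def rate(self, tki_nM: np.ndarray) -> np.ndarray:
        if self.ic50_nM is None:
            raise ValueError("censored IC50 has no point estimate")
        return 100.0 / (1.0 + np.asarray(tki_nM, dtype=float) / self.ic50_nM)


def fit_ic50(
    points: Sequence[Tuple[float, float]],
    atp_conc_uM: Optional[float] = None,
    inhibitor_name: Optional[str] = None,
) -> IC50Fit:
    """One-parameter fit of Rate = 100 / (1 + [TKI]/IC50).

    ``points`` are ([TKI] in nM, rate as % of the uninhibited rate).  The
    censored flag is set when the highest tested concentration inhibits less
    than 50%; if every observed rate is above 80% (or below 20%) only a bound
    is reported and no point estimate is made.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        warnings.warn("fewer than 4 inhibitor levels", UserWarning, stacklevel=2)
    dose, rate = pts[:, 0], pts[:, 1]
    nz = dose > 0
    if np.all(rate[nz] > 80):
        return IC50Fit(None, atp_conc_uM, inhibitor_name, True, f">{dose.max():g}")
    if np.all(rate[nz] < 20):
        return IC50Fit(
            None, atp_conc_uM, inhibitor_name, True, f"<{dose[nz].min():g}"
        )
    # initial guess: dose whose rate is nearest 50%
    guess = dose[nz][np.argmin(np.abs(rate[nz] - 50.0))]
    try:
        popt, _ = optimize.curve_fit(
            lambda x, ic50: 100.0 / (1.0 + x / ic50),
            dose,
            rate,
            p0=(max(guess, 1e-6),),
            bounds=([1e-9], [np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"IC50 fit did not converge: {exc}") from exc
    ic50 = float(popt[0])
    top = dose.max()
    censored = 100.0 / (1.0 + top / ic50) > 50.0  # <50% inhibition at top dose
    return IC50Fit(
        ic50_nM=ic50,
        atp_conc_uM=atp_conc_uM,
        inhibitor_name=inhibitor_name,
        censored=censored,
        bound=f">{top:g}" if censored else None,
    )


# --- Cheng-Prusoff ----------------------------------------------------------

@dataclass(frozen=True)
class KIFit:
    ki_nM: float
    km_atp_uM: Optional[float]
    method: str  # "one-parameter" | "linear-regression"
    non_competitive_flag: bool = False


def predict_ic50(ki_nM: float, km_atp_uM: float, atp_uM: float) -> float:
    """Cheng-Prusoff forward prediction IC50 = K_I (1 + [ATP]/K_M,ATP)."""
    if ki_nM <= 0 or km_atp_uM <= 0 or atp_uM < 0:
        raise ValueError("Cheng-Prusoff arguments must be positive")
    return ki_nM * (1.0 + atp_uM / km_atp_uM)


def fit_ki_cheng_prusoff(
    series: Sequence[Tuple[float, float]],
    km_atp_uM: Optional[float] = None,
    flat_span_threshold: float = 0.2,
) -> KIFit:
    """Estimate K_I from IC50 measured at several ATP concentrations.

    ``series`` is ([ATP] in μM, IC50 in nM).  With ``km_atp_uM`` supplied the
    single free parameter K_I is fit by least squares to
    ``IC50 = K_I (1 + [ATP]/K_M,ATP)``; otherwise an unconstrained line is
    fit, with intercept K_I and slope K_I/K_M,ATP.

    A non-competitive flag is raised when the IC50 series is essentially flat
    across the ATP range (relative span below ``flat_span_threshold``) or the
    fitted slope is non-positive — behaviour inconsistent with a purely
    ATP-competitive inhibitor.
    """
    pts = np.asarray(series, dtype=float)
    if pts.shape[0] < 3:
        raise FitError("Cheng-Prusoff fit needs at least 3 ATP levels")
    atp, ic50 = pts[:, 0], pts[:, 1]
    span = (ic50.max() - ic50.min()) / np.mean(ic50)
    flat = span < flat_span_threshold

    if km_atp_uM is not None:
        x = 1.0 + atp / km_atp_uM
        ki = float(np.dot(x, ic50) / np.dot(x, x))
        if ki <= 0:
            raise FitError(f"non-positive K_I estimate {ki:.3g} nM")
        fit = KIFit(ki, km_atp_uM, "one-parameter", flat)
    else:
        res = stats.linregress(atp, ic50)
        if res.intercept <= 0:
            raise FitError(
                f"negative fitted intercept ({res.intercept:.3g} nM): "
                "inconsistent with competitive inhibition"
            )
        flat = flat or res.slope <= 0
        km = res.intercept / res.slope if res.slope > 0 else None
        fit = KIFit(float(res.intercept), km, "linear-regression", flat)
    if fit.non_competitive_flag:
        warnings.warn(
            "IC50 shows little or no dependence on [ATP]; non-competitive "
            "behaviour flagged",
            NonCompetitiveBehaviourWarning,
            stacklevel=2,
        )
    return fit


# --- active-site titration correction ---------------------------------------

@dataclass(frozen=True)
class ActiveSiteCorrection:
    afatinib_ic50_nM: float
    tkd_conc_nM: float
    active_conc_nM: float
    active_fraction: float
    apparent_kcat: float
    corrected_kcat: float
    warning: Optional[str] = None


def correct_kcat(
    apparent_kcat: float, tkd_conc_nM: float, afatinib_ic50_nM: float
) -> ActiveSiteCorrection:
    """Correct an apparent kcat for the active-enzyme fraction.

    The afatinib IC50 is treated as an endpoint titration of the active
    enzyme: IC50 = 50% of the active concentration, so
    ``active = 2 * IC50`` and
    ``kcat_corr = kcat_app * [TKD] / (2 * IC50_afatinib)``.
    """
    if min(apparent_kcat, tkd_conc_nM, afatinib_ic50_nM) <= 0:
        raise ValueError("all inputs to correct_kcat must be positive")
    active = 2.0 * afatinib_ic50_nM
    fraction = active / tkd_conc_nM
    note = None
    if fraction > 1.0:
        note = (
            f"active fraction {fraction:.2f} > 1 "
            "(afatinib IC50 exceeds half the enzyme concentration)"
        )
        warnings.warn(note, ActiveFractionWarning, stacklevel=2)
    return ActiveSiteCorrection(
        afatinib_ic50_nM=afatinib_ic50_nM,
        tkd_conc_nM=tkd_conc_nM,
        active_conc_nM=active,
        active_fraction=fraction,
        apparent_kcat=apparent_kcat,
        corrected_kcat=apparent_kcat / fraction,
        warning=note,
    )


# --- fold-change tables -----------------------------------------------------

def fold_change_table(
    summary: pd.DataFrame, reference_variant: str
) -> pd.DataFrame:
    """Fold changes of summary IC50 (or K_M) values versus a reference variant.

    ``summary`` must have columns ``variant, inhibitor, mean, sd, n``.  For
    every (variant, inhibitor) cell with a matching reference cell the fold
    ratio mean_variant / mean_reference is computed, its SD by first-order
    (delta-method) error propagation, and a two-sided unpaired Student's
    t-test from the summary statistics.  Cells without a point estimate
    (censored bounds) must be omitted from ``summary`` upstream.
    """
    required = {"variant", "inhibitor", "mean", "sd", "n"}
    if not required.issubset(summary.columns):
        raise ValueError(f"summary table needs columns {sorted(required)}")
    ref = summary[summary["variant"] == reference_variant].set_index("inhibitor")
    if ref.empty:
        raise ValueError(f"reference variant {reference_variant!r} not in table")
    rows = []
    for _, row in summary.iterrows():
        if row["inhibitor"] not in ref.index:
            continue
        r = ref.loc[row["inhibitor"]]
        if r["mean"] == 0:
            raise ZeroDivisionError(
                f"zero reference mean for {row['inhibitor']}: fold undefined"
            )
        fold = row["mean"] / r["mean"]
        fold_sd = abs(fold) * np.sqrt(
            (row["sd"] / row["mean"]) ** 2 + (r["sd"] / r["mean"]) ** 2
        )
        if row["n"] >= 2 and r["n"] >= 2:
            t, p = stats.ttest_ind_from_stats(
                row["mean"], row["sd"], row["n"], r["mean"], r["sd"], r["n"]
            )
        else:
            t, p = np.nan, np.nan
        rows.append(
            {
                "variant": row["variant"],
                "inhibitor": row["inhibitor"],
                "fold": fold,
                "fold_sd": fold_sd,
                "t_stat": t,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
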