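"""Hydrogen–deuterium exchange mass spectrometry (HDX-MS) analysis.

Peptide-level deuterium uptake is expressed as percent exchange

    %Ex = (m_t - m_0) / (m_f - m_0) * 100

where ``m_t`` is the centroid mass of a peptic peptide after labelling time
``t``, ``m_0`` the undeuterated centroid and ``m_f`` the fully-deuterated
reference centroid.  Peptide-level values are projected onto residues by the
shortest-covering-peptide rule, and the kinetic regime of each peptide is
diagnosed from its mass envelopes:

* **EX2** — frequent, short-lived opening events; a single envelope whose
  centroid drifts progressively to higher mass.
* **EX1** — long-lived local unfolding; two envelopes with (approximately)
  fixed positions whose *areas* interconvert over time.  The low-mass
  component reports the folded (exchange-incompetent) population, the
  high-mass component the unfolded (fully exchanged) population.
* **fused-bimodal** — two populations whose envelopes are insufficiently
  separated to resolve; intermediate behaviour.

Envelope deconvolution fits one or two Gaussians to the m/z profile and
selects between them with a corrected information criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.ndimage import gaussian_filter1d

PROTON_MASS = 1.007276

#: default labelling time grid, seconds
DEFAULT_TIMEPOINTS = (10.0, 60.0, 180.0, 600.0)


class DegenerateReferenceError(ValueError):
    """Fully-deuterated and undeuterated centroids coincide."""


class EnvelopeFitError(RuntimeError):
    pass


class RegimeInputError(ValueError):
    pass


# --- peptides and centroid series -------------------------------------------

@dataclass(frozen=True)
class PepticPeptide:
    sequence: str
    start_res: int
    end_res: int
    charge: int
    mono_mass_mh: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end_res - self.start_res + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match span "
                f"{self.start_res}-{self.end_res}"
            )
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def exchangeable_amides(self) -> int:
        """Backbone amides able to retain deuterium: length - 1 minus
        prolines after the first position (prolines have no amide NH)."""
        return len(self.sequence) - 1 - self.sequence[1:].count("P")

    @property
    def median_residue(self) -> float:
        return (self.start_res + self.end_res) / 2.0


def theoretical_max_uptake_mass(m0: float, peptide: PepticPeptide,
                                d2o_fraction: float = 0.95) -> float:
    """Convenience theoretical fully-deuterated centroid
    ``m_f = m_0 + d2o_fraction * exchangeable_amides * (m_D - m_H)``.
    Standard HDX convention; an experimental reference is preferred."""
    return m0 + d2o_fraction * peptide.exchangeable_amides * 1.00628


@dataclass(frozen=True)
class CentroidSeries:
    """Centroid masses of one peptide across labelling timepoints."""

    peptide: PepticPeptide
    timepoints_s: Tuple[float, ...]
    m_t: Tuple[float, ...]  # Da, one per timepoint
    m_0: float  # undeuterated centroid, Da
    m_f: float  # fully-deuterated centroid, Da
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoints_s) != len(self.m_t):
            raise ValueError("timepoints and centroids differ in length")
        if self.m_f <= self.m_0:
            raise ValueError("fully-deuterated centroid must exceed m_0")


@dataclass(frozen=True)
class ExchangeRecord:
    """Percent exchange time course for one peptide (replicate-aggregated)."""

    peptide: PepticPeptide
    timepoints_s: Tuple[float, ...]
    percent_exchange: Tuple[float, ...]
    sd: Tuple[float, ...]
    median_residue: float
    n_replicates: int = 1


def percent_exchange(
    series: Sequence[CentroidSeries] | CentroidSeries,
) -> ExchangeRecord:
    """Per-timepoint %Ex = (m_t - m_0)/(m_f - m_0) * 100.

    A single :class:`CentroidSeries` or a list of replicates may be given;
    replicates are aggregated as mean ± SD per timepoint.
    """
    if isinstance(series, CentroidSeries):
        series = [series]
    if not series:
        raise ValueError("no centroid series supplied")
    first = series[0]
    for s in series:
        if s.m_f == s.m_0:
            raise DegenerateReferenceError("m_f equals m_0; %Ex undefined")
        if s.timepoints_s != first.timepoints_s:
            raise ValueError("replicates must share the timepoint grid")
        if (s.peptide.start_res, s.peptide.end_res, s.peptide.charge) != (
            first.peptide.start_res,
            first.peptide.end_res,
            first.peptide.charge,
        ):
            raise ValueError("replicates must be the same peptide")
    ex = np.array(
        [
            [(mt - s.m_0) / (s.m_f - s.m_0) * 100.0 for mt in s.m_t]
            for s in series
        ]
    )
    return ExchangeRecord(
        peptide=first.peptide,
        timepoints_s=first.timepoints_s,
        percent_exchange=tuple(ex.mean(axis=0)),
        sd=tuple(ex.std(axis=0, ddof=1) if len(series) > 1 else np.zeros(ex.shape[1])),
        median_residue=first.peptide.median_residue,
        n_replicates=len(series),
    )


# --- residue mapping --------------------------------------------------------

@dataclass(frozen=True)
class ResidueAssignment:
    residue: int
    percent_exchange: Tuple[float, ...]
    source_span: Tuple[int, int]


@dataclass
class ResidueExchangeMap:
    timepoints_s: Tuple[float, ...]
    assignments: Dict[int, ResidueAssignment]
    uncovered: Tuple[int, ...] = ()


def map_to_residues(
    records: Sequence[ExchangeRecord],
    residue_range: Optional[Tuple[int, int]] = None,
) -> ResidueExchangeMap:
    """Assign each residue the %Ex of the shortest peptide covering it.

    Among equal-shortest covering peptides the one whose C-terminus extends
    furthest to the right is used (the peptide "retaining the overlapping
    region at its C-terminus"); any remaining tie is broken towards the
    later start, making the rule deterministic and independent of the input
    order.  Residues covered by no peptide are flagged, never interpolated.
    """
    if not records:
        return ResidueExchangeMap(timepoints_s=(), assignments={}, uncovered=())
    tp = records[0].timepoints_s
    for r in records:
        if r.timepoints_s != tp:
            raise ValueError("records must share the timepoint grid")
    if residue_range is None:
        residue_range = (
            min(r.peptide.start_res for r in records),
            max(r.peptide.end_res for r in records),
        )
    assignments: Dict[int, ResidueAssignment] = {}
    uncovered: List[int] = []
    for res in range(residue_range[0], residue_range[1] + 1):
        covering = [
            r for r in records if r.peptide.start_res <= res <= r.peptide.end_res
        ]
        if not covering:
            uncovered.append(res)
            continue
        chosen = min(
            covering,
            key=lambda r: (
                r.peptide.end_res - r.peptide.start_res,  # shortest
                -r.peptide.end_res,  # C-terminal retention
                -r.peptide.start_res,
            ),
        )
        assignments[res] = ResidueAssignment(
            residue=res,
            percent_exchange=chosen.percent_exchange,
            source_span=(chosen.peptide.start_res, chosen.peptide.end_res),
        )
    return ResidueExchangeMap(
        timepoints_s=tp, assignments=assignments, uncovered=tuple(uncovered)
    )


# --- envelope deconvolution -------------------------------------------------

@dataclass(frozen=True)
class SpectralEnvelope:
    mz: np.ndarray
    intensity: np.ndarray
    charge: int
    timepoint_s: float

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", it)
        if mz.shape != it.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if not np.isfinite(it).all() or it.sum() <= 0:
            raise ValueError("intensity must be finite with positive sum")

    def centroid_mz(self) -> float:
        return float(np.average(self.mz, weights=self.intensity))

    def centroid_mass(self) -> float:
        """Intensity-weighted neutral mass of the envelope."""
        return (self.centroid_mz() - PROTON_MASS) * self.charge


@dataclass(frozen=True)
class GaussianComponent:
    mean_mz: float
    width: float  # Gaussian sigma, Th
    area: float


@dataclass(frozen=True)
class BimodalFit:
    components: Tuple[GaussianComponent, ...]
    folded_fraction: float
    unfolded_fraction: float
    regime: str  # "unimodal" | "EX1" | "fused-bimodal"
    model_selection_score: float  # AICc(1-comp) - AICc(2-comp)
    timepoint_s: float = 0.0
    charge: int = 1


def _gauss(x: np.ndarray, mu: float, sigma: float, area: float) -> np.ndarray:
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _aicc(rss: float, n: int, k: int) -> float:
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def fit_envelope(
    envelope: SpectralEnvelope,
    max_components: int = 2,
    smooth_sigma_points: float = 0.0,
    fused_threshold: float = 1.5,
    selection_margin: float = 2.0,
) -> BimodalFit:
    """Fit one or two Gaussians to a mass envelope and pick the better model.

    Model selection uses the corrected Akaike criterion with a
    ``selection_margin``-point preference for the simpler model.  When the
    two-component model wins, the low-mass component is reported as the
    folded population and the high-mass one as unfolded; if their means are
    separated by less than ``fused_threshold`` times the pooled width the fit
    is labelled ``"fused-bimodal"``.

    Isotope-resolved combs should be smoothed first (``smooth_sigma_points``
    applies a Gaussian kernel, in grid points, before fitting).
    """
    mz = envelope.mz
    it = envelope.intensity.astype(float)
    if len(mz) < 10:
        raise EnvelopeFitError("envelope needs >= 10 sample points")
    if smooth_sigma_points > 0:
        it = gaussian_filter1d(it, smooth_sigma_points)
    w = it / it.sum()
    mu0 = float(np.dot(w, mz))
    sig0 = float(np.sqrt(np.dot(w, (mz - mu0) ** 2))) or (mz[-1] - mz[0]) / 10
    area0 = float(np.trapezoid(it, mz))

    # one-component fit
    try:
        p1, _ = optimize.curve_fit(
            _gauss, mz, it, p0=(mu0, sig0, area0),
            bounds=([mz[0], 1e-6, 0], [mz[-1], np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise EnvelopeFitError(f"single-Gaussian fit failed: {exc}") from exc
    rss1 = float(np.sum((it - _gauss(mz, *p1)) ** 2))
    aicc1 = _aicc(rss1, len(mz), 3)

    if max_components == 1:
        comp = GaussianComponent(*p1)
        return BimodalFit(
            components=(comp,), folded_fraction=1.0, unfolded_fraction=0.0,
            regime="unimodal", model_selection_score=0.0,
            timepoint_s=envelope.timepoint_s, charge=envelope.charge,
        )

    # two-component fit, initialised by splitting the envelope at its centroid
    def two(x, m1, s1, a1, m2, s2, a2):
        return _gauss(x, m1, s1, a1) + _gauss(x, m2, s2, a2)

    lo = mz <= mu0
    mu_lo = float(np.average(mz[lo], weights=it[lo])) if it[lo].sum() > 0 else mz[0]
    mu_hi = (
        float(np.average(mz[~lo], weights=it[~lo])) if it[~lo].sum() > 0 else mz[-1]
    )
    p0 = (mu_lo, sig0 / 2, area0 / 2, mu_hi, sig0 / 2, area0 / 2)
    try:
        p2, _ = optimize.curve_fit(
            two, mz, it, p0=p0,
            bounds=(
                [mz[0], 1e-6, 0, mz[0], 1e-6, 0],
                [mz[-1], np.inf, np.inf, mz[-1], np.inf, np.inf],
            ),
            maxfev=40000,
        )
        rss2 = float(np.sum((it - two(mz, *p2)) ** 2))
        aicc2 = _aicc(rss2, len(mz), 6)
    except RuntimeError:
        rss2, aicc2, p2 = np.inf, np.inf, None

    score = aicc1 - aicc2  # positive favours the two-component model
    if p2 is None or score <= selection_margin:
        comp = GaussianComponent(*p1)
        return BimodalFit(
            components=(comp,), folded_fraction=1.0, unfolded_fraction=0.0,
            regime="unimodal", model_selection_score=score if p2 is not None else 0.0,
            timepoint_s=envelope.timepoint_s, charge=envelope.charge,
        )
    c1 = GaussianComponent(p2[0], p2[1], p2[2])
    c2 = GaussianComponent(p2[3], p2[4], p2[5])
    folded, unfolded = (c1, c2) if c1.mean_mz <= c2.mean_mz else (c2, c1)
    total = folded.area + unfolded.area
    sep = unfolded.mean_mz - folded.mean_mz
    pooled = np.sqrt((folded.width**2 + unfolded.width**2) / 2)
    regime = "fused-bimodal" if sep < fused_threshold * pooled else "EX1"
    return BimodalFit(
        components=(folded, unfolded),
        folded_fraction=folded.area / total,
        unfolded_fraction=unfolded.area / total,
        regime=regime,
        model_selection_score=score,
        timepoint_s=envelope.timepoint_s,
        charge=envelope.charge,
    )


def comb_smoothing_points(
    envelope: SpectralEnvelope, spacing_fraction: float = 0.6
) -> float:
    """Gaussian-kernel sigma (grid points) that merges an isotope-resolved
    deuterium comb (peak spacing ~1.006/charge Th) into a smooth envelope:
    ``spacing_fraction`` of the comb spacing, converted to grid points."""
    step = float(np.median(np.diff(envelope.mz)))
    spacing = 1.00628 / envelope.charge
    return spacing_fraction * spacing / step


def classify_exchange_regime(
    fits: Sequence[BimodalFit],
    mean_stability_fraction: float = 0.25,
) -> str:
    """Classify a peptide's exchange regime from per-timepoint envelope fits.

    * ``"EX1"`` — at least two timepoints show well-separated two-component
      fits whose component means agree with the consensus (median) positions
      to within ``mean_stability_fraction`` of the consensus separation,
      while the component areas shift over time;
    * ``"fused-bimodal"`` — two-component fits recur with time-stable
      component positions but are insufficiently separated to resolve;
    * ``"EX2"`` — otherwise: the envelope (or its fitted components, when a
      skewed unimodal envelope is over-split into two) drifts progressively
      to higher mass.

    The consensus rule makes the call robust to single degenerate timepoints
    (e.g. when one population has nearly vanished and the fit splits the
    dominant envelope instead).
    """
    if len(fits) < 2:
        raise RegimeInputError("regime classification needs >= 2 timepoints")
    charges = {f.charge for f in fits}
    if len(charges) > 1:
        raise RegimeInputError(f"inconsistent charge states {sorted(charges)}")
    separated = [f for f in fits if len(f.components) == 2 and f.regime == "EX1"]
    two_comp = [f for f in fits if len(f.components) == 2]
    if len(separated) >= 2:
        mu_f = np.array([f.components[0].mean_mz for f in separated])
        mu_u = np.array([f.components[1].mean_mz for f in separated])
        ref_f, ref_u = float(np.median(mu_f)), float(np.median(mu_u))
        tol = mean_stability_fraction * (ref_u - ref_f)
        consistent = (np.abs(mu_f - ref_f) <= tol) & (np.abs(mu_u - ref_u) <= tol)
        if consistent.sum() >= 2:
            return "EX1"
    if len(two_comp) >= 2:
        # stable positions with shifting areas -> two real (fused) populations;
        # concerted drift to higher mass -> one population exchanging in EX2
        mu_f = np.array([f.components[0].mean_mz for f in two_comp])
        mu_u = np.array([f.components[1].mean_mz for f in two_comp])
        width = float(
            np.median([np.hypot(f.components[0].width, f.components[1].width)
                       / np.sqrt(2) for f in two_comp])
        )
        ref_f, ref_u = float(np.median(mu_f)), float(np.median(mu_u))
        consistent = (np.abs(mu_f - ref_f) <= 0.5 * width) & (
            np.abs(mu_u - ref_u) <= 0.5 * width
        )
        if consistent.sum() >= 2:
            return "fused-bimodal"
    return "EX2"


# --- differential exchange --------------------------------------------------

@dataclass(frozen=True)
class DifferentialExchange:
    peptide: PepticPeptide
    timepoints_s: Tuple[float, ...]
    delta_percent: Tuple[float, ...]  # variant mean - wild-type mean
    outside_band: Tuple[bool, ...]  # variant mean outside WT mean +/- SD


def differential_exchange(
    variant_records: Sequence[ExchangeRecord],
    wildtype_records: Sequence[ExchangeRecord],
) -> List[DifferentialExchange]:
    """Per-peptide difference in %Ex between a variant and wild type.

    Peptides are matched on (start, end, charge); unmatched peptides are
    excluded with a warning.  A timepoint is flagged when the variant mean
    lies outside the wild-type mean ± SD band.
    """
    def key(r: ExchangeRecord):
        return (r.peptide.start_res, r.peptide.end_res, r.peptide.charge)

    wt = {key(r): r for r in wildtype_records}
    out: List[DifferentialExchange] = []
    for rec in variant_records:
        ref = wt.get(key(rec))
        if ref is None:
            warnings.warn(
                f"peptide {rec.peptide.start_res}-{rec.peptide.end_res} "
                f"(z={rec.peptide.charge}) has no wild-type match; excluded",
                UserWarning,
                stacklevel=2,
            )
            continue
        if rec.timepoints_s != ref.timepoints_s:
            warnings.warn(
                f"peptide {key(rec)}: timepoint grids differ; excluded",
                UserWarning,
                stacklevel=2,
            )
            continue
        delta = tuple(
            v - w for v, w in zip(rec.percent_exchange, ref.percent_exchange)
        )
        flags = tuple(
            abs(v - w) > sd
            for v, w, sd in zip(rec.percent_exchange, ref.percent_exchange, ref.sd)
        )
        out.append(
            DifferentialExchange(
                peptide=rec.peptide,
                timepoints_s=rec.timepoints_s,
                delta_percent=delta,
                outside_band=flags,
            )
        )
    return out


# --- binding equilibrium ----------------------------------------------------

def ligand_occupancy(protein_uM: float, ligand_uM: float, kd_uM: float) -> float:
    """Exact two-state equilibrium fraction of protein bound by ligand.

    Solves the quadratic for the complex concentration:
    ``bound = ((P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)) / 2`` and returns
    ``bound / P``.  Used e.g. to confirm >90% inhibitor occupancy under
    labelling conditions.
    """
    if protein_uM <= 0 or kd_uM <= 0 or ligand_uM < 0:
        raise ValueError("concentrations must be positive (ligand may be 0)")
    if ligand_uM == 0:
        return 0.0
    b = protein_uM + ligand_uM + kd_uM
    bound = (b - np.sqrt(b * b - 4 * protein_uM * ligand_uM)) / 2
    return float(bound / protein_uM)
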