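"""Percent exchange, residue mapping, envelope deconvolution, occupancy."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from egfr19.hdx import (
    CentroidSeries,
    DegenerateReferenceError,
    PepticPeptide,
    RegimeInputError,
    SpectralEnvelope,
    classify_exchange_regime,
    comb_smoothing_points,
    differential_exchange,
    fit_envelope,
    ligand_occupancy,
    map_to_residues,
    percent_exchange,
    theoretical_max_uptake_mass,
)
from egfr19.simulate import HDXScenario, gen_hdx_series


def _pep(start=820, end=830, charge=2, seq=None):
    n = end - start + 1
    return PepticPeptide(
        sequence=seq or "A" * n, start_res=start, end_res=end, charge=charge
    )


def _series(m_t, m_0=1000.0, m_f=1010.0, **kw):
    return CentroidSeries(
        peptide=_pep(), timepoints_s=tuple(10.0 * (i + 1) for i in range(len(m_t))),
        m_t=tuple(m_t), m_0=m_0, m_f=m_f, **kw
    )


class TestPercentExchange:
    def test_endpoints_and_arithmetic(self):
        rec = percent_exchange(_series([1000.0, 1004.0, 1010.0]))
        assert rec.percent_exchange[0] == pytest.approx(0.0)
        assert rec.percent_exchange[1] == pytest.approx(40.0)
        assert rec.percent_exchange[2] == pytest.approx(100.0)
        assert rec.median_residue == 825.0

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            _series([1000.0], m_0=1000.0, m_f=1000.0)

    @given(st.floats(min_value=-50, max_value=50))
    def test_affine_invariance_mass_offset(self, delta):
        base = percent_exchange(_series([1002.0, 1007.0]))
        shifted = percent_exchange(
            _series([1002.0 + delta, 1007.0 + delta],
                    m_0=1000.0 + delta, m_f=1010.0 + delta)
        )
        assert np.allclose(base.percent_exchange, shifted.percent_exchange)

    def test_replicate_aggregation_mean_sd(self):
        reps = [
            _series([1004.0], replicate_id=0),
            _series([1006.0], replicate_id=1),
        ]
        rec = percent_exchange(reps)
        assert rec.percent_exchange[0] == pytest.approx(50.0)
        assert rec.sd[0] == pytest.approx(np.std([40.0, 60.0], ddof=1))
        assert rec.n_replicates == 2

    def test_theoretical_fully_deuterated_convention(self):
        pep = _pep(seq="ALPINESTRAP", start=820, end=830)
        # amides: 11 - 1 (N-term) - prolines after position 1 (2 of them)
        assert pep.exchangeable_amides == 8
        assert theoretical_max_uptake_mass(1000.0, pep) == pytest.approx(
            1000.0 + 0.95 * 8 * 1.00628
        )


def _record(start, end, value, charge=2):
    pep = _pep(start=start, end=end, charge=charge)
    return percent_exchange(
        CentroidSeries(
            peptide=pep, timepoints_s=(60.0,),
            m_t=(1000.0 + value / 10.0,), m_0=1000.0, m_f=1010.0,
        )
    )


class TestResidueMapping:
    def test_shortest_covering_peptide_wins(self):
        recs = [_record(820, 830, 20.0), _record(821, 827, 80.0)]
        rmap = map_to_residues(recs)
        assert rmap.assignments[825].percent_exchange[0] == pytest.approx(80.0)
        assert rmap.assignments[825].source_span == (821, 827)
        # residues only the long peptide covers fall back to it
        assert rmap.assignments[829].source_span == (820, 830)

    def test_equal_length_tie_prefers_c_terminal_retention(self):
        recs = [_record(820, 827, 30.0), _record(821, 828, 70.0)]
        rmap = map_to_residues(recs)
        assert rmap.assignments[824].source_span == (821, 828)
        assert rmap.assignments[824].percent_exchange[0] == pytest.approx(70.0)

    def test_single_peptide_and_uncovered_flagging(self):
        recs = [_record(820, 823, 55.0), _record(826, 828, 10.0)]
        rmap = map_to_residues(recs, residue_range=(819, 829))
        assert rmap.assignments[821].percent_exchange[0] == pytest.approx(55.0)
        assert set(rmap.uncovered) == {819, 824, 825, 829}

    def test_empty_input_gives_empty_map(self):
        rmap = map_to_residues([])
        assert rmap.assignments == {} and rmap.uncovered == ()

    @given(st.permutations(range(4)))
    def test_permutation_invariance(self, order):
        recs = [
            _record(820, 830, 20.0),
            _record(821, 827, 80.0),
            _record(823, 829, 50.0),
            _record(826, 831, 35.0),
        ]
        base = map_to_residues(recs)
        shuffled = map_to_residues([recs[i] for i in order])
        for res in base.assignments:
            assert (
                base.assignments[res].source_span
                == shuffled.assignments[res].source_span
            )


def _gauss_envelope(mz, comps, timepoint=10.0, charge=3, noise=0.0, rng=None):
    it = np.zeros_like(mz)
    for mu, sigma, area in comps:
        it += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((mz - mu) / sigma) ** 2
        )
    if noise > 0:
        it = it * (1 + noise * rng.standard_normal(it.shape))
        it = np.clip(it, 1e-12, None)
    return SpectralEnvelope(mz=mz, intensity=it, charge=charge, timepoint_s=timepoint)


class TestEnvelopeFitting:
    mz = np.linspace(730, 742, 800)

    def test_single_gaussian_selects_one_component(self):
        env = _gauss_envelope(self.mz, [(735.0, 0.5, 1.0)])
        fit = fit_envelope(env)
        assert fit.regime == "unimodal"
        assert len(fit.components) == 1
        assert fit.folded_fraction == 1.0

    @pytest.mark.parametrize("sep_widths", [2.0, 3.0, 4.0])
    @pytest.mark.parametrize("frac", [0.3, 0.6])
    def test_mixture_fraction_recovery(self, sep_widths, frac, rng):
        w = 0.5
        env = _gauss_envelope(
            self.mz,
            [(733.0, w, frac), (733.0 + sep_widths * w, w, 1 - frac)],
            noise=0.01, rng=rng,
        )
        fit = fit_envelope(env)
        assert len(fit.components) == 2
        assert fit.folded_fraction == pytest.approx(frac, abs=0.05)
        assert fit.components[1].mean_mz > fit.components[0].mean_mz

    def test_overlapping_mixture_flagged_fused(self):
        w = 1.2
        env = _gauss_envelope(self.mz, [(734.0, w, 0.6), (735.0, w, 0.4)])
        fit = fit_envelope(env)
        assert fit.regime == "fused-bimodal"

    def test_too_few_points_rejected(self):
        with pytest.raises(Exception):
            fit_envelope(
                SpectralEnvelope(
                    mz=np.linspace(730, 731, 5), intensity=np.ones(5),
                    charge=2, timepoint_s=10.0,
                )
            )


class TestRegimeClassification:
    def _fits(self, scenario):
        truth = gen_hdx_series(scenario)
        return [
            fit_envelope(env, smooth_sigma_points=comb_smoothing_points(env))
            for env in truth.envelopes
        ]

    def test_ex1_series_recovered(self):
        scenario = HDXScenario(
            sequence="HRDLAARNVLV", start_res=835, ex1_opening_rate=0.005
        )
        assert classify_exchange_regime(self._fits(scenario)) == "EX1"

    def test_ex2_series_recovered(self):
        scenario = HDXScenario(sequence="HRDLAARNVLV", start_res=835,
                               rate_per_s=5e-3)
        assert classify_exchange_regime(self._fits(scenario)) == "EX2"

    def test_single_timepoint_is_input_error(self):
        scenario = HDXScenario(sequence="HRDLAARNVLV", start_res=835)
        fits = self._fits(scenario)
        with pytest.raises(RegimeInputError):
            classify_exchange_regime(fits[:1])

    def test_inconsistent_charge_states_rejected(self):
        f1 = self._fits(HDXScenario(sequence="HRDLAARNVLV", start_res=835))
        f2 = self._fits(
            HDXScenario(sequence="HRDLAARNVLV", start_res=835, charge=3)
        )
        with pytest.raises(RegimeInputError):
            classify_exchange_regime([f1[0], f2[1]])


class TestDifferentialExchange:
    def test_identical_inputs_no_flags(self):
        wt = [_record(820, 830, 40.0)]
        diff = differential_exchange(wt, wt)
        assert diff[0].delta_percent[0] == pytest.approx(0.0)
        assert not any(diff[0].outside_band)

    def test_shift_beyond_band_flagged_within_band_not(self):
        def rec(val, sd_pair):
            pep = _pep(820, 830)
            reps = [
                CentroidSeries(peptide=pep, timepoints_s=(60.0,),
                               m_t=(1000.0 + v / 10.0,), m_0=1000.0, m_f=1010.0,
                               replicate_id=i)
                for i, v in enumerate(sd_pair)
            ]
            return percent_exchange(reps)

        wt = [rec(40.0, (38.0, 42.0))]  # mean 40, SD ~2.8
        shifted = [rec(50.0, (49.0, 51.0))]
        inside = [rec(41.0, (40.0, 42.0))]
        assert differential_exchange(shifted, wt)[0].outside_band[0]
        assert not differential_exchange(inside, wt)[0].outside_band[0]

    def test_unmatched_peptide_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="no wild-type match"):
            out = differential_exchange([_record(900, 910, 10.0)],
                                        [_record(820, 830, 10.0)])
        assert out == []


class TestLigandOccupancy:
    def test_labelling_condition_exceeds_90pct(self):
        frac = ligand_occupancy(0.39, 0.78, 0.005)
        assert frac == pytest.approx(0.987, abs=0.001)
        assert frac > 0.90

    def test_saturation_limit(self):
        assert ligand_occupancy(0.1, 1e6, 0.01) == pytest.approx(1.0, abs=1e-4)

    def test_no_ligand_no_binding(self):
        assert ligand_occupancy(0.5, 0.0, 0.01) == 0.0
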