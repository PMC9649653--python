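"""Published steady-state parameters for EGFR TKD variants.

These are the printed biochemical summary values for purified EGFR tyrosine
kinase domains carrying exon 19 variants (plus wild type and L858R controls),
used as generator presets, worked-example inputs and cross-checks.  IC50
values were measured at 1 mM ATP with 10 μM peptide substrate.

``ic50_assay_tkd_nM`` is the enzyme concentration of the IC50/afatinib
titration assay (100 nM for all variants except ΔL747-E749, which required
1 μM enzyme; its published IC50s are presentation-scale, i.e. divided by 10,
and ``afatinib_ic50_assay_scale_nM`` restores the assay-scale value used in
all arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple


@dataclass(frozen=True)
class VariantKinetics:
    descriptor: str
    profile: Optional[int]  # None for wild type / exon 21 controls
    ic50_erlotinib_nM: Optional[float]
    ic50_afatinib_nM: Optional[float]
    ic50_osimertinib_nM: Optional[float]  # None when only a bound is known
    ic50_osimertinib_bound: Optional[str]
    ki_erlotinib_nM: Optional[float]
    km_atp_uM: Optional[float]
    km_atp_sd_uM: Optional[float]
    km_pept_uM: Optional[float]
    apparent_kcat: Optional[float]  # 1/s
    corrected_kcat: Optional[float]  # 1/s, printed
    ic50_assay_tkd_nM: float = 100.0
    ic50_presentation_scale: float = 1.0  # published IC50 = assay-scale / this

    @property
    def afatinib_ic50_assay_scale_nM(self) -> Optional[float]:
        if self.ic50_afatinib_nM is None:
            return None
        return self.ic50_afatinib_nM * self.ic50_presentation_scale


TABLE: Tuple[VariantKinetics, ...] = (
    VariantKinetics("wild type", None, None, None, None, None, None,
                    12.0, 3.0, 406.0, 0.042, 0.042),
    # profile 1
    VariantKinetics("ΔL747-A750InsP", 1, 232.0, 36.0, 65.0, None, 5.3,
                    23.0, 6.0, 15.0, 0.91, 1.26),
    VariantKinetics("L747P", 1, 141.0, 37.0, 159.0, None, 6.2,
                    21.0, 6.0, 52.0, 0.84, 1.14),
    VariantKinetics("ΔL747-E749", 1, 108.0, 42.0, None, ">1000", None,
                    13.0, 8.0, None, 0.044, 0.052,
                    ic50_assay_tkd_nM=1000.0, ic50_presentation_scale=10.0),
    # profile 2
    VariantKinetics("ΔE746-A750", 2, 31.0, 27.0, 37.0, None, None,
                    158.0, 24.0, 261.0, 0.60, 1.11),
    VariantKinetics("ΔE746-T751InsA", 2, 20.0, 8.0, 11.0, None, None,
                    240.0, 59.0, 156.0, 0.12, 0.75),
    VariantKinetics("ΔL747-T751InsP", 2, 14.0, 6.0, 7.0, None, None,
                    164.0, 48.0, 38.0, 0.16, 1.33),
    VariantKinetics("ΔL747-P753InsS", 2, 37.0, 23.0, 26.0, None, 4.2,
                    101.0, 22.0, 292.0, 0.49, 1.07),
    VariantKinetics("ΔS752-I759", 2, 25.0, 20.0, 22.0, None, None,
                    91.0, 25.0, 80.0, 1.2, 3.0),
    # exon 21 controls
    VariantKinetics("L858R", None, 75.0, 23.0, 52.0, None, 4.7,
                    74.0, 14.0, 218.0, 1.4, 3.04),
    VariantKinetics("L858R/T790M", None, 10000.0, 92.0, 101.0, None, 41.0,
                    45.0, 6.0, 99.0, 6.6, None,
                    ic50_assay_tkd_nM=5.0),
)


def get(descriptor: str) -> VariantKinetics:
    for row in TABLE:
        if row.descriptor == descriptor:
            return row
    raise KeyError(descriptor)


#: Variant descriptors of the erlotinib-treated GENIE+ cohort, with patient
#: counts, grouped by predicted profile.
GENIE_COHORT_PROFILE1 = {"ΔL747-A750InsP": 4, "ΔE746-L747InsIP": 1}
GENIE_COHORT_PROFILE2 = {
    "ΔE746-A750": 43, "ΔL747-P753InsS": 5, "ΔL747-T751": 3,
    "ΔE746-S752InsV": 3, "ΔS752-I759": 2, "ΔL747-S752": 2,
    "ΔE746-S752InsI": 1, "ΔE746-T751InsA": 1, "ΔL747-T751InsP": 1,
    "ΔE746-T751InsIP": 1,
}

#: Variant descriptors of the erlotinib-treated Yale cohort, with counts.
YALE_COHORT_PROFILE1 = {"ΔL747-A750InsP": 6}
YALE_COHORT_PROFILE2 = {
    "ΔE746-A750": 55, "ΔL747-P753InsS": 5, "ΔL747-T751": 3,
    "ΔL747-T751InsP": 2, "ΔE746-S752InsV": 1, "ΔL747-T751InsA": 1,
    "ΔL747-S752": 1, "ΔE746-T751InsVP": 1, "ΔT751-I759InsN": 1,
}

#: Published median progression-free survival (months) on erlotinib for the
#: GENIE+ cohort, by profile: used as synthetic-cohort generator defaults.
GENIE_MEDIAN_PFS_MONTHS = {1: 2.3, 2: 8.5}
YALE_MEDIAN_PFS_MONTHS = {1: 1.8, 2: 9.8}
YALE_COHORT_SIZES = {1: 6, 2: 70}
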