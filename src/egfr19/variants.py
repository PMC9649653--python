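"""Parsing and classification of EGFR exon 19 variants.

EGFR exon 19 encodes the loop connecting kinase-domain strand beta-3 to the
regulatory alpha-C helix.  In-frame deletions and indels in this loop are
common oncogenic drivers in non-small cell lung cancer, and their sensitivity
to ATP-competitive tyrosine kinase inhibitors (TKIs) tracks with how many
residues the loop loses on net:

* **profile 1** — net loop shortening of at most 3 residues.  These variants
  retain wild-type-like ATP affinity (low ``K_M,ATP``) and show primary
  resistance to erlotinib and osimertinib.
* **profile 2** — net shortening of 4 or more residues.  ATP affinity is
  reduced (raised ``K_M,ATP``), which sensitises the kinase to
  ATP-competitive TKIs.

A proline introduced into the loop (by insertion or substitution, e.g.
``L747P``) can activate the kinase even when the shortening is small, so the
classifier also carries a proline flag and an activation heuristic.

Residue numbering follows the UniProt P00533 precursor sequence; mature-chain
numbers are 24 lower (the signal peptide is cleaved).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

MATURE_OFFSET = 24

#: K745..E762 of the EGFR precursor (UniProt P00533): the beta-3/alpha-C loop
#: plus the flanking catalytic lysine (K745) and alpha-C glutamate (E762).
DEFAULT_REFERENCE_START = 745
DEFAULT_REFERENCE_SEQUENCE = "KELREATSPKANKEILDE"
DEFAULT_LOOP_REGION = (746, 759)

# Canonical identities used to sanity-check any user-supplied reference.
_ANCHOR_RESIDUES = {
    745: "K", 746: "E", 747: "L", 748: "R", 749: "E", 750: "A", 751: "T",
    752: "S", 753: "P", 754: "K", 755: "A", 756: "N", 757: "K", 758: "E",
    759: "I", 762: "E",
}


class VariantError(ValueError):
    """Base class for variant parsing/validation failures."""


class VariantParseError(VariantError):
    """Descriptor text could not be parsed; message names the bad token."""


class ReferenceMismatchError(VariantError):
    """A stated reference residue disagrees with the reference sequence."""


class CoordinateRangeError(VariantError):
    """A residue index falls outside the reference interval (or is <= 0)."""


class UnsupportedVariantError(VariantError):
    """Variant lies outside the classification rule's domain."""


class LoopWindowWarning(UserWarning):
    """Deletion extends beyond the configured beta-3/alpha-C window."""


@dataclass(frozen=True)
class ReferenceContext:
    """Reference sequence and numbering for the beta-3/alpha-C region.

    Parameters
    ----------
    numbering_scheme:
        ``"precursor"`` (UniProt P00533) or ``"mature"`` (precursor - 24).
    loop_region:
        Inclusive residue interval treated as the beta-3/alpha-C loop for
        classification purposes (default E746-I759).
    reference_start:
        Precursor index of the first residue of ``reference_sequence``.
    reference_sequence:
        One-letter amino-acid string for the covered interval.
    """

    numbering_scheme: str = "precursor"
    loop_region: Tuple[int, int] = DEFAULT_LOOP_REGION
    reference_start: int = DEFAULT_REFERENCE_START
    reference_sequence: str = DEFAULT_REFERENCE_SEQUENCE

    def __post_init__(self) -> None:
        if self.numbering_scheme not in ("precursor", "mature"):
            raise ValueError(f"unknown numbering scheme {self.numbering_scheme!r}")
        for pos, aa in _ANCHOR_RESIDUES.items():
            if self.contains(pos) and self.residue(pos) != aa:
                raise ReferenceMismatchError(
                    f"reference residue at {pos} is {self.residue(pos)!r}, expected {aa!r}"
                )

    @property
    def reference_end(self) -> int:
        return self.reference_start + len(self.reference_sequence) - 1

    def contains(self, index: int) -> bool:
        return self.reference_start <= index <= self.reference_end

    def residue(self, index: int) -> str:
        """One-letter code at a precursor residue index."""
        if not self.contains(index):
            raise CoordinateRangeError(
                f"residue {index} outside reference interval "
                f"{self.reference_start}-{self.reference_end}"
            )
        return self.reference_sequence[index - self.reference_start]


def convert_numbering(index: int, direction: str) -> int:
    """Convert a residue index between precursor and mature EGFR numbering.

    Precursor numbers (UniProt P00533) are 24 greater than mature-chain
    numbers because the 24-residue signal peptide is removed.

    ``direction`` is ``"precursor_to_mature"`` or ``"mature_to_precursor"``.
    """
    if index <= 0:
        raise CoordinateRangeError(f"residue index must be positive, got {index}")
    if direction in ("precursor_to_mature", "precursor->mature"):
        result = index - MATURE_OFFSET
    elif direction in ("mature_to_precursor", "mature->precursor"):
        result = index + MATURE_OFFSET
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if result <= 0:
        raise CoordinateRangeError(
            f"conversion of {index} ({direction}) gives non-positive index {result}"
        )
    return result


@dataclass(frozen=True)
class Exon19Variant:
    """A parsed protein-level exon 19 variant (deletion/indel/substitution)."""

    raw_descriptor: str
    deletion_start: Optional[int] = None
    deletion_end: Optional[int] = None
    inserted_sequence: str = ""
    substitution: Optional[Tuple[int, str, str]] = None  # (position, ref, alt)

    @property
    def deleted_count(self) -> int:
        if self.deletion_start is None:
            return 0
        return self.deletion_end - self.deletion_start + 1

    @property
    def net_loop_shortening(self) -> int:
        return self.deleted_count - len(self.inserted_sequence)

    @property
    def is_substitution(self) -> bool:
        return self.substitution is not None

    def format(self) -> str:
        """Canonical re-serialisation (delta notation, or ``L747P`` style)."""
        if self.is_substitution:
            pos, ref, alt = self.substitution
            return f"{ref}{pos}{alt}"
        if self.deletion_start is None:
            return ""
        core = f"Δ{self._ref_letter_start}{self.deletion_start}"
        if self.deletion_end != self.deletion_start:
            core += f"-{self._ref_letter_end}{self.deletion_end}"
        if self.inserted_sequence:
            core += f"Ins{self.inserted_sequence}"
        return core

    # reference letters recorded at parse time so format() round-trips
    _ref_letter_start: str = field(default="", compare=False)
    _ref_letter_end: str = field(default="", compare=False)


@dataclass(frozen=True)
class ProfileCall:
    """Profile 1/2 classification of an exon 19 variant."""

    profile: int
    net_loop_shortening: int
    proline_introduced: bool
    activation_predicted: bool
    rationale: str


# --- descriptor grammar -----------------------------------------------------

_DELTA_CHARS = "Δ∆"  # GREEK CAPITAL DELTA, INCREMENT
_DASH_CHARS = "–—−"  # en dash, em dash, minus

_SUB_RE = re.compile(r"([A-Z])(\d+)([A-Z])\Z")
_HGVS_RE = re.compile(
    r"(?:p\.)?([A-Z])(\d+)(?:_([A-Z])(\d+))?DEL(?:INS([A-Z]+))?\Z", re.IGNORECASE
)
_DELTA_RE = re.compile(
    r"DEL\s*([A-Z])(\d+)(?:-([A-Z])(\d+))?(?:INS([A-Z]+))?\Z", re.IGNORECASE
)


def _normalize(descriptor: str) -> str:
    s = descriptor.strip()
    for ch in _DELTA_CHARS:
        s = s.replace(ch, "del")
    for ch in _DASH_CHARS:
        s = s.replace(ch, "-")
    return re.sub(r"\s+", "", s)


def parse_variant(
    descriptor: str, context: Optional[ReferenceContext] = None
) -> Exon19Variant:
    """Parse an exon 19 variant descriptor and validate it against a reference.

    Accepts delta notation (``ΔE746-A750``, ``ΔL747-A750InsP``), HGVS-like
    protein notation (``E746_A750del``, ``L747_A750delinsP``) and single
    residue substitutions (``L747P``).  Keywords are case-insensitive; the
    Unicode delta and an ASCII ``del`` prefix are interchangeable, as are
    hyphen and en-dash range separators.
    """
    if context is None:
        context = ReferenceContext()
    if not descriptor or not descriptor.strip():
        raise VariantParseError("empty variant descriptor")
    s = _normalize(descriptor)

    m = _SUB_RE.fullmatch(s)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        _check_reference(context, pos, ref, descriptor)
        return Exon19Variant(raw_descriptor=descriptor, substitution=(pos, ref, alt))

    m = _HGVS_RE.fullmatch(s) or _DELTA_RE.fullmatch(s)
    if m is None:
        raise VariantParseError(
            f"cannot parse variant descriptor {descriptor!r} (token {s!r})"
        )
    start_aa, start = m.group(1).upper(), int(m.group(2))
    if m.group(3) is not None:
        end_aa, end = m.group(3).upper(), int(m.group(4))
    else:
        end_aa, end = start_aa, start
    inserted = (m.group(5) or "").upper()

    if end < start:
        raise VariantParseError(
            f"deletion end {end} precedes start {start} in {descriptor!r}"
        )
    _check_reference(context, start, start_aa, descriptor)
    _check_reference(context, end, end_aa, descriptor)
    for pos in range(start, end + 1):
        context.residue(pos)  # raises CoordinateRangeError if outside

    lo, hi = context.loop_region
    in_window = [p for p in range(start, end + 1) if lo <= p <= hi]
    if len(in_window) < (end - start + 1):
        if in_window:
            warnings.warn(
                f"{descriptor!r}: deletion extends beyond the configured "
                f"loop window {lo}-{hi}; classifying on the full deletion",
                LoopWindowWarning,
                stacklevel=2,
            )
        else:
            warnings.warn(
                f"{descriptor!r}: deletion lies entirely outside the loop "
                f"window {lo}-{hi}",
                LoopWindowWarning,
                stacklevel=2,
            )

    return Exon19Variant(
        raw_descriptor=descriptor,
        deletion_start=start,
        deletion_end=end,
        inserted_sequence=inserted,
        _ref_letter_start=start_aa,
        _ref_letter_end=end_aa,
    )


def _check_reference(
    context: ReferenceContext, pos: int, stated: str, descriptor: str
) -> None:
    actual = context.residue(pos)  # CoordinateRangeError if outside interval
    if actual != stated.upper():
        raise ReferenceMismatchError(
            f"{descriptor!r}: stated residue {stated}{pos} does not match "
            f"reference {actual}{pos}"
        )


def apply_variant(variant: Exon19Variant, context: Optional[ReferenceContext] = None) -> str:
    """Return the mutant sequence of the reference interval.

    The deleted interval is removed and any inserted residues are spliced at
    the deletion site; a substitution replaces one letter.  The output length
    is the reference length minus the net loop shortening.
    """
    if context is None:
        context = ReferenceContext()
    seq = context.reference_sequence
    if variant.is_substitution:
        pos, ref, alt = variant.substitution
        _check_reference(context, pos, ref, variant.raw_descriptor)
        i = pos - context.reference_start
        return seq[:i] + alt + seq[i + 1 :]
    if variant.deletion_start is None:
        return seq
    i = variant.deletion_start - context.reference_start
    j = variant.deletion_end - context.reference_start + 1
    return seq[:i] + variant.inserted_sequence + seq[j:]


def classify_profile(variant: Exon19Variant) -> ProfileCall:
    """Assign profile 1 (net shortening <= 3) or profile 2 (>= 4).

    Profile 2 variants have raised ``K_M,ATP`` and are sensitive to erlotinib
    and osimertinib; profile 1 variants retain wild-type-like ATP affinity and
    show primary resistance to those TKIs (afatinib sensitivity is similar in
    both groups).  A proline introduced into the loop predicts kinase
    activation even for short deletions, hence
    ``activation_predicted = (profile 2) or proline_introduced``.
    """
    net = variant.net_loop_shortening
    if net < 0:
        raise UnsupportedVariantError(
            f"{variant.raw_descriptor!r}: net insertion ({-net} residues) is "
            "outside the deletion-length classification rule"
        )
    proline = "P" in variant.inserted_sequence or (
        variant.is_substitution and variant.substitution[2] == "P"
    )
    profile = 1 if net <= 3 else 2
    rationale = (
        f"net beta3/alphaC loop shortening of {net} residue(s) "
        f"({'<= 3' if profile == 1 else '>= 4'}) -> profile {profile}"
        + ("; proline introduced" if proline else "")
    )
    return ProfileCall(
        profile=profile,
        net_loop_shortening=net,
        proline_introduced=proline,
        activation_predicted=(profile == 2) or proline,
        rationale=rationale,
    )


def classify_descriptor(
    descriptor: str, context: Optional[ReferenceContext] = None
) -> ProfileCall:
    """Convenience: parse then classify a descriptor string."""
    return classify_profile(parse_variant(descriptor, context))
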