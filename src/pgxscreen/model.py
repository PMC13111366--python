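"""Domain model for aggregate pharmacogene frequency screening.

The central objects mirror what an aggregate variant browser exports for a
single gene: one row per variant with a ``chrom-pos-ref-alt`` identifier
(GRCh38, 1-based), an rsID, a ClinVar significance class, and an allele
frequency spectrum (overall cohort plus seven genetic-ancestry subgroups).
Star-allele haplotype definitions (PharmVar-style) are modelled separately
as sub-alleles carrying curation evidence levels and defining rsID sets.

Frequencies are held as :class:`decimal.Decimal`, parsed from the printed
strings without renormalisation, so that downstream subgroup-minus-overall
differences are exact arithmetic on the published values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "AncestryCategory",
    "AncestrySpectrum",
    "CohortMetadata",
    "HaplotypeTable",
    "EvidenceLevel",
    "SignificanceClass",
    "SubAllele",
    "VariantId",
    "VariantIdError",
    "VariantRecord",
    "format_variant_id",
    "parse_variant_id",
    "star_allele_sort_key",
]

_ACGT = re.compile(r"[ACGT]+\Z")
_RSID = re.compile(r"rs[0-9]+\Z")
_STAR = re.compile(r"CYP2D6\*[0-9]+\Z")


class AncestryCategory(Enum):
    """The seven genetic-ancestry subgroups of the aggregate cohort.

    ``LATIN_AMERICAN`` and ``OTHER`` carry the browser's display aliases
    ("Americas" and "Remaining" respectively); :meth:`from_label` resolves
    canonical names, aliases and column-style tokens alike.
    """

    AFRICAN = "African"
    EAST_ASIAN = "East Asian"
    EUROPEAN = "European"
    LATIN_AMERICAN = "Latin American"
    MIDDLE_EASTERN = "Middle Eastern"
    SOUTH_ASIAN = "South Asian"
    OTHER = "Other"

    @property
    def alias(self) -> str:
        """Browser display alias (differs from the name for two categories)."""
        return _ALIASES.get(self, self.value)

    @property
    def token(self) -> str:
        """Lower-snake token used in column names (``east_asian`` ...)."""
        return self.value.lower().replace(" ", "_")

    @classmethod
    def from_label(cls, label: str) -> "AncestryCategory":
        key = label.strip().lower().replace("_", " ")
        try:
            return _LABELS[key]
        except KeyError:
            raise ValueError(f"unknown ancestry category: {label!r}") from None


_ALIASES = {
    AncestryCategory.LATIN_AMERICAN: "Americas",
    AncestryCategory.OTHER: "Remaining",
}
_LABELS: dict[str, AncestryCategory] = {}
for _cat in AncestryCategory:
    _LABELS[_cat.value.lower()] = _cat
    _LABELS[_cat.alias.lower()] = _cat


class SignificanceClass(Enum):
    """ClinVar significance classes tracked by the browser export.

    ``UNDEFINED`` is the browser's default for variants with no submitted
    interpretation.
    """

    DRUG_RESPONSE = "drug_response"
    UNDEFINED = "undefined"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    OTHER = "other"

    @classmethod
    def from_label(cls, label: str) -> "SignificanceClass":
        key = label.strip().lower().replace(" ", "_")
        for member in cls:
            if member.value == key:
                return member
        raise ValueError(f"unknown significance class: {label!r}")


class EvidenceLevel(Enum):
    """PharmVar haplotype-curation evidence tiers (attached to sub-alleles)."""

    DEFINITIVE = "Definitive"
    MODERATE = "Moderate"
    LIMITED = "Limited"
    UNKNOWN = "Unknown"

    @classmethod
    def from_label(cls, label: str) -> "EvidenceLevel":
        for member in cls:
            if member.value.lower() == label.strip().lower():
                return member
        raise ValueError(f"unknown evidence level: {label!r}")


class VariantIdError(ValueError):
    """Raised for malformed ``chrom-pos-ref-alt`` variant identifiers."""


@dataclass(frozen=True, order=True)
class VariantId:
    """A ``chrom-pos-ref-alt`` identifier (GRCh38, 1-based).

    Multi-base ref/alt strings are preserved verbatim; no left-normalisation
    is applied, so the identifier is an opaque key after validation.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantIdError(f"position must be >= 1, got {self.pos}")
        for name in ("ref", "alt"):
            allele = getattr(self, name)
            if not allele or not _ACGT.match(allele):
                raise VariantIdError(
                    f"{name} allele must be nonempty A/C/G/T, got {allele!r}"
                )
        if self.ref == self.alt:
            raise VariantIdError(f"ref equals alt ({self.ref!r})")

    def __str__(self) -> str:
        return format_variant_id(self)


def parse_variant_id(text: str) -> VariantId:
    """Parse ``"22-42126611-C-G"`` into a :class:`VariantId`.

    Raises :class:`VariantIdError` naming the offending field on malformed
    input (wrong field count, non-numeric position, non-ACGT alleles).
    """
    fields = text.strip().split("-")
    if len(fields) != 4:
        raise VariantIdError(
            f"expected 4 dash-delimited fields (chrom-pos-ref-alt), "
            f"got {len(fields)} in {text!r}"
        )
    chrom, pos_text, ref, alt = fields
    if not chrom:
        raise VariantIdError(f"empty chromosome field in {text!r}")
    try:
        pos = int(pos_text)
    except ValueError:
        raise VariantIdError(f"non-integer position {pos_text!r} in {text!r}") from None
    return VariantId(chrom=chrom, pos=pos, ref=ref, alt=alt)


def format_variant_id(v: VariantId) -> str:
    """Dash-joined canonical form; inverse of :func:`parse_variant_id`."""
    return f"{v.chrom}-{v.pos}-{v.ref}-{v.alt}"


@dataclass(frozen=True)
class AncestrySpectrum:
    """Overall cohort frequency plus per-subgroup frequencies.

    A complete spectrum carries all seven subgroups. Records from browsers
    that suppress low-count cells may be *partial*: missing subgroups are
    simply absent from ``by_subgroup`` and downstream screening skips them.
    """

    overall: Decimal
    by_subgroup: Mapping[AncestryCategory, Decimal]
    partial: bool = False

    def __post_init__(self) -> None:
        vals = [self.overall, *self.by_subgroup.values()]
        for v in vals:
            if not (0 <= v <= 1):
                raise ValueError(f"frequency out of [0,1]: {v}")
        missing = set(AncestryCategory) - set(self.by_subgroup)
        if missing and not self.partial:
            names = ", ".join(sorted(c.value for c in missing))
            raise ValueError(f"incomplete spectrum (missing {names}) "
                             "not marked partial")
        object.__setattr__(self, "by_subgroup", dict(self.by_subgroup))


@dataclass(frozen=True)
class VariantRecord:
    """One aggregate-browser row: identifier, rsID, class, spectrum.

    Variant IDs are unique per table; rsIDs are not (distinct alt alleles at
    one site, or browser annotation quirks, can repeat an rsID), so keyed
    operations always use the variant ID.
    """

    variant_id: VariantId
    rsid: str
    significance: SignificanceClass
    spectrum: AncestrySpectrum

    def __post_init__(self) -> None:
        if not _RSID.match(self.rsid):
            raise ValueError(f"malformed rsID: {self.rsid!r}")


@dataclass
class CohortMetadata:
    """Cohort-level bookkeeping for a frequency table.

    ``complete=False`` marks metadata whose class counts are quoted from an
    external summary rather than tallied from the table rows; the sum
    invariant is only enforced for complete metadata.
    """

    n_total_variants: int
    n_participants_wgs: int = 0
    class_counts: dict[SignificanceClass, int] = field(default_factory=dict)
    source_label: str = ""
    complete: bool = True

    def __post_init__(self) -> None:
        if self.class_counts and self.complete:
            total = sum(self.class_counts.values())
            if total != self.n_total_variants:
                raise ValueError(
                    f"class_counts sum {total} != n_total_variants "
                    f"{self.n_total_variants}"
                )


def star_allele_sort_key(name: str) -> int:
    """Numeric star-allele ordering: CYP2D6*2 < *10 < *184."""
    return int(name.rsplit("*", 1)[1])


@dataclass(frozen=True)
class SubAllele:
    """A PharmVar-style sub-allele: named haplotype with an evidence tier."""

    star_allele: str
    suballele_label: str
    evidence: EvidenceLevel
    defining_rsids: frozenset[str]

    def __post_init__(self) -> None:
        if not _STAR.match(self.star_allele):
            raise ValueError(f"malformed star-allele name: {self.star_allele!r}")
        object.__setattr__(self, "defining_rsids", frozenset(self.defining_rsids))


class HaplotypeTable:
    """Star-allele haplotype definitions with an inverted rsID index.

    The index maps each rsID to the set of star alleles any of whose
    sub-alleles list it as a defining variant; it is rebuilt from the
    sub-allele list at construction, so the two views cannot drift.
    """

    def __init__(self, suballeles: Iterable[SubAllele]):
        self.suballeles: list[SubAllele] = list(suballeles)
        self.index: dict[str, set[str]] = self.build_index(self.suballeles)
        self._by_star: dict[str, list[SubAllele]] = {}
        for sa in self.suballeles:
            self._by_star.setdefault(sa.star_allele, []).append(sa)

    @staticmethod
    def build_index(suballeles: Iterable[SubAllele]) -> dict[str, set[str]]:
        index: dict[str, set[str]] = {}
        for sa in suballeles:
            for rsid in sa.defining_rsids:
                index.setdefault(rsid, set()).add(sa.star_allele)
        return index

    @property
    def star_alleles(self) -> list[str]:
        return sorted(self._by_star, key=star_allele_sort_key)

    def suballeles_of(self, star_allele: str) -> list[SubAllele]:
        try:
            return self._by_star[star_allele]
        except KeyError:
            raise KeyError(f"unknown star allele: {star_allele!r}") from None

    def __len__(self) -> int:
        return len(self.suballeles)
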