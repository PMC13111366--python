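"""Cross-reference flagged variants against star-allele haplotype definitions.

A variant with "undefined" ClinVar significance that is (a) flagged as
enriched in at least one ancestry subgroup and (b) carried on at least one
star allele with a Definitive-evidence sub-allele is nominated as a
candidate for reclassification to "drug response" significance.

The cross-reference key is the rsID (what haplotype definitions publish);
because rsIDs are not unique across variant rows, each row is looked up
independently and results carry the row's variant ID.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal

from .model import (
    AncestryCategory,
    EvidenceLevel,
    HaplotypeTable,
    VariantRecord,
    star_allele_sort_key,
)
from .screening import ScreenResult

__all__ = [
    "XrefResult",
    "has_definitive_suballele",
    "reclassification_candidates",
    "star_allele_count_range",
    "star_alleles_containing",
]


@dataclass(frozen=True)
class XrefResult:
    """One variant's haplotype cross-reference outcome."""

    variant: VariantRecord
    star_alleles: tuple[str, ...]  # ordered by numeric star suffix, deduped
    has_definitive: bool
    flagged_subgroups: tuple[tuple[AncestryCategory, Decimal], ...]

    @property
    def n_star_alleles(self) -> int:
        return len(self.star_alleles)

    @property
    def max_delta(self) -> Decimal:
        return max(d for _, d in self.flagged_subgroups)


def star_alleles_containing(rsid: str, table: HaplotypeTable) -> tuple[str, ...]:
    """Star alleles any of whose sub-alleles list ``rsid`` as defining.

    Ordered by numeric star-allele suffix; an absent rsID yields an empty
    tuple, not an error.
    """
    names = table.index.get(rsid, set())
    return tuple(sorted(names, key=star_allele_sort_key))


def has_definitive_suballele(star_allele: str, table: HaplotypeTable) -> bool:
    """True iff any sub-allele of ``star_allele`` is Definitive evidence.

    Raises ``KeyError`` for a star allele unknown to the table.
    """
    return any(
        sa.evidence is EvidenceLevel.DEFINITIVE
        for sa in table.suballeles_of(star_allele)
    )


def cross_reference(result: ScreenResult, table: HaplotypeTable) -> XrefResult:
    """Look up one screened variant's rsID in the haplotype table."""
    stars = star_alleles_containing(result.variant.rsid, table)
    return XrefResult(
        variant=result.variant,
        star_alleles=stars,
        has_definitive=any(has_definitive_suballele(s, table) for s in stars),
        flagged_subgroups=tuple(result.flagged_subgroups),
    )


def reclassification_candidates(
    screen: list[ScreenResult],
    table: HaplotypeTable,
    require_definitive: bool = True,
) -> list[XrefResult]:
    """Variants flagged in ≥1 subgroup whose haplotypes reach Definitive.

    The rule is conjunctive: a candidate must carry at least one subgroup
    flag and (unless ``require_definitive=False``, an exploratory mode) be
    contained in at least one star allele that has a Definitive-evidence
    sub-allele. Sorted by descending maximum delta, ties broken by variant
    ID for determinism.
    """
    out = []
    for res in screen:
        if not any(res.flags.values()):
            continue
        xref = cross_reference(res, table)
        if require_definitive and not xref.has_definitive:
            continue
        out.append(xref)
    out.sort(key=lambda x: (-x.max_delta, str(x.variant.variant_id)))
    return out


def star_allele_count_range(candidates: list[XrefResult]) -> tuple[int, int]:
    """(min, max) of per-candidate star-allele counts; empty input is an error."""
    if not candidates:
        raise ValueError("star_allele_count_range requires a nonempty candidate list")
    counts = [c.n_star_alleles for c in candidates]
    return min(counts), max(counts)
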