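"""Packaged reference fixtures: the published summary tables.

Three tables ship with the package as TSV, transcribed verbatim from the
published aggregate-browser summaries they reproduce:

* ``table1`` — 11 "drug response" variants with overall frequency ≥ 0.10;
* ``table2`` — 60 "undefined" variants with overall frequency ≥ 0.10;
* ``table3`` — the cross-reference listing: per flagged "undefined" variant,
  the star alleles (with a Definitive-evidence sub-allele) whose definitions
  contain its rsID.

Printed quirks are preserved on purpose — the duplicated table-3 row
(rs1080998), the duplicated CYP2D6*10 token in the rs28371699 list, and
the repeated rsIDs in the frequency tables — because regression tests pin
recomputation against the publication exactly as printed.

A markings file records which cells the publication flagged (``**``) and
which rows it marked as Definitive-reachable (``***``); it is the ground
truth for marking-reproduction regression tests, not an input to screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from importlib import resources
from pathlib import Path

from .io import read_frequency_table, read_haplotype_table
from .model import (
    AncestryCategory,
    CohortMetadata,
    HaplotypeTable,
    VariantRecord,
)

__all__ = [
    "FIXTURE_NAMES",
    "Table3Row",
    "TableMarkings",
    "fixture_path",
    "load_fixture",
]

FIXTURE_NAMES = (
    "table1",
    "table2",
    "table1_markings",
    "table2_markings",
    "table3_xref",
    "table3_rows",
)

#: published cohort-level counts quoted in the tables' captions
PUBLISHED_CLASS_COUNTS = {
    "drug_response": 89,
    "undefined": 6262,
    "likely_benign": 17,
    "benign": 2,
    "other": 14,
}
PUBLISHED_TOTAL_VARIANTS = 6359
PUBLISHED_N_PARTICIPANTS = 245460


def published_cohort_metadata() -> CohortMetadata:
    """Cohort metadata as quoted by the published summary.

    Marked incomplete: the quoted per-class counts sum to 6,384, not the
    quoted total of 6,359 — an inconsistency in the source that the package
    surfaces rather than repairs. Percentages are computed over the quoted
    total, reproducing the published figures.
    """
    from .model import SignificanceClass

    return CohortMetadata(
        n_total_variants=PUBLISHED_TOTAL_VARIANTS,
        n_participants_wgs=PUBLISHED_N_PARTICIPANTS,
        class_counts={
            SignificanceClass.from_label(c): n
            for c, n in PUBLISHED_CLASS_COUNTS.items()
        },
        source_label="published cohort summary",
        complete=False,
    )


@dataclass(frozen=True)
class TableMarkings:
    """Published per-cell flags for one table.

    ``marked``: variant ID → set of subgroups printed with the enrichment
    mark; ``definitive``: variant IDs printed as carried on ≥1 star allele
    with a Definitive-evidence sub-allele.
    """

    marked: dict[str, frozenset[AncestryCategory]]
    definitive: frozenset[str]

    def marked_cells(self) -> set[tuple[str, AncestryCategory]]:
        return {(vid, cat) for vid, cats in self.marked.items() for cat in cats}

    def count(self, category: AncestryCategory) -> int:
        return sum(category in cats for cats in self.marked.values())


@dataclass(frozen=True)
class Table3Row:
    """One printed cross-reference row, token list as published (with dups)."""

    variant_id: str
    rsid: str
    printed_deltas: dict[AncestryCategory, Decimal]
    star_alleles: tuple[str, ...]

    @property
    def n_tokens(self) -> int:
        return len(self.star_alleles)

    @property
    def n_unique(self) -> int:
        return len(set(self.star_alleles))


def fixture_path(filename: str) -> Path:
    return Path(resources.files("pgxscreen").joinpath("data", filename))


def _load_markings(table: str) -> TableMarkings:
    marked: dict[str, frozenset[AncestryCategory]] = {}
    definitive = set()
    lines = fixture_path("table_markings.tsv").read_text().splitlines()
    for line in lines[1:]:
        tab, vid, _rsid, cats, defin = line.split("\t")
        if tab != table:
            continue
        marked[vid] = frozenset(
            AncestryCategory.from_label(c) for c in cats.split(";") if c
        )
        if defin == "1":
            definitive.add(vid)
    return TableMarkings(marked=marked, definitive=frozenset(definitive))


def _load_table3_rows() -> list[Table3Row]:
    rows = []
    lines = fixture_path("table3_xref.tsv").read_text().splitlines()
    for line in lines[1:]:
        vid, rsid, deltas_text, stars = line.split("\t")
        deltas = {}
        for item in deltas_text.split(";"):
            label, value = item.split(":")
            deltas[AncestryCategory.from_label(label)] = Decimal(value)
        rows.append(
            Table3Row(
                variant_id=vid,
                rsid=rsid,
                printed_deltas=deltas,
                star_alleles=tuple(stars.split(";")),
            )
        )
    return rows


def load_fixture(
    name: str,
) -> (
    tuple[list[VariantRecord], CohortMetadata]
    | TableMarkings
    | HaplotypeTable
    | list[Table3Row]
):
    """Load one packaged fixture by name.

    ``table1``/``table2`` return (records, metadata); ``table1_markings``/
    ``table2_markings`` return the published cell flags; ``table3_xref``
    returns the haplotype-definition table derived from the published
    cross-reference (every star allele carries a Definitive sub-allele, per
    the publication's inclusion rule); ``table3_rows`` returns the printed
    rows themselves, duplicate tokens intact.
    """
    if name in ("table1", "table2"):
        return read_frequency_table(fixture_path(f"{name}.tsv"))
    if name in ("table1_markings", "table2_markings"):
        return _load_markings(name.removesuffix("_markings"))
    if name == "table3_xref":
        return read_haplotype_table(fixture_path("table3_haplotypes.tsv"))
    if name == "table3_rows":
        return _load_table3_rows()
    raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
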