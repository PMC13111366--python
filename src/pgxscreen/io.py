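"""Readers and writers for frequency tables, haplotype tables, screen output.

Frequency columns are read as strings and converted to ``Decimal`` so the
published decimal values survive round trips bit-for-bit; the screen writer
prints deltas via ``str(Decimal)`` for the same reason.
"""

from __future__ import annotations

import warnings
from collections import Counter
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable

import pandas as pd

from .model import (
    AncestryCategory,
    AncestrySpectrum,
    CohortMetadata,
    EvidenceLevel,
    HaplotypeTable,
    SignificanceClass,
    SubAllele,
    VariantRecord,
    parse_variant_id,
)

__all__ = [
    "FrequencyTableDialect",
    "SchemaError",
    "TableIntegrityError",
    "read_frequency_table",
    "read_haplotype_table",
    "write_screen_table",
]

#: canonical frequency-table column names, in file order
FREQ_COLUMNS = (
    "variant_id",
    "rsid",
    "clinvar_significance",
    "af_overall",
    *(f"af_{c.token}" for c in AncestryCategory),
)


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class TableIntegrityError(ValueError):
    """Duplicate variant IDs or out-of-range values in an input table."""


class FrequencyTableDialect:
    """Header-alias mapping for browser-style exports.

    The defaults accept the canonical column names plus the browser display
    aliases ("Americas" for Latin American, "Remaining" for Other). Extra
    aliases may be supplied as ``{observed_header: canonical_name}``.
    """

    def __init__(self, aliases: dict[str, str] | None = None, sep: str | None = None):
        self.sep = sep  # None: infer from extension (.csv -> ',', else tab)
        base = {
            "af_americas": "af_latin_american",
            "af_remaining": "af_other",
        }
        if aliases:
            base.update({k.lower(): v for k, v in aliases.items()})
        self.aliases = base

    def canonical(self, header: str) -> str:
        key = header.strip().lower().replace(" ", "_")
        return self.aliases.get(key, key)


def _infer_sep(path: Path, dialect: FrequencyTableDialect | None) -> str:
    if dialect is not None and dialect.sep is not None:
        return dialect.sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def _decimal(text: str, column: str, row: int) -> Decimal:
    try:
        value = Decimal(text)
    except InvalidOperation:
        raise TableIntegrityError(
            f"row {row}: cannot parse {column}={text!r} as a decimal"
        ) from None
    if not (0 <= value <= 1):
        raise TableIntegrityError(f"row {row}: {column}={text} outside [0,1]")
    return value


def read_frequency_table(
    path: str | Path,
    dialect: FrequencyTableDialect | None = None,
    allow_partial: bool = False,
) -> tuple[list[VariantRecord], CohortMetadata]:
    """Read a browser-style aggregate frequency table.

    Returns records in file order plus cohort metadata (row and per-class
    counts). Duplicate variant IDs are rejected; duplicate rsIDs are allowed.
    With ``allow_partial``, empty subgroup cells yield partial spectra that
    screening will skip rather than flag.
    """
    path = Path(path)
    dialect = dialect or FrequencyTableDialect()
    df = pd.read_csv(path, sep=_infer_sep(path, dialect), dtype=str)
    df.columns = [dialect.canonical(c) for c in df.columns]

    missing = [c for c in FREQ_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")

    records: list[VariantRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        vid_text = getattr(row, "variant_id")
        if vid_text in seen:
            raise TableIntegrityError(f"row {i}: duplicate variant ID {vid_text}")
        seen.add(vid_text)
        by_subgroup = {}
        for cat in AncestryCategory:
            cell = getattr(row, f"af_{cat.token}")
            if pd.isna(cell) or str(cell).strip() == "":
                if not allow_partial:
                    raise TableIntegrityError(
                        f"row {i}: missing af_{cat.token} (pass allow_partial "
                        "to accept suppressed cells)"
                    )
                continue
            by_subgroup[cat] = _decimal(str(cell), f"af_{cat.token}", i)
        spectrum = AncestrySpectrum(
            overall=_decimal(str(getattr(row, "af_overall")), "af_overall", i),
            by_subgroup=by_subgroup,
            partial=len(by_subgroup) < len(AncestryCategory),
        )
        records.append(
            VariantRecord(
                variant_id=parse_variant_id(vid_text),
                rsid=str(getattr(row, "rsid")),
                significance=SignificanceClass.from_label(
                    str(getattr(row, "clinvar_significance"))
                ),
                spectrum=spectrum,
            )
        )

    counts = Counter(r.significance for r in records)
    meta = CohortMetadata(
        n_total_variants=len(records),
        class_counts=dict(counts),
        source_label=path.name,
    )
    return records, meta


def read_haplotype_table(path: str | Path) -> HaplotypeTable:
    """Read a PharmVar-style haplotype definition TSV.

    Expects columns ``star_allele``, ``suballele_label``, ``evidence``,
    ``defining_rsids`` (semicolon-separated). A non-reference sub-allele with
    an empty rsID list is kept but warned about.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["star_allele", "suballele_label", "evidence", "defining_rsids"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    suballeles = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rsids = frozenset(t for t in str(row.defining_rsids).split(";") if t)
        if not rsids:
            warnings.warn(
                f"{path.name} row {i}: sub-allele {row.star_allele} "
                f"{row.suballele_label} has no defining rsIDs",
                stacklevel=2,
            )
        suballeles.append(
            SubAllele(
                star_allele=str(row.star_allele),
                suballele_label=str(row.suballele_label),
                evidence=EvidenceLevel.from_label(str(row.evidence)),
                defining_rsids=rsids,
            )
        )
    return HaplotypeTable(suballeles)


def write_screen_table(results: Iterable, path: str | Path) -> None:
    """Write screen results as a wide TSV (one row per screened variant).

    Columns: variant identity, overall frequency, then ``delta_<subgroup>``
    and ``flag_<subgroup>`` for each of the seven categories. Deltas are
    printed at full decimal precision (0/1 for flags); re-reading the file
    reproduces the decimal strings exactly. Deltas for subgroups absent from
    a partial spectrum are left empty.
    """
    cats = list(AncestryCategory)
    header = (
        ["variant_id", "rsid", "clinvar_significance", "af_overall"]
        + [f"delta_{c.token}" for c in cats]
        + [f"flag_{c.token}" for c in cats]
    )
    lines = ["\t".join(header)]
    for res in results:
        rec = res.variant
        row = [
            str(rec.variant_id),
            rec.rsid,
            rec.significance.value,
            str(rec.spectrum.overall),
        ]
        row += [str(res.deltas[c]) if c in res.deltas else "" for c in cats]
        row += ["1" if res.flags.get(c) else "0" for c in cats]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
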