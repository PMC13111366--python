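"""Ancestry-stratified allele-frequency screening.

The procedure selects variants whose overall cohort frequency clears a
threshold (default 0.10), computes each subgroup's signed frequency
difference from the overall cohort (Δ = subgroup − overall), and flags
subgroup cells under a stated policy. Two flagging criteria are supported:

* ``DELTA`` (default): flag when Δ ≥ delta_threshold. The comparison can be
  made on the exact decimal difference (``Strict``) or after round-half-up
  to two decimals (``ROUNDED_2DP``), which approximates how a human reading
  two-decimal summaries would mark cells.
* ``ELEVATED_SUBGROUP``: flag when the subgroup frequency itself clears
  overall_threshold and exceeds the overall frequency.

All arithmetic is exact ``decimal.Decimal`` on the parsed values — two
printed frequencies that differ by exactly 0.10 compare as flagged, with no
binary-float edge cases. Flags are computed for all seven subgroups; none is
special-cased.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

from .model import AncestryCategory, SignificanceClass, VariantRecord

__all__ = [
    "Comparison",
    "DeltaMode",
    "FlagCriterion",
    "ScreenPolicy",
    "ScreenResult",
    "compute_deltas",
    "flag_subgroups",
    "screen",
    "select_by_overall_frequency",
    "stratify_by_significance",
]


class Comparison(Enum):
    GREATER_EQUAL = ">="
    STRICTLY_GREATER = ">"


class DeltaMode(Enum):
    STRICT = "strict"
    ROUNDED_2DP = "rounded2dp"


class FlagCriterion(Enum):
    DELTA = "delta"
    ELEVATED_SUBGROUP = "elevated"


@dataclass(frozen=True)
class ScreenPolicy:
    """Thresholds and comparison rules for one screening run."""

    overall_threshold: Decimal = Decimal("0.10")
    delta_threshold: Decimal = Decimal("0.10")
    comparison: Comparison = Comparison.GREATER_EQUAL
    delta_mode: DeltaMode = DeltaMode.STRICT
    criterion: FlagCriterion = FlagCriterion.DELTA

    def __post_init__(self) -> None:
        for name in ("overall_threshold", "delta_threshold"):
            value = getattr(self, name)
            if not isinstance(value, Decimal):
                object.__setattr__(self, name, Decimal(str(value)))
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0,1)")


@dataclass(frozen=True)
class ScreenResult:
    """Per-variant screening outcome: signed deltas and subgroup flags."""

    variant: VariantRecord
    deltas: dict[AncestryCategory, Decimal]
    flags: dict[AncestryCategory, bool]
    passed_overall: bool = True

    @property
    def flagged_subgroups(self) -> list[tuple[AncestryCategory, Decimal]]:
        return [(c, self.deltas[c]) for c in AncestryCategory
                if self.flags.get(c)]

    @property
    def max_delta(self) -> Decimal:
        return max(self.deltas.values())


def _passes(value: Decimal, threshold: Decimal, comparison: Comparison) -> bool:
    if comparison is Comparison.GREATER_EQUAL:
        return value >= threshold
    return value > threshold


def select_by_overall_frequency(
    records: list[VariantRecord], policy: ScreenPolicy | None = None
) -> list[VariantRecord]:
    """Keep records whose overall frequency clears the policy threshold."""
    policy = policy or ScreenPolicy()
    return [
        r
        for r in records
        if _passes(r.spectrum.overall, policy.overall_threshold, policy.comparison)
    ]


def compute_deltas(record: VariantRecord) -> dict[AncestryCategory, Decimal]:
    """Exact signed differences Δ[g] = subgroup[g] − overall.

    Subgroups absent from a partial spectrum are omitted from the result.
    """
    overall = record.spectrum.overall
    return {
        cat: freq - overall
        for cat, freq in record.spectrum.by_subgroup.items()
    }


_TWO_DP = Decimal("0.01")


def flag_subgroups(
    deltas: dict[AncestryCategory, Decimal],
    record: VariantRecord,
    policy: ScreenPolicy | None = None,
) -> dict[AncestryCategory, bool]:
    """Apply the policy's flag criterion to each available subgroup cell."""
    policy = policy or ScreenPolicy()
    flags: dict[AncestryCategory, bool] = {}
    for cat, delta in deltas.items():
        if policy.criterion is FlagCriterion.DELTA:
            if policy.delta_mode is DeltaMode.ROUNDED_2DP:
                delta = delta.quantize(_TWO_DP, rounding=ROUND_HALF_UP)
            flags[cat] = delta >= policy.delta_threshold
        else:
            subgroup = record.spectrum.by_subgroup[cat]
            flags[cat] = (
                _passes(subgroup, policy.overall_threshold, policy.comparison)
                and delta > 0
            )
    return flags


def stratify_by_significance(
    records: list[VariantRecord],
) -> dict[SignificanceClass, list[VariantRecord]]:
    """Partition records by ClinVar class, preserving per-class order."""
    out: dict[SignificanceClass, list[VariantRecord]] = {}
    for r in records:
        out.setdefault(r.significance, []).append(r)
    return out


def screen(
    records: list[VariantRecord], policy: ScreenPolicy | None = None
) -> list[ScreenResult]:
    """Full composition: overall selection → deltas → subgroup flags.

    Returns one result per record that passes the overall-frequency
    selection, in input order.
    """
    policy = policy or ScreenPolicy()
    results = []
    for record in select_by_overall_frequency(records, policy):
        deltas = compute_deltas(record)
        results.append(
            ScreenResult(
                variant=record,
                deltas=deltas,
                flags=flag_subgroups(deltas, record, policy),
                passed_overall=True,
            )
        )
    return results
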