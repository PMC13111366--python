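"""Summary reporting and end-to-end pipeline orchestration.

Reproduces the headline quantities of an ancestry-stratified frequency
screen: per-significance-class counts and proportions, per-subgroup flag
counts with integer-rounded percentages, reclassification-candidate counts
(rows as printed and unique variant IDs), the star-allele count range, and
a discrepancy log comparing recomputed flags against packaged published
markings.

Percentage conventions follow the summaries the fixtures reproduce:
round-half-up to whole percent for subgroup flag rates, one decimal for
class proportions, except that proportions that would print as 0.0 are
given enough decimals to be nonzero (e.g. 2/6359 → 0.03%).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .io import read_frequency_table, read_haplotype_table, write_screen_table
from .model import AncestryCategory, CohortMetadata, SignificanceClass
from .screening import ScreenPolicy, ScreenResult, screen, stratify_by_significance
from .xref import XrefResult, reclassification_candidates, star_allele_count_range

__all__ = [
    "SummaryReport",
    "build_report",
    "class_proportions",
    "compare_to_markings",
    "render_report",
    "run_pipeline",
    "subgroup_flag_counts",
]

log = logging.getLogger("pgxscreen")

_ONE = Decimal("1")
_TENTH = Decimal("0.1")


def _round_half_up_int(numerator: int, denominator: int) -> int:
    return int(
        (Decimal(100 * numerator) / Decimal(denominator)).quantize(
            _ONE, rounding=ROUND_HALF_UP
        )
    )


def subgroup_flag_counts(
    results: list[ScreenResult], denominator: int
) -> dict[AncestryCategory, tuple[int, int]]:
    """Per-subgroup (count, integer percent) of variants flagged.

    ``denominator`` is the reporting base (normally the number of screened
    variants); it must be positive.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    out = {}
    for cat in AncestryCategory:
        count = sum(1 for r in results if r.flags.get(cat))
        out[cat] = (count, _round_half_up_int(count, denominator))
    return out


def class_proportions(meta: CohortMetadata) -> dict[SignificanceClass, Decimal]:
    """Class percentages at one decimal (round-half-up).

    A nonzero class whose one-decimal percentage would round to 0.0 is
    reported with the fewest extra decimals that make it nonzero, matching
    how small fractions are conventionally printed (0.03%, not 0.0%).
    """
    if meta.n_total_variants <= 0:
        raise ValueError("cohort has no variants")
    out = {}
    for cls, count in meta.class_counts.items():
        exact = Decimal(100 * count) / Decimal(meta.n_total_variants)
        quantum = _TENTH
        pct = exact.quantize(quantum, rounding=ROUND_HALF_UP)
        while count > 0 and pct == 0:
            quantum *= _TENTH
            pct = exact.quantize(quantum, rounding=ROUND_HALF_UP)
        out[cls] = pct
    return out


@dataclass
class SummaryReport:
    """Headline numbers for one pipeline run, JSON-serializable.

    Every percentage stored here is recomputable from the numerator and
    denominator stored next to it; :func:`render_report` re-checks that on
    each render. ``discrepancies`` lists cells where recomputation disagrees
    with packaged published markings (empty when no markings were supplied
    or all agree).
    """

    policy: dict[str, str]
    total_variants: int
    class_counts: dict[str, int] = field(default_factory=dict)
    class_percents: dict[str, str] = field(default_factory=dict)
    subgroup_flags: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    candidate_rows: int = 0
    candidate_unique: int = 0
    star_range: list[int] | None = None
    discrepancies: list[dict[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SummaryReport":
        return cls(**json.loads(text))

    def check_consistency(self) -> None:
        for cls_name, pct_text in self.class_percents.items():
            expected = class_proportions(
                CohortMetadata(
                    n_total_variants=self.total_variants,
                    class_counts={
                        SignificanceClass.from_label(c): n
                        for c, n in self.class_counts.items()
                    },
                    complete=False,
                )
            )[SignificanceClass.from_label(cls_name)]
            if Decimal(pct_text) != expected:
                raise ValueError(
                    f"inconsistent class percentage for {cls_name}: "
                    f"{pct_text} != {expected}"
                )
        for cls_name, per_subgroup in self.subgroup_flags.items():
            for token, cell in per_subgroup.items():
                recomputed = _round_half_up_int(cell["count"], cell["denominator"])
                if recomputed != cell["percent"]:
                    raise ValueError(
                        f"inconsistent percentage for {cls_name}/{token}: "
                        f"{cell['percent']} != {recomputed}"
                    )


def compare_to_markings(
    results: list[ScreenResult], marked: dict[str, frozenset[AncestryCategory]]
) -> list[dict[str, str]]:
    """Cells where recomputed flags disagree with published markings.

    ``marked`` maps variant ID → published flagged subgroups. Returns one
    entry per disagreeing (variant, subgroup) cell with the exact delta.
    """
    out = []
    for res in results:
        vid = str(res.variant.variant_id)
        published = marked.get(vid, frozenset())
        for cat in AncestryCategory:
            ours = bool(res.flags.get(cat))
            theirs = cat in published
            if ours != theirs:
                out.append(
                    {
                        "variant_id": vid,
                        "rsid": res.variant.rsid,
                        "subgroup": cat.value,
                        "delta": str(res.deltas[cat]),
                        "published_mark": str(int(theirs)),
                        "recomputed_flag": str(int(ours)),
                    }
                )
    return out


def _policy_echo(policy: ScreenPolicy) -> dict[str, str]:
    return {
        "overall_threshold": str(policy.overall_threshold),
        "delta_threshold": str(policy.delta_threshold),
        "comparison": policy.comparison.value,
        "delta_mode": policy.delta_mode.value,
        "criterion": policy.criterion.value,
    }


def build_report(
    results_by_class: dict[SignificanceClass, list[ScreenResult]],
    meta: CohortMetadata,
    policy: ScreenPolicy,
    candidates: list[XrefResult] | None = None,
    markings: dict[str, frozenset[AncestryCategory]] | None = None,
) -> SummaryReport:
    """Assemble the summary for screened results grouped by class."""
    report = SummaryReport(
        policy=_policy_echo(policy),
        total_variants=meta.n_total_variants,
        class_counts={c.value: n for c, n in meta.class_counts.items()},
        class_percents={
            c.value: str(p) for c, p in class_proportions(meta).items()
        },
    )
    for cls, results in results_by_class.items():
        if not results:
            continue
        counts = subgroup_flag_counts(results, len(results))
        report.subgroup_flags[cls.value] = {
            cat.token: {
                "count": n,
                "denominator": len(results),
                "percent": pct,
            }
            for cat, (n, pct) in counts.items()
        }
    if candidates is not None:
        report.candidate_rows = len(candidates)
        report.candidate_unique = len(
            {str(c.variant.variant_id) for c in candidates}
        )
        if candidates:
            report.star_range = list(star_allele_count_range(candidates))
    if markings is not None:
        all_results = [r for rs in results_by_class.values() for r in rs]
        report.discrepancies = compare_to_markings(all_results, markings)
    return report


def render_report(report: SummaryReport, format: str = "text") -> str:
    """Render a report as ``text``, ``markdown`` or ``json``.

    Deterministic; the JSON form round-trips to an equal report. Percentages
    are re-verified against their numerators/denominators before rendering.
    """
    report.check_consistency()
    if format == "json":
        return report.to_json()
    if format not in ("text", "markdown"):
        raise ValueError(f"unknown render format {format!r}")

    bullet = "- " if format == "markdown" else "  "
    h = (lambda s: f"## {s}") if format == "markdown" else (lambda s: s.upper())
    lines = [h("Screen policy")]
    lines += [f"{bullet}{k} = {v}" for k, v in sorted(report.policy.items())]
    lines.append(h("Significance classes"))
    lines.append(f"{bullet}total variants: {report.total_variants}")
    for cls in sorted(report.class_counts):
        lines.append(
            f"{bullet}{cls}: n = {report.class_counts[cls]} "
            f"({report.class_percents[cls]}%)"
        )
    for cls, per_subgroup in report.subgroup_flags.items():
        lines.append(h(f"Subgroup flags ({cls})"))
        ordered = sorted(
            per_subgroup.items(), key=lambda kv: -kv[1]["count"]
        )
        for token, cell in ordered:
            lines.append(
                f"{bullet}{token}: {cell['count']}/{cell['denominator']} "
                f"({cell['percent']}%)"
            )
    lines.append(h("Reclassification candidates"))
    lines.append(f"{bullet}rows as printed: {report.candidate_rows}")
    lines.append(f"{bullet}unique variant IDs: {report.candidate_unique}")
    if report.star_range:
        lines.append(
            f"{bullet}star alleles per candidate: "
            f"{report.star_range[0]}-{report.star_range[1]}"
        )
    lines.append(h("Discrepancies vs published markings"))
    if report.discrepancies:
        for d in report.discrepancies:
            lines.append(
                f"{bullet}{d['variant_id']} ({d['rsid']}) {d['subgroup']}: "
                f"delta {d['delta']}, published {d['published_mark']}, "
                f"recomputed {d['recomputed_flag']}"
            )
    else:
        lines.append(f"{bullet}none")
    return "\n".join(lines) + "\n"


def _write_candidates(candidates: list[XrefResult], path: Path) -> None:
    header = [
        "variant_id",
        "rsid",
        "flagged_subgroups",
        "n_star_alleles",
        "star_alleles",
        "has_definitive",
    ]
    lines = ["\t".join(header)]
    for c in candidates:
        flagged = ";".join(
            f"{cat.token}:{delta}" for cat, delta in c.flagged_subgroups
        )
        lines.append(
            "\t".join(
                [
                    str(c.variant.variant_id),
                    c.variant.rsid,
                    flagged,
                    str(c.n_star_alleles),
                    ";".join(c.star_alleles),
                    str(int(c.has_definitive)),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(
    freq_path: str | Path,
    haplotype_path: str | Path,
    policy: ScreenPolicy | None = None,
    out_dir: str | Path | None = None,
    markings: dict[str, frozenset[AncestryCategory]] | None = None,
) -> SummaryReport:
    """End-to-end: read → screen → stratify → cross-reference → report.

    Writes ``screen.tsv``, ``candidates.tsv``, ``report.json`` and
    ``report.txt`` under ``out_dir`` when given. Candidates are drawn from
    the screened undefined-class variants only, per the reclassification
    question the pipeline answers.
    """
    policy = policy or ScreenPolicy()
    records, meta = read_frequency_table(freq_path)
    log.info("read %d records from %s", len(records), freq_path)
    haplotypes = read_haplotype_table(haplotype_path)
    log.info("read %d sub-alleles from %s", len(haplotypes), haplotype_path)

    results = screen(records, policy)
    log.info("screened %d/%d records past overall threshold %s",
             len(results), len(records), policy.overall_threshold)
    by_class = stratify_by_significance([r.variant for r in results])
    results_by_class = {
        cls: [r for r in results if r.variant.significance is cls]
        for cls in by_class
    }
    undefined = results_by_class.get(SignificanceClass.UNDEFINED, [])
    candidates = reclassification_candidates(undefined, haplotypes)
    log.info("%d reclassification candidates", len(candidates))

    report = build_report(results_by_class, meta, policy, candidates, markings)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_screen_table(results, out / "screen.tsv")
        _write_candidates(candidates, out / "candidates.tsv")
        (out / "report.json").write_text(report.to_json() + "\n")
        (out / "report.txt").write_text(render_report(report, "text"))
        log.info("wrote outputs to %s", out)
    return report
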