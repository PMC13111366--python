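"""Star-allele cross-referencing and reclassification-candidate selection."""

import pytest

from pgxscreen.model import EvidenceLevel, HaplotypeTable, SubAllele
from pgxscreen.screening import DeltaMode, ScreenPolicy, ScreenResult, screen
from pgxscreen.xref import (
    has_definitive_suballele,
    reclassification_candidates,
    star_allele_count_range,
    star_alleles_containing,
)

ROUNDED = ScreenPolicy(delta_mode=DeltaMode.ROUNDED_2DP)

# the 15 distinct variant IDs the publication marks as carried on >= 1
# star allele with a Definitive-evidence sub-allele (its in-text list of 16
# repeats one entry)
DEFINITIVE_MARKED = {
    "22-42130482-C-A", "22-42127407-T-G", "22-42129130-C-G", "22-42130047-G-C",
    "22-42131531-G-A", "22-42127207-C-T", "22-42130565-A-G", "22-42130547-T-C",
    "22-42130559-T-G", "22-42130578-C-G", "22-42130560-C-G", "22-42130569-G-C",
    "22-42130571-G-T", "22-42131469-C-T", "22-42126310-C-T",
}


def test_star_alleles_containing_published_row(haplotypes):
    stars = star_alleles_containing("rs28633410", haplotypes)
    assert len(stars) == 41
    assert stars[0] == "CYP2D6*1" and stars[-1] == "CYP2D6*184"
    assert list(stars) == sorted(stars, key=lambda s: int(s.split("*")[1]))


def test_star_alleles_containing_absent_rsid(haplotypes):
    assert star_alleles_containing("rs0", haplotypes) == ()


def test_star_alleles_deduplicated_across_suballeles():
    table = HaplotypeTable([
        SubAllele("CYP2D6*17", "*17.001", EvidenceLevel.DEFINITIVE,
                  frozenset({"rs16947"})),
        SubAllele("CYP2D6*17", "*17.002", EvidenceLevel.LIMITED,
                  frozenset({"rs16947"})),
    ])
    assert star_alleles_containing("rs16947", table) == ("CYP2D6*17",)


def test_has_definitive_suballele():
    table = HaplotypeTable([
        SubAllele("CYP2D6*17", "*17.001", EvidenceLevel.DEFINITIVE, frozenset({"rs1"})),
        SubAllele("CYP2D6*17", "*17.002", EvidenceLevel.LIMITED, frozenset({"rs1"})),
        SubAllele("CYP2D6*4", "*4.001", EvidenceLevel.UNKNOWN, frozenset({"rs2"})),
    ])
    assert has_definitive_suballele("CYP2D6*17", table)
    assert not has_definitive_suballele("CYP2D6*4", table)
    with pytest.raises(KeyError):
        has_definitive_suballele("CYP2D6*999", table)


def test_every_fixture_star_allele_is_definitive(haplotypes):
    """The packaged cross-reference only lists Definitive-reachable alleles."""
    for star in haplotypes.star_alleles:
        assert has_definitive_suballele(star, haplotypes)


def test_candidates_strict_vs_rounded(table2, haplotypes):
    """Strict screening yields 14 candidates: the one definitive-marked row
    whose only published mark falls below 0.10 exactly (rs28371701) cannot
    carry a strict flag. Rounded-2dp mode recovers it, matching the
    publication's 15 distinct marked variant IDs."""
    strict = reclassification_candidates(screen(table2[0]), haplotypes)
    strict_ids = {str(c.variant.variant_id) for c in strict}
    assert len(strict) == 14
    assert strict_ids == DEFINITIVE_MARKED - {"22-42130047-G-C"}

    rounded = reclassification_candidates(screen(table2[0], ROUNDED), haplotypes)
    assert {str(c.variant.variant_id) for c in rounded} == DEFINITIVE_MARKED
    assert len(rounded) == 15


def test_candidates_from_published_markings(table2, table2_markings, haplotypes):
    """Using the published marks themselves as flags reproduces the
    publication's candidate list exactly (15 distinct variant IDs)."""
    results = []
    for res in screen(table2[0]):
        marked = table2_markings.marked.get(str(res.variant.variant_id), frozenset())
        results.append(ScreenResult(
            variant=res.variant,
            deltas=res.deltas,
            flags={cat: cat in marked for cat in res.deltas},
        ))
    candidates = reclassification_candidates(results, haplotypes)
    ids = {str(c.variant.variant_id) for c in candidates}
    assert ids == DEFINITIVE_MARKED
    assert ids == table2_markings.definitive


def test_candidates_sorted_by_descending_max_delta(table2, haplotypes):
    candidates = reclassification_candidates(screen(table2[0]), haplotypes)
    deltas = [c.max_delta for c in candidates]
    assert deltas == sorted(deltas, reverse=True)


def test_no_flags_means_no_candidates(table1, haplotypes):
    results = screen(table1[0], ScreenPolicy(delta_threshold="0.9"))
    assert reclassification_candidates(results, haplotypes) == []


def test_removing_definitive_labels_never_adds_candidates(table2, haplotypes):
    """Candidate monotonicity in the evidence relation."""
    results = screen(table2[0])
    base = reclassification_candidates(results, haplotypes)
    demoted = HaplotypeTable([
        SubAllele(sa.star_allele, sa.suballele_label, EvidenceLevel.LIMITED,
                  sa.defining_rsids)
        for sa in haplotypes.suballeles
    ])
    assert reclassification_candidates(results, demoted) == []
    loose = reclassification_candidates(results, demoted, require_definitive=False)
    assert {str(c.variant.variant_id) for c in loose} >= {
        str(c.variant.variant_id) for c in base
    }


def test_candidate_star_alleles_verified_by_direct_scan(table2, haplotypes):
    """Index inversion: every reported star allele's definition really
    contains the candidate's rsID (checked against the sub-allele list,
    not the index)."""
    for cand in reclassification_candidates(screen(table2[0]), haplotypes):
        for star in cand.star_alleles:
            assert any(
                sa.star_allele == star and cand.variant.rsid in sa.defining_rsids
                for sa in haplotypes.suballeles
            )
        assert cand.n_star_alleles == len(cand.star_alleles)
        assert 41 <= cand.n_star_alleles <= 76


def test_star_allele_count_range(table2, haplotypes):
    candidates = reclassification_candidates(screen(table2[0], ROUNDED), haplotypes)
    assert star_allele_count_range(candidates) == (41, 75)  # unique names
    one = candidates[:1]
    assert star_allele_count_range(one) == (one[0].n_star_alleles,) * 2
    with pytest.raises(ValueError):
        star_allele_count_range([])


def test_printed_token_lists_span_41_to_76(table3_rows):
    """As printed, the cross-reference lists 41–76 star-allele names per
    row; the maximum includes one duplicated token (75 unique names)."""
    tokens = [row.n_tokens for row in table3_rows]
    assert (min(tokens), max(tokens)) == (41, 76)
    widest = max(table3_rows, key=lambda r: r.n_tokens)
    assert widest.rsid == "rs28371699"
    assert widest.n_unique == 75
    narrow = next(r for r in table3_rows if r.rsid == "rs28633410")
    assert narrow.n_tokens == narrow.n_unique == 41
    # the printed listing repeats one row verbatim: 16 rows, 15 distinct IDs
    assert len(table3_rows) == 16
    assert len({r.variant_id for r in table3_rows}) == 15
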