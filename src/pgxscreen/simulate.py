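"""Synthetic browser-style cohorts and haplotype tables with planted truth.

The generator emulates the structure of an aggregate variant-browser export
for a single pharmacogene: per-variant overall and per-subgroup allele
frequencies over the seven ancestry categories, plus a ClinVar significance
label. Subgroup enrichment is planted on the logit scale — an enriched
subgroup's frequency is ``expit(logit(p0) + effect + jitter)`` against a
baseline ``p0`` drawn from a beta family — so planted frequency differences
are directly controllable. The overall frequency is the subgroup-weight
mixture Σ w_g·p_g, which is how an aggregate browser pools subgroups.

The default significance-label mixture mirrors the proportions observed in
the cohort the package's fixtures summarize (≈1.4% drug response, ≈98.5%
undefined, with traces of benign/likely-benign/other); subgroup weights
loosely mimic a majority-European national cohort and are fully
configurable — no demographic fidelity is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

import numpy as np
from scipy.special import expit, logit

from .model import (
    AncestryCategory,
    AncestrySpectrum,
    EvidenceLevel,
    HaplotypeTable,
    SignificanceClass,
    SubAllele,
    VariantId,
    VariantRecord,
)

__all__ = [
    "DEFAULT_CLASS_MIXTURE",
    "DEFAULT_SUBGROUP_WEIGHTS",
    "PlantedTruth",
    "SyntheticCohortSpec",
    "generate_cohort",
    "generate_haplotype_table",
]

DEFAULT_SUBGROUP_WEIGHTS: dict[AncestryCategory, float] = {
    AncestryCategory.AFRICAN: 0.20,
    AncestryCategory.EAST_ASIAN: 0.02,
    AncestryCategory.EUROPEAN: 0.51,
    AncestryCategory.LATIN_AMERICAN: 0.17,
    AncestryCategory.MIDDLE_EASTERN: 0.015,
    AncestryCategory.SOUTH_ASIAN: 0.025,
    AncestryCategory.OTHER: 0.06,
}

DEFAULT_CLASS_MIXTURE: dict[SignificanceClass, float] = {
    SignificanceClass.DRUG_RESPONSE: 0.014,
    SignificanceClass.UNDEFINED: 0.985,
    SignificanceClass.LIKELY_BENIGN: 0.003,
    SignificanceClass.BENIGN: 0.0003,
    SignificanceClass.OTHER: 0.002,
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generator parameters for one synthetic cohort.

    ``baseline_distribution`` is the (alpha, beta) shape of the overall
    baseline draw; the default (0.2, 1.8) gives the rare-skewed frequency
    spectrum typical of a deeply sequenced gene, with a minority of common
    variants that clear a 0.10 screen. ``baseline_range`` clips the draw to
    keep logits finite. ``enrichment_effect`` and ``noise_sd`` act on the
    logit scale.
    """

    n_variants: int = 1000
    subgroup_weights: dict[AncestryCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_WEIGHTS)
    )
    baseline_distribution: tuple[float, float] = (0.2, 1.8)
    baseline_range: tuple[float, float] = (1e-4, 0.999)
    enrichment_rate: float = 0.05
    enrichment_effect: float = 1.5
    noise_sd: float = 0.1
    class_mixture: dict[SignificanceClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 0:
            raise ValueError("n_variants must be nonnegative")
        wsum = sum(self.subgroup_weights.values())
        if wsum <= 0:
            raise ValueError("subgroup weights must have positive sum")
        if set(self.subgroup_weights) != set(AncestryCategory):
            raise ValueError("subgroup_weights must cover all seven categories")
        msum = sum(self.class_mixture.values())
        if msum <= 0 or any(p < 0 for p in self.class_mixture.values()):
            raise ValueError("class_mixture must be nonnegative with positive sum")
        for rate in (self.enrichment_rate,):
            if not (0 <= rate <= 1):
                raise ValueError("enrichment_rate must lie in [0,1]")
        # renormalize in place (frozen dataclass: rebind the dicts)
        object.__setattr__(
            self,
            "subgroup_weights",
            {c: w / wsum for c, w in self.subgroup_weights.items()},
        )
        object.__setattr__(
            self,
            "class_mixture",
            {c: p / msum for c, p in self.class_mixture.items()},
        )


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside a synthetic cohort or haplotype table.

    ``enriched_subgroups[i]`` is the planted enrichment set of variant *i*;
    ``expected_flags`` / ``expected_flag_counts`` are the cells a default
    strict 0.10/0.10 screen should flag given the numbers actually generated
    (they coincide with the planted sets when noise is zero and the effect
    is large); ``is_candidate[i]`` marks undefined-class variants with ≥1
    expected flag. For haplotype tables, ``definitive_reachable`` is the set
    of rsIDs carried on ≥1 star allele with a Definitive sub-allele.
    """

    enriched_subgroups: list[frozenset[AncestryCategory]] = field(default_factory=list)
    assigned_class: list[SignificanceClass] = field(default_factory=list)
    expected_flags: set[tuple[str, AncestryCategory]] = field(default_factory=set)
    expected_flag_counts: dict[AncestryCategory, int] = field(default_factory=dict)
    is_candidate: list[bool] = field(default_factory=list)
    definitive_reachable: frozenset[str] = frozenset()


_BASES = "ACGT"
_FLAG_THRESHOLD = Decimal("0.10")


def _decimal(x: float) -> Decimal:
    # repr round-trips exactly, so Decimal(record) == float value generated
    return Decimal(repr(float(x)))


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[VariantRecord], PlantedTruth]:
    """Generate a synthetic cohort; same spec (incl. seed) → identical output.

    Subgroup frequencies are rounded to six decimals (browser display
    precision) *before* the overall mixture is taken, so every record
    satisfies overall == Σ w_g·p_g exactly in float arithmetic.
    """
    rng = np.random.default_rng(spec.seed)
    cats = list(AncestryCategory)
    weights = np.array([spec.subgroup_weights[c] for c in cats])
    alpha, beta = spec.baseline_distribution
    lo, hi = spec.baseline_range

    positions = rng.choice(np.arange(42_120_000, 42_140_000), size=spec.n_variants,
                           replace=False)
    class_pool = list(spec.class_mixture)
    class_probs = np.array([spec.class_mixture[c] for c in class_pool])

    records: list[VariantRecord] = []
    truth = PlantedTruth()
    for i in range(spec.n_variants):
        p0 = float(np.clip(rng.beta(alpha, beta), lo, hi))
        enriched: frozenset[AncestryCategory] = frozenset()
        if rng.random() < spec.enrichment_rate:
            k = 1 + int(rng.random() < 0.3)  # usually one subgroup, sometimes two
            enriched = frozenset(rng.choice(len(cats), size=k, replace=False).tolist())
            enriched = frozenset(cats[j] for j in enriched)
        base_logit = logit(p0)
        p_sub = {}
        for c in cats:
            shift = spec.enrichment_effect if c in enriched else 0.0
            jitter = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            p_sub[c] = round(float(expit(base_logit + shift + jitter)), 6)
        overall = float(np.dot(weights, [p_sub[c] for c in cats]))

        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        record = VariantRecord(
            variant_id=VariantId("22", int(positions[i]), str(ref), str(alt)),
            rsid=f"rs{900_000_000 + i}",
            significance=class_pool[int(rng.choice(len(class_pool), p=class_probs))],
            spectrum=AncestrySpectrum(
                overall=_decimal(overall),
                by_subgroup={c: _decimal(p_sub[c]) for c in cats},
            ),
        )
        records.append(record)
        truth.enriched_subgroups.append(enriched)
        truth.assigned_class.append(record.significance)

        flagged = set()
        if record.spectrum.overall >= _FLAG_THRESHOLD:
            for c in cats:
                delta = record.spectrum.by_subgroup[c] - record.spectrum.overall
                if delta >= _FLAG_THRESHOLD:
                    flagged.add(c)
                    truth.expected_flags.add((str(record.variant_id), c))
        truth.is_candidate.append(
            bool(flagged) and record.significance is SignificanceClass.UNDEFINED
        )
    truth.expected_flag_counts = {
        c: sum(1 for _, cat in truth.expected_flags if cat is c) for c in cats
    }
    return records, truth


def generate_haplotype_table(
    n_star_alleles: int,
    rsid_pool: list[str],
    definitive_rate: float,
    seed: int,
) -> tuple[HaplotypeTable, PlantedTruth]:
    """Random star-allele definitions over an rsID pool, with truth.

    Each star allele gets 1–3 sub-alleles; each sub-allele draws 1–4
    defining rsIDs from the pool and is Definitive with the stated
    probability (otherwise a random lesser tier).
    """
    if not rsid_pool:
        raise ValueError("rsid_pool must be nonempty")
    rng = np.random.default_rng(seed)
    lesser = [EvidenceLevel.MODERATE, EvidenceLevel.LIMITED, EvidenceLevel.UNKNOWN]
    suballeles = []
    for i in range(1, n_star_alleles + 1):
        star = f"CYP2D6*{i}"
        for j in range(1, int(rng.integers(1, 4)) + 1):
            size = int(rng.integers(1, min(4, len(rsid_pool)) + 1))
            rsids = rng.choice(rsid_pool, size=size, replace=False)
            evidence = (
                EvidenceLevel.DEFINITIVE
                if rng.random() < definitive_rate
                else lesser[int(rng.integers(0, 3))]
            )
            suballeles.append(
                SubAllele(
                    star_allele=star,
                    suballele_label=f"*{i}.{j:03d}",
                    evidence=evidence,
                    defining_rsids=frozenset(map(str, rsids)),
                )
            )
    table = HaplotypeTable(suballeles)
    definitive_stars = {
        sa.star_allele
        for sa in suballeles
        if sa.evidence is EvidenceLevel.DEFINITIVE
    }
    reachable = {
        rsid
        for sa in suballeles
        if sa.star_allele in definitive_stars
        for rsid in sa.defining_rsids
    }
    truth = PlantedTruth(definitive_reachable=frozenset(reachable))
    return table, truth
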