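"""Trio de novo identification, rarity tiers, damage classes, and trio QC.

A candidate de novo variant must be heterozygous in the child (alternate
allele fraction within a window around 0.5), effectively absent from both
parents, and well supported: minimum depth in every family member, minimum
child alternate-read count, and minimum mapping quality. On the X chromosome
the rules are sex-aware: a male child is hemizygous (the allele-fraction
window widens toward 1 and only the mother can transmit an X), a female
child is treated as on the autosomes.

Rarity tiers use the gnomAD non-neuro subset allele frequency: rare < 1e-3,
ultra-rare < 5e-5 (strict). Damage classes: protein-truncating variants
(stop-gain, frameshift, canonical splice), damaging missense (MPC > 2),
other missense, synonymous, other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .records import (
    Consequence,
    DAMAGE_SEVERITY,
    DamageClass,
    DeNovoCall,
    Rarity,
    Role,
    Sex,
    VariantRecord,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds for the de novo filters; defaults are the stringent
    values used for exome trio studies of childhood-onset conditions.

    ``child_af_min``/``child_af_max`` bound the child's alternate allele
    fraction (inclusive); ``male_x_af_max`` replaces ``child_af_max`` for
    hemizygous male-X calls. Parents must each be below ``parent_af_max``
    (strict). ``rare_af``/``ultra_rare_af`` are strict upper bounds on the
    gnomAD non-neuro frequency. Children carrying more than
    ``max_denovo_per_child`` calls are excluded as outliers.
    """

    child_af_min: float = 0.3
    child_af_max: float = 0.7
    male_x_af_max: float = 1.0
    parent_af_max: float = 0.05
    min_depth: int = 20
    min_alt_depth: int = 5
    min_mq: float = 30.0
    rare_af: float = 0.001
    ultra_rare_af: float = 0.00005
    max_denovo_per_child: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.child_af_min < self.child_af_max < 1:
            raise ValueError("need 0 < child_af_min < child_af_max < 1")
        if not self.ultra_rare_af < self.rare_af:
            raise ValueError("ultra_rare_af must be below rare_af")


def allele_fraction(alt_depth: int, total_depth: int) -> Optional[float]:
    """Alternate allele fraction; ``None`` (unevaluable) when depth is 0."""
    if total_depth is None or alt_depth is None or total_depth <= 0:
        return None
    return alt_depth / total_depth


def passes_denovo_filters(
    record: VariantRecord,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[bool, tuple[tuple[str, bool], ...]]:
    """Apply the trio de novo genotype filters to one record.

    Returns (passed, trace) where trace is an ordered tuple of
    (rule, outcome) pairs covering every rule evaluated. For male children
    on the X chromosome the father's genotype is not used to reject and his
    depth is not required; the child AF window widens to
    [child_af_min, male_x_af_max].
    """
    male_x = record.is_x and record.child_sex is Sex.MALE
    required = [Role.CHILD, Role.MOTHER]
    if not male_x:
        required.append(Role.FATHER)

    trace: list[tuple[str, bool]] = []

    evidence = {role: record.evidence(role) for role in required}
    evaluable = all(e is not None and e.evaluable for e in evidence.values())
    trace.append(("evaluable_evidence", evaluable))
    if not evaluable:
        return False, tuple(trace)

    mqs = [e.mq for e in evidence.values()]
    mq_ok = all(m is not None and m >= thresholds.min_mq for m in mqs)
    trace.append(("mapping_quality", mq_ok))

    depth_ok = all(e.dp >= thresholds.min_depth for e in evidence.values())
    trace.append(("member_depth", depth_ok))

    child = evidence[Role.CHILD]
    alt_ok = child.alt_dp >= thresholds.min_alt_depth
    trace.append(("child_alt_depth", alt_ok))

    child_af = allele_fraction(child.alt_dp, child.dp)
    af_max = thresholds.male_x_af_max if male_x else thresholds.child_af_max
    af_ok = (
        child_af is not None
        and thresholds.child_af_min <= child_af <= af_max
    )
    trace.append(("child_af_window", af_ok))

    parents_ok = True
    for role in (Role.MOTHER, Role.FATHER):
        if role is Role.FATHER and male_x:
            continue
        e = evidence[role]
        paf = allele_fraction(e.alt_dp, e.dp)
        if paf is None or paf >= thresholds.parent_af_max:
            parents_ok = False
    trace.append(("parent_absence", parents_ok))

    passed = all(ok for _, ok in trace)
    return passed, tuple(trace)


def classify_damage(
    record: VariantRecord, mpc_threshold: float = 2.0
) -> DamageClass:
    """Damage class of a variant; missense needs MPC strictly above the
    threshold to count as damaging (missing MPC can never qualify)."""
    c = record.consequence
    if c in (
        Consequence.STOPGAIN,
        Consequence.FRAMESHIFT_INSERTION,
        Consequence.FRAMESHIFT_DELETION,
        Consequence.CANONICAL_SPLICE,
    ):
        return DamageClass.PTV
    if c is Consequence.MISSENSE:
        if record.mpc is not None and record.mpc > mpc_threshold:
            return DamageClass.MISD
        return DamageClass.MISSENSE_OTHER
    if c is Consequence.SYNONYMOUS:
        return DamageClass.SYNONYMOUS
    return DamageClass.OTHER


def classify_rarity(
    gnomad_nonneuro_af: float,
    thresholds: FilterThresholds = FilterThresholds(),
) -> Rarity:
    """Rarity tier from the gnomAD non-neuro AF (strict thresholds)."""
    if not 0.0 <= gnomad_nonneuro_af <= 1.0:
        raise ValueError(f"AF {gnomad_nonneuro_af} outside [0, 1]")
    if gnomad_nonneuro_af < thresholds.ultra_rare_af:
        return Rarity.ULTRA_RARE
    if gnomad_nonneuro_af < thresholds.rare_af:
        return Rarity.RARE
    return Rarity.COMMON


def dedupe_per_gene(calls: Sequence[DeNovoCall]) -> list[DeNovoCall]:
    """Keep one call per (family, gene): the most severe consequence, ties
    broken by lower genomic position, then lexicographic alt allele."""
    best: dict[tuple[str, str], DeNovoCall] = {}
    order: list[tuple[str, str]] = []
    for call in calls:
        key = (call.family_id, call.record.gene)
        rank = (
            DAMAGE_SEVERITY[call.damage_class],
            call.record.pos,
            call.record.alt_allele,
        )
        if key not in best:
            best[key] = call
            order.append(key)
        else:
            incumbent = best[key]
            inc_rank = (
                DAMAGE_SEVERITY[incumbent.damage_class],
                incumbent.record.pos,
                incumbent.record.alt_allele,
            )
            if rank < inc_rank:
                best[key] = call
    return [best[k] for k in order]


def trio_qc(
    calls: Sequence[DeNovoCall],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[DeNovoCall], dict[str, int]]:
    """Exclude families whose child carries an outlier number of de novo
    calls (strictly more than ``max_denovo_per_child``).

    Returns (retained calls, excluded {family_id: call count}).
    """
    counts: dict[str, int] = {}
    for call in calls:
        counts[call.family_id] = counts.get(call.family_id, 0) + 1
    excluded = {
        fam: n for fam, n in counts.items()
        if n > thresholds.max_denovo_per_child
    }
    for fam, n in excluded.items():
        logger.info("excluding family %s: %d de novo calls (outlier)", fam, n)
    retained = [c for c in calls if c.family_id not in excluded]
    return retained, excluded


def call_denovos(
    records: Sequence[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    mpc_threshold: float = 2.0,
) -> tuple[list[DeNovoCall], dict[str, int]]:
    """Full per-variant pipeline: genotype filters, rarity and damage
    classification, one-per-gene collapse, then trio-level outlier QC.

    Filter order is fixed (evidence -> genotype gates -> classification ->
    dedupe -> trio QC) and each call carries its complete filter trace.
    """
    candidates: list[DeNovoCall] = []
    for record in records:
        passed, trace = passes_denovo_filters(record, thresholds)
        if not passed:
            continue
        candidates.append(
            DeNovoCall(
                record=record,
                family_id=record.family_id,
                rarity=classify_rarity(record.gnomad_nonneuro_af, thresholds),
                damage_class=classify_damage(record, mpc_threshold),
                filter_trace=trace,
            )
        )
    deduped = dedupe_per_gene(candidates)
    return trio_qc(deduped, thresholds)
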