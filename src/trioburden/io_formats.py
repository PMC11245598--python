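"""Readers and writers for the external formats the pipeline touches.

VCF parsing goes through cyvcf2; everything downstream operates on the typed
records in :mod:`trioburden.records`. Annotation tag names default to
ANNOVAR-style spellings but are configurable, since annotation pipelines vary
in how they name the gene, consequence, MPC, and gnomAD-frequency fields.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from cyvcf2 import VCF

from .records import (
    Consequence,
    CoverageRecord,
    DamageClass,
    DeNovoCall,
    GeneSetCollection,
    MemberEvidence,
    PedigreeEntry,
    Rarity,
    Role,
    Sex,
    VariantRecord,
    parse_consequence,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationTags:
    """INFO-field spellings used to pull annotations out of a VCF."""

    gene: str = "Gene.refGene"
    consequence: str = "ExonicFunc.refGene"
    mpc: str = "MPC"
    gnomad_af: str = "gnomAD_nonneuro_AF"
    mq: str = "MQ"


def read_ped(path: str | Path) -> list[PedigreeEntry]:
    """Read a 6-column PED file into pedigree entries with trio roles.

    The child is the member whose father and mother columns are non-zero;
    each family must contain exactly one child, one mother, one father.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"PED line has <6 columns: {line!r}")
            rows.append(fields[:6])

    entries: list[PedigreeEntry] = []
    by_family: dict[str, list[Sequence[str]]] = {}
    for row in rows:
        by_family.setdefault(row[0], []).append(row)
    for fam, members in by_family.items():
        children = [m for m in members if m[2] != "0" and m[3] != "0"]
        if len(children) != 1:
            raise ValueError(
                f"family {fam} must have exactly one child, found "
                f"{len(children)}"
            )
        child = children[0]
        father_id, mother_id = child[2], child[3]
        ids = {m[1]: m for m in members}
        for required, role in ((child[1], Role.CHILD),
                               (mother_id, Role.MOTHER),
                               (father_id, Role.FATHER)):
            if required not in ids:
                raise ValueError(
                    f"family {fam}: member {required} ({role.value}) "
                    f"missing from PED"
                )
            row = ids[required]
            sex = Sex.MALE if row[4] == "1" else Sex.FEMALE
            entries.append(
                PedigreeEntry(
                    family_id=fam,
                    member_id=required,
                    role=role,
                    sex=sex,
                    affected=row[5] == "2",
                )
            )
    return entries


def _trios(pedigree: Iterable[PedigreeEntry]) -> dict[str, dict[Role, PedigreeEntry]]:
    out: dict[str, dict[Role, PedigreeEntry]] = {}
    for entry in pedigree:
        out.setdefault(entry.family_id, {})[entry.role] = entry
    for fam, roles in out.items():
        missing = set(Role) - set(roles)
        if missing:
            raise ValueError(
                f"family {fam} missing roles: "
                + ", ".join(sorted(r.value for r in missing))
            )
    return out


def _info_for_alt(value, alt_index: int):
    """Annotation INFO fields may carry one value per ALT allele."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[alt_index] if alt_index < len(value) else value[0]
    if isinstance(value, str) and "," in value:
        parts = value.split(",")
        return parts[alt_index] if alt_index < len(parts) else parts[0]
    return value


def _member_evidence(dp, ad_row, alt_index: int, mq) -> MemberEvidence:
    total = int(dp) if dp is not None and dp >= 0 else None
    alt = None
    if ad_row is not None:
        raw = ad_row[alt_index + 1] if len(ad_row) > alt_index + 1 else None
        if raw is not None and raw >= 0:
            alt = int(raw)
    if total is not None and alt is not None and alt > total:
        # joint callers occasionally emit AD sums exceeding DP after
        # downsampling; clamp rather than reject
        total = alt
    return MemberEvidence(dp=total, alt_dp=alt, mq=mq)


def read_trio_variants(
    vcf_path: str | Path,
    pedigree: Sequence[PedigreeEntry],
    tags: AnnotationTags = AnnotationTags(),
    normalize_chr: Optional[str] = None,
) -> list[VariantRecord]:
    """Read a jointly-called VCF into one record per (family, site, alt).

    Multi-allelic sites are decomposed into one record per ALT allele.
    Records whose per-member depth fields are missing are returned with
    unevaluable evidence (filters fail them explicitly) rather than dropped.

    Parameters
    ----------
    normalize_chr
        ``None`` keeps chromosome labels as-is; ``"strip"`` removes a
        leading ``chr``; ``"add"`` ensures one.
    """
    trios = _trios(pedigree)
    vcf = VCF(str(vcf_path))
    sample_index = {s: i for i, s in enumerate(vcf.samples)}
    for fam, roles in trios.items():
        for role, entry in roles.items():
            if entry.member_id not in sample_index:
                raise ValueError(
                    f"sample {entry.member_id} ({role.value} of family "
                    f"{fam}) not present in VCF {vcf_path}"
                )

    records: list[VariantRecord] = []
    for variant in vcf:
        chrom = variant.CHROM
        if normalize_chr == "strip":
            chrom = chrom.removeprefix("chr")
        elif normalize_chr == "add" and not chrom.startswith("chr"):
            chrom = "chr" + chrom
        try:
            depths = variant.format("DP")
        except KeyError:
            depths = None
        try:
            ad = variant.format("AD")
        except KeyError:
            ad = None
        site_mq = variant.INFO.get(tags.mq)
        for alt_index, alt in enumerate(variant.ALT):
            gene = _info_for_alt(variant.INFO.get(tags.gene), alt_index)
            conseq = _info_for_alt(
                variant.INFO.get(tags.consequence), alt_index
            )
            mpc = _info_for_alt(variant.INFO.get(tags.mpc), alt_index)
            af = _info_for_alt(variant.INFO.get(tags.gnomad_af), alt_index)
            consequence = (
                parse_consequence(str(conseq)) if conseq is not None
                else Consequence.OTHER
            )
            af = float(af) if af is not None else 0.0
            if not 0.0 <= af <= 1.0:
                raise ValueError(
                    f"malformed allele frequency {af} at "
                    f"{chrom}:{variant.POS}"
                )
            mpc_val = None
            if mpc is not None and consequence is Consequence.MISSENSE:
                try:
                    mpc_val = float(mpc)
                except (TypeError, ValueError):
                    mpc_val = None
            for fam, roles in trios.items():
                evidence = {}
                for role in Role:
                    idx = sample_index[roles[role].member_id]
                    dp = depths[idx][0] if depths is not None else None
                    if dp is not None and dp < 0:
                        dp = None
                    ad_row = ad[idx] if ad is not None else None
                    evidence[role] = _member_evidence(
                        dp, ad_row, alt_index, site_mq
                    )
                records.append(
                    VariantRecord(
                        family_id=fam,
                        chrom=chrom,
                        pos=variant.POS,
                        ref_allele=variant.REF,
                        alt_allele=alt,
                        gene=str(gene) if gene is not None else "",
                        consequence=consequence,
                        gnomad_nonneuro_af=af,
                        child_sex=roles[Role.CHILD].sex,
                        mpc=mpc_val,
                        child=evidence[Role.CHILD],
                        mother=evidence[Role.MOTHER],
                        father=evidence[Role.FATHER],
                    )
                )
    return records


def read_coverage_table(path: str | Path) -> list[CoverageRecord]:
    """Read a per-family callable-coverage TSV (family_id, callable_bp)."""
    records: list[CoverageRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("coverage table %s is empty", path)
            return []
        for col in ("family_id", "callable_bp"):
            if col not in reader.fieldnames:
                raise ValueError(f"coverage table missing column {col!r}")
        for row in reader:
            fam = row["family_id"]
            if fam in seen:
                raise ValueError(f"duplicate family_id {fam!r} in {path}")
            seen.add(fam)
            records.append(
                CoverageRecord(family_id=fam,
                               callable_bp=int(row["callable_bp"]))
            )
    if not records:
        logger.warning("coverage table %s has no data rows", path)
    return records


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>source<TAB>genes...``."""
    sets: dict[str, frozenset[str]] = {}
    sources: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    f"expected >= 3"
                )
            name, source = fields[0], fields[1]
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            sets[name] = genes
            sources[name] = source
    return GeneSetCollection(sets=sets, sources=sources)


_TABLE_COLUMNS = [
    "proband_id", "gene", "chrom", "pos", "ref_allele", "alt_allele",
    "consequence", "mpc", "gnomad_nonneuro_af", "child_sex", "rarity",
    "damage_class",
]


def write_denovo_table(calls: Sequence[DeNovoCall], path: str | Path) -> None:
    """Write calls as a TSV (one row per call, published-table layout).

    MPC is written only for missense calls; the paired reader
    :func:`read_denovo_table` restores every tabulated field losslessly.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABLE_COLUMNS)
        for call in calls:
            r = call.record
            writer.writerow([
                call.family_id, r.gene, r.chrom, r.pos, r.ref_allele,
                r.alt_allele, r.consequence.value,
                "" if r.mpc is None else repr(r.mpc),
                repr(r.gnomad_nonneuro_af), r.child_sex.value,
                call.rarity.value, call.damage_class.value,
            ])


def read_denovo_table(path: str | Path) -> list[DeNovoCall]:
    """Read a call table written by :func:`write_denovo_table`.

    Genotype evidence is not tabulated, so the returned records carry no
    per-member depths; all other fields round-trip exactly.
    """
    calls: list[DeNovoCall] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            record = VariantRecord(
                family_id=row["proband_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref_allele=row["ref_allele"],
                alt_allele=row["alt_allele"],
                gene=row["gene"],
                consequence=Consequence(row["consequence"]),
                gnomad_nonneuro_af=float(row["gnomad_nonneuro_af"]),
                child_sex=Sex(row["child_sex"]),
                mpc=float(row["mpc"]) if row["mpc"] else None,
            )
            calls.append(
                DeNovoCall(
                    record=record,
                    family_id=row["proband_id"],
                    rarity=Rarity(row["rarity"]),
                    damage_class=DamageClass(row["damage_class"]),
                )
            )
    return calls
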