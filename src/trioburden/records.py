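"""Typed records shared across the pipeline.

Coordinates are 1-based and fully closed throughout (VCF convention); no
0-based representation is exposed outside the BED utilities in
:mod:`trioburden.burden_stats`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Consequence(str, enum.Enum):
    """Coding consequence of a variant, collapsed to the classes the burden
    analysis distinguishes."""

    STOPGAIN = "stopgain"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    CANONICAL_SPLICE = "canonical_splice"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Spellings accepted when parsing annotation fields (ANNOVAR-style names,
#: spaces or underscores, case-insensitive).
_CONSEQUENCE_ALIASES = {
    "stopgain": Consequence.STOPGAIN,
    "stop_gain": Consequence.STOPGAIN,
    "stopgain_snv": Consequence.STOPGAIN,
    "frameshift_insertion": Consequence.FRAMESHIFT_INSERTION,
    "frameshift_deletion": Consequence.FRAMESHIFT_DELETION,
    "splicing": Consequence.CANONICAL_SPLICE,
    "splice": Consequence.CANONICAL_SPLICE,
    "canonical_splice": Consequence.CANONICAL_SPLICE,
    "missense": Consequence.MISSENSE,
    "nonsynonymous_snv": Consequence.MISSENSE,
    "synonymous": Consequence.SYNONYMOUS,
    "synonymous_snv": Consequence.SYNONYMOUS,
    "other": Consequence.OTHER,
}


def parse_consequence(label: str) -> Consequence:
    """Map an annotation string (e.g. ANNOVAR ``ExonicFunc``) to a
    :class:`Consequence`; unrecognized labels map to ``OTHER``."""
    key = label.strip().lower().replace(" ", "_")
    return _CONSEQUENCE_ALIASES.get(key, Consequence.OTHER)


class DamageClass(str, enum.Enum):
    PTV = "PTV"
    MISD = "MisD"
    MISSENSE_OTHER = "missense_other"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Severity used when collapsing to one variant per person per gene.
DAMAGE_SEVERITY = {
    DamageClass.PTV: 0,
    DamageClass.MISD: 1,
    DamageClass.MISSENSE_OTHER: 2,
    DamageClass.SYNONYMOUS: 3,
    DamageClass.OTHER: 4,
}


class Rarity(str, enum.Enum):
    COMMON = "common"
    RARE = "rare"
    ULTRA_RARE = "ultra_rare"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Role(str, enum.Enum):
    CHILD = "child"
    MOTHER = "mother"
    FATHER = "father"


@dataclass(frozen=True)
class MemberEvidence:
    """Per-sample genotype evidence at one site.

    ``None`` fields mean the value was absent from the call set; filters
    treat such records as unevaluable rather than silently dropping them.
    """

    dp: Optional[int]
    alt_dp: Optional[int]
    mq: Optional[float]

    def __post_init__(self) -> None:
        if (
            self.dp is not None
            and self.alt_dp is not None
            and self.alt_dp > self.dp
        ):
            raise ValueError(
                f"alt depth {self.alt_dp} exceeds total depth {self.dp}"
            )

    @property
    def evaluable(self) -> bool:
        return self.dp is not None and self.alt_dp is not None


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant observation in one trio.

    ``mpc`` is meaningful only for missense variants; a missense record with
    missing MPC is retained (it simply cannot reach the damaging-missense
    class). ``gnomad_nonneuro_af`` is the allele frequency in the gnomAD
    subset of individuals not ascertained for neuropsychiatric conditions.
    """

    family_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str
    consequence: Consequence
    gnomad_nonneuro_af: float
    child_sex: Sex
    mpc: Optional[float] = None
    child: Optional[MemberEvidence] = None
    mother: Optional[MemberEvidence] = None
    father: Optional[MemberEvidence] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not 0.0 <= self.gnomad_nonneuro_af <= 1.0:
            raise ValueError(
                f"gnomAD AF {self.gnomad_nonneuro_af!r} outside [0, 1] "
                f"at {self.chrom}:{self.pos}"
            )
        if self.mpc is not None and self.mpc < 0:
            raise ValueError(f"MPC must be nonnegative, got {self.mpc}")

    @property
    def is_x(self) -> bool:
        return self.chrom.lower().removeprefix("chr") == "x"

    def evidence(self, role: Role) -> Optional[MemberEvidence]:
        return {Role.CHILD: self.child, Role.MOTHER: self.mother,
                Role.FATHER: self.father}[role]


@dataclass(frozen=True)
class PedigreeEntry:
    family_id: str
    member_id: str
    role: Role
    sex: Sex
    affected: bool


@dataclass(frozen=True)
class CoverageRecord:
    """Callable-exome size for one trio: loci in the capture intersection
    where all members meet depth/quality thresholds (the denominator of the
    mutation rate)."""

    family_id: str
    callable_bp: int

    def __post_init__(self) -> None:
        if self.callable_bp < 0:
            raise ValueError(
                f"callable_bp must be >= 0 for family {self.family_id}"
            )


@dataclass(frozen=True)
class DeNovoCall:
    """A variant that passed all trio de novo filters."""

    record: VariantRecord
    family_id: str
    rarity: Rarity
    damage_class: DamageClass
    filter_trace: tuple = field(default=(), compare=False)

    @property
    def gene(self) -> str:
        return self.record.gene

    def table_key(self) -> tuple:
        """Fields preserved by the tabular writer/reader round trip."""
        r = self.record
        return (
            self.family_id, r.gene, r.chrom, r.pos, r.ref_allele,
            r.alt_allele, r.consequence, r.mpc, r.gnomad_nonneuro_af,
            r.child_sex, self.rarity, self.damage_class,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics); symbols uppercase-normalized."""

    sets: dict[str, frozenset[str]]
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()
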