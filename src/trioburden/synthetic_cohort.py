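"""Synthetic trio cohorts and case-control count tables.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without access to controlled sequencing
data: per-trio de novo events are Poisson with mean twice the summed
per-gene haploid mutation rate (two haplotypes per child), placed in genes
proportionally to their rates; risk genes carry an elevated rate (relative
risk multiplier) in case trios only; inherited variants sit in exactly one
parent and transmit with probability 1/2; every emitted record carries
read-depth, allele-fraction, and mapping-quality values drawn from explicit
noise models so the genotype filters are genuinely exercised; and the truth
(which records are real de novos, which genes are risk genes) is recorded.

Case-control counts follow the generative model of the gene-association
stage: per-gene baselines scaled by sample size, with a Gamma-distributed
relative risk in risk genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gene_association import Category, TadaHyperparameters
from .records import (
    Consequence,
    CoverageRecord,
    MemberEvidence,
    PedigreeEntry,
    Role,
    Sex,
    VariantRecord,
)

_BASES = np.array(["A", "C", "G", "T"])

_CLASSES = ("ptv", "misd", "mis_other", "syn")

_PTV_CONSEQUENCES = (
    Consequence.STOPGAIN,
    Consequence.FRAMESHIFT_DELETION,
    Consequence.FRAMESHIFT_INSERTION,
    Consequence.CANONICAL_SPLICE,
)


def default_gene_table(
    n_genes: int = 200,
    seed: int = 0,
    x_fraction: float = 0.05,
    total_ptv: float = 0.04,
    total_misd: float = 0.035,
    total_mis_other: float = 0.34,
    total_syn: float = 0.125,
) -> pd.DataFrame:
    """Per-gene haploid mutation rates per class, drawn log-uniformly and
    scaled so class totals match typical human exome-wide haploid totals
    (about 1.1 coding de novo events per child across two haplotypes).

    The last ``x_fraction`` of genes are placed on the X chromosome so the
    sex-specific filter branch is exercised.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    totals = {
        "ptv": total_ptv, "misd": total_misd,
        "mis_other": total_mis_other, "syn": total_syn,
    }
    n_x = int(round(n_genes * x_fraction))
    chroms = [str(1 + i % 22) for i in range(n_genes - n_x)] + ["X"] * n_x
    table = pd.DataFrame({
        "gene": [f"GENE{i:05d}" for i in range(n_genes)],
        "chrom": chroms,
        "start": 1_000_000 + 100_000 * np.arange(n_genes),
    })
    for cls in _CLASSES:
        raw = np.exp(rng.uniform(np.log(0.1), np.log(10.0), size=n_genes))
        table[f"mu_{cls}"] = raw / raw.sum() * totals[cls]
    return table


@dataclass(frozen=True)
class DepthModel:
    """Gamma-Poisson per-sample depth: mean ``mean`` with overdispersion
    shape ``shape`` (larger = tighter)."""

    mean: float = 55.0
    shape: float = 8.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lam = rng.gamma(self.shape, self.mean / self.shape, size=n)
        return np.maximum(rng.poisson(lam), 1)


@dataclass(frozen=True)
class NoiseModel:
    """Allele-fraction and mapping-quality noise.

    True heterozygous alt fractions are Beta(20, 20) around 0.5, so most
    but not all calls pass the 0.3-0.7 gate; hemizygous male-X calls use a
    near-1 Beta. Parents of true de novos carry a small contamination/error
    alt-read rate (mean fraction 0.005) so the parental-absence gate is
    exercised. A small fraction of sites receives low mapping quality.
    """

    het_af_alpha: float = 20.0
    het_af_beta: float = 20.0
    hemi_af_alpha: float = 30.0
    hemi_af_beta: float = 1.5
    parent_alt_fraction: float = 0.005
    mq_mean: float = 59.0
    mq_sd: float = 2.0
    mq_low_prob: float = 0.02
    mq_low_range: tuple[float, float] = (10.0, 29.0)
    denovo_af_spike_prob: float = 0.1
    denovo_af_spike_range: tuple[float, float] = (1e-5, 5e-5)

    def sample_mq(self, rng: np.random.Generator) -> float:
        if self.mq_low_prob > 0 and rng.random() < self.mq_low_prob:
            return float(rng.uniform(*self.mq_low_range))
        return float(min(60.0, rng.normal(self.mq_mean, self.mq_sd)))

    def sample_denovo_af(self, rng: np.random.Generator) -> float:
        if (
            self.denovo_af_spike_prob > 0
            and rng.random() < self.denovo_af_spike_prob
        ):
            return float(rng.uniform(*self.denovo_af_spike_range))
        return 0.0


@dataclass(frozen=True)
class CallableModel:
    """Per-trio callable bp: truncated normal around the size of a capture
    intersection (about 32 Mb)."""

    mean: float = 3.2e7
    sd: float = 2e6
    minimum: int = 1_000_000

    def sample(self, rng: np.random.Generator) -> int:
        return int(max(self.minimum, rng.normal(self.mean, self.sd)))


@dataclass
class SimulationConfig:
    """All generative parameters for one synthetic cohort.

    Defaults emulate the study conditions of the ADHD trio analysis:
    147 case and 780 control trios, case probands 83% male and control
    children 45% male, ~1.1 coding de novo events per child. The relative
    risk multipliers apply to risk genes in case trios only.
    """

    n_case_trios: int = 147
    n_control_trios: int = 780
    gene_table: pd.DataFrame = field(default_factory=default_gene_table)
    risk_gene_fraction: float = 0.0
    gamma_ptv: float = 1.0
    gamma_misd: float = 1.0
    inherited_rate: float = 2.0
    depth_model: DepthModel = field(default_factory=DepthModel)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    callable_model: CallableModel = field(default_factory=CallableModel)
    male_fraction_case: float = 0.83
    male_fraction_control: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.gene_table) == 0:
            raise ValueError("gene_table has zero genes")
        if not 0.0 <= self.risk_gene_fraction < 1.0:
            raise ValueError("risk_gene_fraction must be in [0, 1)")
        for cls in _CLASSES:
            if (self.gene_table[f"mu_{cls}"] < 0).any():
                raise ValueError("mutation rates must be nonnegative")
        if min(self.gamma_ptv, self.gamma_misd) < 0:
            raise ValueError("relative risks must be nonnegative")
        if self.inherited_rate < 0:
            raise ValueError("inherited_rate must be nonnegative")


@dataclass
class SimulatedCohort:
    variants: list[VariantRecord]
    pedigree: list[PedigreeEntry]
    coverage: list[CoverageRecord]
    truth: pd.DataFrame
    risk_genes: frozenset[str]

    def case_families(self) -> list[str]:
        return sorted({
            e.family_id for e in self.pedigree
            if e.role is Role.CHILD and e.affected
        })

    def control_families(self) -> list[str]:
        return sorted({
            e.family_id for e in self.pedigree
            if e.role is Role.CHILD and not e.affected
        })


def _consequence_for_class(cls: str, rng: np.random.Generator):
    if cls == "ptv":
        conseq = _PTV_CONSEQUENCES[rng.integers(len(_PTV_CONSEQUENCES))]
        mpc = None
    elif cls == "misd":
        conseq = Consequence.MISSENSE
        mpc = float(rng.uniform(2.05, 3.5))
    elif cls == "mis_other":
        conseq = Consequence.MISSENSE
        mpc = float(rng.uniform(0.0, 2.0))
    else:
        conseq = Consequence.SYNONYMOUS
        mpc = None
    return conseq, mpc


def _alleles(conseq: Consequence, rng: np.random.Generator) -> tuple[str, str]:
    ref = str(_BASES[rng.integers(4)])
    if conseq is Consequence.FRAMESHIFT_DELETION:
        return ref + str(_BASES[rng.integers(4)]), ref
    if conseq is Consequence.FRAMESHIFT_INSERTION:
        return ref, ref + "".join(_BASES[rng.integers(4, size=2)])
    alt = str(_BASES[rng.integers(4)])
    while alt == ref:
        alt = str(_BASES[rng.integers(4)])
    return ref, alt


def _member(
    rng: np.random.Generator,
    depth: DepthModel,
    af: float,
    mq: float,
    min_alt: int = 0,
) -> MemberEvidence:
    dp = int(depth.sample(rng, 1)[0])
    alt = int(rng.binomial(dp, min(af, 1.0)))
    alt = max(alt, min_alt)
    dp = max(dp, alt)
    return MemberEvidence(dp=dp, alt_dp=alt, mq=mq)


def simulate_trio_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a trio cohort with truth labels; fully determined by the
    config (including its seed)."""
    rng = np.random.default_rng(config.seed)
    table = config.gene_table.reset_index(drop=True)
    n_genes = len(table)
    risk = rng.random(n_genes) < config.risk_gene_fraction
    risk_genes = frozenset(table.loc[risk, "gene"])

    mu = {cls: table[f"mu_{cls}"].to_numpy(dtype=float) for cls in _CLASSES}
    multipliers = {"ptv": config.gamma_ptv, "misd": config.gamma_misd,
                   "mis_other": 1.0, "syn": 1.0}
    class_probs_flat = np.array([mu[c].sum() for c in _CLASSES])
    if class_probs_flat.sum() > 0:
        class_probs_flat = class_probs_flat / class_probs_flat.sum()

    variants: list[VariantRecord] = []
    pedigree: list[PedigreeEntry] = []
    coverage: list[CoverageRecord] = []
    truth_rows: list[dict] = []
    noise = config.noise_model

    arms = (
        ("CASE", config.n_case_trios, True, config.male_fraction_case),
        ("CTRL", config.n_control_trios, False, config.male_fraction_control),
    )
    for prefix, n_trios, is_case, male_fraction in arms:
        for i in range(n_trios):
            fam = f"{prefix}{i + 1:05d}"
            child_sex = (
                Sex.MALE if rng.random() < male_fraction else Sex.FEMALE
            )
            pedigree.extend([
                PedigreeEntry(fam, f"{fam}.p1", Role.CHILD, child_sex,
                              affected=is_case),
                PedigreeEntry(fam, f"{fam}.mo", Role.MOTHER, Sex.FEMALE,
                              affected=False),
                PedigreeEntry(fam, f"{fam}.fa", Role.FATHER, Sex.MALE,
                              affected=False),
            ])
            coverage.append(
                CoverageRecord(fam, config.callable_model.sample(rng))
            )

            # true de novo events, class by class
            for cls in _CLASSES:
                rates = mu[cls].copy()
                if is_case and multipliers[cls] != 1.0:
                    rates[risk] *= multipliers[cls]
                total = rates.sum()
                if total == 0:
                    continue
                n_events = rng.poisson(2.0 * total)
                if n_events == 0:
                    continue
                gene_idx = rng.choice(
                    n_genes, size=n_events, p=rates / total
                )
                for gi in gene_idx:
                    row = table.iloc[int(gi)]
                    conseq, mpc = _consequence_for_class(cls, rng)
                    ref, alt = _alleles(conseq, rng)
                    pos = int(row["start"] + rng.integers(0, 50_000))
                    mq = noise.sample_mq(rng)
                    hemi = row["chrom"] == "X" and child_sex is Sex.MALE
                    if hemi:
                        child_af = rng.beta(
                            noise.hemi_af_alpha, noise.hemi_af_beta
                        )
                    else:
                        child_af = rng.beta(
                            noise.het_af_alpha, noise.het_af_beta
                        )
                    record = VariantRecord(
                        family_id=fam,
                        chrom=str(row["chrom"]),
                        pos=pos,
                        ref_allele=ref,
                        alt_allele=alt,
                        gene=str(row["gene"]),
                        consequence=conseq,
                        gnomad_nonneuro_af=noise.sample_denovo_af(rng),
                        child_sex=child_sex,
                        mpc=mpc,
                        child=_member(rng, config.depth_model, child_af, mq,
                                      min_alt=1),
                        mother=_member(rng, config.depth_model,
                                       noise.parent_alt_fraction, mq),
                        father=_member(rng, config.depth_model,
                                       noise.parent_alt_fraction, mq),
                    )
                    variants.append(record)
                    truth_rows.append({
                        "family_id": fam, "chrom": record.chrom,
                        "pos": pos, "ref": ref, "alt": alt,
                        "gene": record.gene, "class": cls,
                        "is_denovo": True, "is_case": is_case,
                    })

            # inherited variants: one carrier parent, transmission prob 1/2
            n_inherited = rng.poisson(config.inherited_rate)
            for _ in range(n_inherited):
                cls = _CLASSES[
                    rng.choice(len(_CLASSES), p=class_probs_flat)
                ] if class_probs_flat.sum() > 0 else "syn"
                gi = int(rng.integers(n_genes))
                row = table.iloc[gi]
                conseq, mpc = _consequence_for_class(cls, rng)
                ref, alt = _alleles(conseq, rng)
                pos = int(row["start"] + rng.integers(0, 50_000))
                mq = noise.sample_mq(rng)
                carrier_is_mother = bool(rng.random() < 0.5)
                transmitted = bool(rng.random() < 0.5)
                carrier_af = rng.beta(noise.het_af_alpha, noise.het_af_beta)
                child_af = (
                    rng.beta(noise.het_af_alpha, noise.het_af_beta)
                    if transmitted else noise.parent_alt_fraction
                )
                parent_evidence = {
                    True: _member(rng, config.depth_model, carrier_af, mq),
                    False: _member(rng, config.depth_model,
                                   noise.parent_alt_fraction, mq),
                }
                record = VariantRecord(
                    family_id=fam,
                    chrom=str(row["chrom"]),
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    gene=str(row["gene"]),
                    consequence=conseq,
                    gnomad_nonneuro_af=float(
                        math.exp(rng.uniform(math.log(1e-6), math.log(1e-2)))
                    ),
                    child_sex=child_sex,
                    mpc=mpc,
                    child=_member(rng, config.depth_model, child_af, mq),
                    mother=parent_evidence[carrier_is_mother],
                    father=parent_evidence[not carrier_is_mother],
                )
                variants.append(record)
                truth_rows.append({
                    "family_id": fam, "chrom": record.chrom, "pos": pos,
                    "ref": ref, "alt": alt, "gene": record.gene,
                    "class": cls, "is_denovo": False, "is_case": is_case,
                })

    truth = pd.DataFrame(
        truth_rows,
        columns=["family_id", "chrom", "pos", "ref", "alt", "gene", "class",
                 "is_denovo", "is_case"],
    )
    return SimulatedCohort(
        variants=variants,
        pedigree=pedigree,
        coverage=coverage,
        truth=truth,
        risk_genes=risk_genes,
    )


def simulate_case_control_counts(
    gene_table: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    hyperparams: TadaHyperparameters,
    pi_sim: float,
    seed: int,
    risk_genes: Optional[Sequence[str]] = None,
    baseline_scale: float = 0.2,
) -> pd.DataFrame:
    """Per-gene case-control counts from the hierarchical generative model.

    Non-risk genes: case and control counts Poisson with rates proportional
    to sample size and a per-gene baseline (``baseline_scale`` times the
    gene's de novo mutation rate). Risk genes: the case rate is multiplied
    by a Gamma-distributed relative risk drawn from the case-control priors.
    Columns: gene, x_ca_ptv, x_co_ptv, x_ca_misd, x_co_misd, is_risk.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("sample sizes must be positive")
    if not 0.0 <= pi_sim < 1.0:
        raise ValueError("pi_sim must be in [0, 1)")
    rng = np.random.default_rng(seed)
    table = gene_table.reset_index(drop=True)
    n_genes = len(table)
    if risk_genes is None:
        risk = rng.random(n_genes) < pi_sim
    else:
        risk = table["gene"].isin(set(risk_genes)).to_numpy()

    out = {"gene": table["gene"], "is_risk": risk}
    for cls, cat in (("ptv", Category.CC_PTV), ("misd", Category.CC_MISD)):
        q = baseline_scale * table[f"mu_{cls}"].to_numpy(dtype=float)
        prior = hyperparams.priors[cat]
        gamma = np.ones(n_genes)
        n_risk = int(risk.sum())
        if n_risk:
            gamma[risk] = rng.gamma(
                prior.shape, 1.0 / prior.beta, size=n_risk
            )
        out[f"x_ca_{cls}"] = rng.poisson(n_cases * q * gamma)
        out[f"x_co_{cls}"] = rng.poisson(n_controls * q)
    return pd.DataFrame(out)


def simulate_denovo_gene_counts(
    gene_table: pd.DataFrame,
    n_trio: int,
    hyperparams: TadaHyperparameters,
    risk_genes: Sequence[str],
    seed: int,
) -> pd.DataFrame:
    """Per-gene de novo PTV/MisD counts under the TADA generative model:
    Poisson(2*N*mu*gamma) with gamma ~ Gamma prior in risk genes, 1
    elsewhere. Companion to :func:`simulate_case_control_counts` for
    gene-level calibration studies."""
    if n_trio <= 0:
        raise ValueError("n_trio must be positive")
    rng = np.random.default_rng(seed)
    table = gene_table.reset_index(drop=True)
    risk = table["gene"].isin(set(risk_genes)).to_numpy()
    out = {"gene": table["gene"], "is_risk": risk}
    for cls, cat in (("ptv", Category.DN_PTV), ("misd", Category.DN_MISD)):
        mu = table[f"mu_{cls}"].to_numpy(dtype=float)
        prior = hyperparams.priors[cat]
        gamma = np.ones(len(table))
        n_risk = int(risk.sum())
        if n_risk:
            gamma[risk] = rng.gamma(
                prior.shape, 1.0 / prior.beta, size=n_risk
            )
        out[f"x_dn_{cls}"] = rng.poisson(2.0 * n_trio * mu * gamma)
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# writers: the same formats io_formats reads

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=Gene.refGene,Number=A,Type=String,Description="Gene symbol">
##INFO=<ID=ExonicFunc.refGene,Number=A,Type=String,Description="Consequence">
##INFO=<ID=MPC,Number=A,Type=Float,Description="Missense MPC score">
##INFO=<ID=gnomAD_nonneuro_AF,Number=A,Type=Float,Description="gnomAD non-neuro allele frequency">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""

_CHROM_ORDER = {str(c): c for c in range(1, 23)} | {"X": 23, "Y": 24}


def _chrom_rank(chrom: str) -> int:
    return _CHROM_ORDER.get(chrom.removeprefix("chr"), 99)


def _gt(evidence: MemberEvidence) -> str:
    if evidence.dp is None or evidence.alt_dp is None:
        return "./."
    af = evidence.alt_dp / evidence.dp if evidence.dp else 0.0
    if af >= 0.9:
        return "1/1"
    return "0/1" if evidence.alt_dp > 0 else "0/0"


def write_family_vcf(
    records: Sequence[VariantRecord],
    pedigree: Sequence[PedigreeEntry],
    path: str | Path,
) -> None:
    """Write one family's records as a VCF 4.2 text file (child, mother,
    father sample columns), readable by ``io_formats.read_trio_variants``."""
    members = {e.role: e for e in pedigree}
    sample_ids = [members[Role.CHILD].member_id,
                  members[Role.MOTHER].member_id,
                  members[Role.FATHER].member_id]
    ordered = sorted(records, key=lambda r: (_chrom_rank(r.chrom), r.pos,
                                             r.alt_allele))
    contigs = sorted({r.chrom for r in ordered}, key=_chrom_rank)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids) + "\n"
        )
        for r in ordered:
            info = [
                f"Gene.refGene={r.gene}",
                f"ExonicFunc.refGene={r.consequence.value}",
                f"gnomAD_nonneuro_AF={r.gnomad_nonneuro_af:.6g}",
            ]
            if r.mpc is not None:
                info.append(f"MPC={r.mpc:.4g}")
            mqs = [e.mq for e in (r.child, r.mother, r.father)
                   if e is not None and e.mq is not None]
            if mqs:
                info.append(f"MQ={min(mqs):.4g}")
            samples = []
            for e in (r.child, r.mother, r.father):
                if e is None or not e.evaluable:
                    samples.append("./.:.:.")
                else:
                    samples.append(
                        f"{_gt(e)}:{e.dp}:{e.dp - e.alt_dp},{e.alt_dp}"
                    )
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}"
                f"\t.\t.\t{';'.join(info)}\tGT:DP:AD\t"
                + "\t".join(samples) + "\n"
            )


def write_ped(pedigree: Sequence[PedigreeEntry], path: str | Path) -> None:
    by_family: dict[str, dict[Role, PedigreeEntry]] = {}
    for e in pedigree:
        by_family.setdefault(e.family_id, {})[e.role] = e
    with open(path, "w") as fh:
        for fam in sorted(by_family):
            roles = by_family[fam]
            child, mother, father = (
                roles[Role.CHILD], roles[Role.MOTHER], roles[Role.FATHER]
            )
            for entry, pat, mat in (
                (father, "0", "0"), (mother, "0", "0"),
                (child, father.member_id, mother.member_id),
            ):
                sex = "1" if entry.sex is Sex.MALE else "2"
                pheno = "2" if entry.affected else "1"
                fh.write(
                    f"{fam}\t{entry.member_id}\t{pat}\t{mat}\t{sex}\t"
                    f"{pheno}\n"
                )


def write_coverage(
    coverage: Sequence[CoverageRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tcallable_bp\n")
        for c in coverage:
            fh.write(f"{c.family_id}\t{c.callable_bp}\n")


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> Path:
    """Materialize a cohort on disk: one VCF per family under ``vcf/``,
    plus ``cohort.ped``, ``coverage.tsv`` and ``truth.tsv``.

    Per-family VCFs (rather than one joint file) keep each family's sites
    independent; the reader emits one record per (family, site, alt), so a
    joint file would cross every family with every other family's sites.
    """
    outdir = Path(outdir)
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    by_family_records: dict[str, list[VariantRecord]] = {}
    for r in cohort.variants:
        by_family_records.setdefault(r.family_id, []).append(r)
    by_family_ped: dict[str, list[PedigreeEntry]] = {}
    for e in cohort.pedigree:
        by_family_ped.setdefault(e.family_id, []).append(e)
    for fam, ped in by_family_ped.items():
        write_family_vcf(
            by_family_records.get(fam, []), ped, vcf_dir / f"{fam}.vcf"
        )
    write_ped(cohort.pedigree, outdir / "cohort.ped")
    write_coverage(cohort.coverage, outdir / "coverage.tsv")
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return outdir
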