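"""Packaged reference data.

``adhd_ultra_rare_denovo_calls.tsv`` transcribes the published table of
ultra-rare de novo damaging variants identified in 147 ADHD parent-child
trios (24 variants in 23 probands), including gene symbols, hg19
coordinates, alleles, consequence classes with MPC scores for missense
variants, gnomAD non-neuro allele frequencies, and whether each gene was
reported as a likely neurodevelopmental-disorder (NDD) risk gene in the
largest autism / developmental-delay meta-analysis. Indel Ref/Alt alleles
follow the left-anchored VCF convention. Proband sex is not part of the
published table; records default to male (the cohort is 83% male), which no
downstream classification uses.
"""

from __future__ import annotations

import csv
from importlib import resources

import pandas as pd

from .records import Sex, VariantRecord, parse_consequence

_CALLS_RESOURCE = "adhd_ultra_rare_denovo_calls.tsv"


def _open_resource(name: str):
    return resources.files("trioburden.data").joinpath(name).open()


def load_adhd_trio_calls() -> tuple[list[VariantRecord], dict[str, bool]]:
    """The published ADHD trio ultra-rare de novo damaging call set.

    Returns (records, ndd_flags): one annotated record per variant (the
    proband identifier is stored as ``family_id``) and a per-gene flag for
    whether the gene is a reported likely NDD risk gene.
    """
    records: list[VariantRecord] = []
    ndd_flags: dict[str, bool] = {}
    with _open_resource(_CALLS_RESOURCE) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                VariantRecord(
                    family_id=row["proband_id"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref_allele=row["ref"],
                    alt_allele=row["alt"],
                    gene=row["gene"],
                    consequence=parse_consequence(row["variant_class"]),
                    gnomad_nonneuro_af=float(row["gnomad_nonneuro_af"]),
                    child_sex=Sex.MALE,
                    mpc=float(row["mpc"]) if row["mpc"] else None,
                )
            )
            flag = row["ndd_risk"].strip().lower().startswith("yes")
            ndd_flags[row["gene"]] = ndd_flags.get(row["gene"], False) or flag
    return records, ndd_flags


def load_adhd_trio_table() -> pd.DataFrame:
    """The same call set as a data frame, all printed columns included."""
    with _open_resource(_CALLS_RESOURCE) as fh:
        return pd.read_csv(fh, sep="\t")
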