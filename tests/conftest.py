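import pytest

from trioburden.records import (
    Consequence,
    MemberEvidence,
    Sex,
    VariantRecord,
)


@pytest.fixture
def make_record():
    """Factory for variant records with sensible trio evidence defaults."""

    def _make(
        chrom="1",
        pos=1000,
        ref="A",
        alt="T",
        gene="GENE1",
        consequence=Consequence.MISSENSE,
        af=0.0,
        mpc=None,
        sex=Sex.FEMALE,
        child=(30, 15, 60.0),
        mother=(30, 0, 60.0),
        father=(30, 0, 60.0),
        family_id="FAM1",
    ):
        def ev(t):
            if t is None:
                return None
            dp, alt_dp, mq = t
            return MemberEvidence(dp=dp, alt_dp=alt_dp, mq=mq)

        return VariantRecord(
            family_id=family_id,
            chrom=chrom,
            pos=pos,
            ref_allele=ref,
            alt_allele=alt,
            gene=gene,
            consequence=consequence,
            gnomad_nonneuro_af=af,
            child_sex=sex,
            mpc=mpc,
            child=ev(child),
            mother=ev(mother),
            father=ev(father),
        )

    return _make
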