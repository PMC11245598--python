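import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trioburden.denovo_discovery import (
    FilterThresholds,
    allele_fraction,
    call_denovos,
    classify_damage,
    classify_rarity,
    dedupe_per_gene,
    passes_denovo_filters,
    trio_qc,
)
from trioburden.records import (
    Consequence,
    DamageClass,
    DeNovoCall,
    Rarity,
    Sex,
    VariantRecord,
)

TH = FilterThresholds()


class TestAlleleFraction:
    @pytest.mark.parametrize(
        "alt,dp,expected", [(15, 30, 0.5), (0, 25, 0.0), (7, 20, 0.35)]
    )
    def test_values(self, alt, dp, expected):
        assert allele_fraction(alt, dp) == pytest.approx(expected)

    def test_zero_depth_unevaluable(self):
        assert allele_fraction(0, 0) is None


class TestGenotypeFilters:
    def test_clean_autosomal_call_passes(self, make_record):
        passed, trace = passes_denovo_filters(make_record())
        assert passed
        assert all(ok for _, ok in trace)

    def test_father_carrier_fails_parent_absence(self, make_record):
        r = make_record(father=(30, 3, 60.0))  # father AF 0.10
        passed, trace = passes_denovo_filters(r)
        assert not passed
        assert dict(trace)["parent_absence"] is False

    def test_male_x_hemizygous_passes_despite_father(self, make_record):
        r = make_record(
            chrom="chrX",
            sex=Sex.MALE,
            child=(40, 38, 60.0),      # AF 0.95
            mother=(30, 0, 60.0),
            father=(30, 30, 60.0),     # father carries the allele
        )
        passed, _ = passes_denovo_filters(r)
        assert passed

    def test_female_x_needs_both_parents_absent(self, make_record):
        r = make_record(
            chrom="chrX", sex=Sex.FEMALE, father=(30, 10, 60.0)
        )
        passed, _ = passes_denovo_filters(r)
        assert not passed

    def test_child_low_depth_fails(self, make_record):
        r = make_record(child=(18, 9, 60.0))
        passed, trace = passes_denovo_filters(r)
        assert not passed
        assert dict(trace)["member_depth"] is False

    @pytest.mark.parametrize("af,ok", [(0.3, True), (0.7, True),
                                       (0.29, False), (0.71, False)])
    def test_child_af_window_inclusive(self, make_record, af, ok):
        r = make_record(child=(100, int(round(af * 100)), 60.0))
        passed, _ = passes_denovo_filters(r)
        assert passed is ok

    def test_parent_af_threshold_is_strict(self, make_record):
        r = make_record(mother=(100, 5, 60.0))  # AF exactly 0.05
        passed, _ = passes_denovo_filters(r)
        assert not passed

    def test_low_mapping_quality_fails(self, make_record):
        r = make_record(child=(30, 15, 25.0), mother=(30, 0, 25.0),
                        father=(30, 0, 25.0))
        passed, trace = passes_denovo_filters(r)
        assert not passed
        assert dict(trace)["mapping_quality"] is False

    def test_unevaluable_evidence_fails_with_reason(self, make_record):
        r = make_record(child=None)
        passed, trace = passes_denovo_filters(r)
        assert not passed
        assert trace[0] == ("evaluable_evidence", False)


class TestDamageClass:
    @pytest.mark.parametrize(
        "consequence,mpc,expected",
        [
            (Consequence.STOPGAIN, None, DamageClass.PTV),
            (Consequence.FRAMESHIFT_DELETION, None, DamageClass.PTV),
            (Consequence.FRAMESHIFT_INSERTION, None, DamageClass.PTV),
            (Consequence.CANONICAL_SPLICE, None, DamageClass.PTV),
            (Consequence.MISSENSE, 2.1, DamageClass.MISD),
            (Consequence.MISSENSE, 2.0, DamageClass.MISSENSE_OTHER),
            (Consequence.MISSENSE, None, DamageClass.MISSENSE_OTHER),
            (Consequence.SYNONYMOUS, None, DamageClass.SYNONYMOUS),
            (Consequence.OTHER, None, DamageClass.OTHER),
        ],
    )
    def test_classes(self, make_record, consequence, mpc, expected):
        r = make_record(consequence=consequence, mpc=mpc)
        assert classify_damage(r) is expected


class TestRarity:
    @pytest.mark.parametrize(
        "af,expected",
        [
            (3.36e-5, Rarity.ULTRA_RARE),
            (0.0, Rarity.ULTRA_RARE),
            (5e-5, Rarity.RARE),       # strict upper bound
            (0.0005, Rarity.RARE),
            (0.001, Rarity.COMMON),    # strict upper bound
            (0.1, Rarity.COMMON),
        ],
    )
    def test_tiers(self, af, expected):
        assert classify_rarity(af) is expected


def _call(make_record, **kwargs):
    family = kwargs.pop("family_id", "FAM1")
    r = make_record(family_id=family, **kwargs)
    return DeNovoCall(
        record=r,
        family_id=family,
        rarity=classify_rarity(r.gnomad_nonneuro_af),
        damage_class=classify_damage(r),
    )


class TestDedupe:
    def test_most_severe_kept(self, make_record):
        stop = _call(make_record, consequence=Consequence.STOPGAIN, pos=200)
        syn = _call(make_record, consequence=Consequence.SYNONYMOUS, pos=100)
        assert dedupe_per_gene([syn, stop]) == [stop]

    def test_different_genes_both_kept(self, make_record):
        a = _call(make_record, gene="OCEL1",
                  consequence=Consequence.STOPGAIN)
        b = _call(make_record, gene="TTC26",
                  consequence=Consequence.CANONICAL_SPLICE)
        assert dedupe_per_gene([a, b]) == [a, b]

    def test_tie_broken_by_position(self, make_record):
        hi = _call(make_record, consequence=Consequence.MISSENSE, mpc=2.5,
                   pos=500)
        lo = _call(make_record, consequence=Consequence.MISSENSE, mpc=2.4,
                   pos=100)
        assert dedupe_per_gene([hi, lo]) == [lo]

    def test_different_families_independent(self, make_record):
        a = _call(make_record, family_id="A")
        b = _call(make_record, family_id="B")
        assert len(dedupe_per_gene([a, b])) == 2


class TestTrioQc:
    @pytest.mark.parametrize("n,kept", [(21, 0), (20, 20), (0, 0)])
    def test_outlier_exclusion_boundary(self, make_record, n, kept):
        calls = [
            _call(make_record, gene=f"G{i}", pos=100 + i) for i in range(n)
        ]
        retained, excluded = trio_qc(calls)
        assert len(retained) == kept
        assert ("FAM1" in excluded) is (n > 20)


@st.composite
def evidence_triples(draw):
    dp = draw(st.integers(min_value=1, max_value=80))
    alt = draw(st.integers(min_value=0, max_value=dp))
    mq = draw(st.floats(min_value=0, max_value=70))
    return (dp, alt, mq)


class TestFilterMonotonicity:
    @settings(max_examples=200, derandomize=True)
    @given(
        child=evidence_triples(),
        mother=evidence_triples(),
        father=evidence_triples(),
        extra_depth=st.integers(min_value=0, max_value=15),
        window_shrink=st.floats(min_value=0, max_value=0.15),
    )
    def test_tightening_never_admits_more(
        self, child, mother, father, extra_depth, window_shrink
    ):
        """Raising min depth or narrowing the AF window can only remove
        calls, never add them."""
        record = VariantRecord(
            family_id="F",
            chrom="1",
            pos=100,
            ref_allele="A",
            alt_allele="T",
            gene="G",
            consequence=Consequence.STOPGAIN,
            gnomad_nonneuro_af=0.0,
            child_sex=Sex.FEMALE,
            child=_mk(child), mother=_mk(mother), father=_mk(father),
        )
        loose = FilterThresholds()
        tight = dataclasses.replace(
            loose,
            min_depth=loose.min_depth + extra_depth,
            child_af_min=loose.child_af_min + window_shrink,
            child_af_max=loose.child_af_max - window_shrink,
            parent_af_max=loose.parent_af_max / 2,
        )
        passed_tight, _ = passes_denovo_filters(record, tight)
        passed_loose, _ = passes_denovo_filters(record, loose)
        assert not (passed_tight and not passed_loose)


def _mk(t):
    from trioburden.records import MemberEvidence

    return MemberEvidence(dp=t[0], alt_dp=t[1], mq=t[2])


class TestSyntheticCohortCalls:
    def test_partition_and_truth_labels(self):
        """Damage classes partition emitted calls; with default noise, false
        calls can only come from simulated parental dropout, and
        sensitivity stays high."""
        from trioburden.synthetic_cohort import (
            SimulationConfig,
            default_gene_table,
            simulate_trio_cohort,
        )

        cfg = SimulationConfig(
            n_case_trios=100,
            n_control_trios=100,
            gene_table=default_gene_table(n_genes=120, seed=1),
            seed=42,
        )
        cohort = simulate_trio_cohort(cfg)
        calls, _ = call_denovos(cohort.variants)
        assert calls, "expected some calls from 200 trios"
        # mutually exclusive and exhaustive classes
        assert all(c.damage_class in DamageClass for c in calls)

        truth = {
            (t.family_id, t.chrom, t.pos, t.alt): t.is_denovo
            for t in cohort.truth.itertuples()
        }
        labels = [
            truth[(c.family_id, c.record.chrom, c.record.pos,
                   c.record.alt_allele)]
            for c in calls
        ]
        true_denovos = int(cohort.truth.is_denovo.sum())
        sensitivity = sum(labels) / true_denovos
        specificity_complement = 1 - sum(labels) / len(labels)
        assert sensitivity > 0.5
        assert specificity_complement < 0.05
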