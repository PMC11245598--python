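import numpy as np
import pandas as pd
import pytest

from trioburden.gene_association import Category, TadaHyperparameters
from trioburden.io_formats import read_coverage_table, read_ped, read_trio_variants
from trioburden.synthetic_cohort import (
    SimulationConfig,
    default_gene_table,
    simulate_case_control_counts,
    simulate_denovo_gene_counts,
    simulate_trio_cohort,
    write_cohort,
)

HYPER = TadaHyperparameters()


def small_config(**kwargs):
    defaults = dict(
        n_case_trios=20,
        n_control_trios=20,
        gene_table=default_gene_table(n_genes=50, seed=1),
        seed=123,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestTrioCohort:
    def test_zero_rates_give_zero_denovos(self):
        table = default_gene_table(n_genes=10, seed=0)
        for col in ("mu_ptv", "mu_misd", "mu_mis_other", "mu_syn"):
            table[col] = 0.0
        cohort = simulate_trio_cohort(
            small_config(gene_table=table, inherited_rate=0.0)
        )
        assert cohort.variants == []
        assert len(cohort.truth) == 0

    def test_same_seed_identical_output(self):
        a = simulate_trio_cohort(small_config())
        b = simulate_trio_cohort(small_config())
        assert a.variants == b.variants
        assert a.pedigree == b.pedigree
        assert a.coverage == b.coverage
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = simulate_trio_cohort(small_config())
        b = simulate_trio_cohort(small_config(seed=124))
        assert a.variants != b.variants

    def test_poisson_mean_of_denovo_counts(self):
        """With total haploid rate 1.0 per trio the de novo count per child
        is Poisson with mean 2.0 (two haplotypes)."""
        table = default_gene_table(
            n_genes=100, seed=2, total_ptv=0.1, total_misd=0.1,
            total_mis_other=0.5, total_syn=0.3,
        )
        n = 1000
        cohort = simulate_trio_cohort(SimulationConfig(
            n_case_trios=n, n_control_trios=0, gene_table=table,
            inherited_rate=0.0, seed=7,
        ))
        counts = cohort.truth.groupby("family_id").size()
        mean = counts.reindex(
            [f"CASE{i + 1:05d}" for i in range(n)], fill_value=0
        ).mean()
        se = np.sqrt(2.0 / n)
        assert abs(mean - 2.0) < 3 * se

    def test_truth_conservation_and_child_support(self):
        cohort = simulate_trio_cohort(small_config())
        assert len(cohort.truth) == len(cohort.variants)
        truth_dn = cohort.truth[cohort.truth.is_denovo]
        keyed = {
            (r.family_id, r.chrom, r.pos, r.alt_allele): r
            for r in cohort.variants
        }
        for t in truth_dn.itertuples():
            record = keyed[(t.family_id, t.chrom, t.pos, t.alt)]
            assert record.child.alt_dp > 0

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(gene_table=default_gene_table(10, 0).iloc[:0])

    def test_written_cohort_reads_back(self, tmp_path):
        cohort = simulate_trio_cohort(small_config(
            n_case_trios=3, n_control_trios=2))
        write_cohort(cohort, tmp_path)
        ped = read_ped(tmp_path / "cohort.ped")
        assert len(ped) == 15
        coverage = read_coverage_table(tmp_path / "coverage.tsv")
        assert len(coverage) == 5
        total = 0
        for fam in sorted({e.family_id for e in ped}):
            sub = [e for e in ped if e.family_id == fam]
            records = read_trio_variants(tmp_path / "vcf" / f"{fam}.vcf", sub)
            for got in records:
                match = [
                    r for r in cohort.variants
                    if (r.family_id, r.chrom, r.pos, r.alt_allele)
                    == (got.family_id, got.chrom, got.pos, got.alt_allele)
                ]
                assert len(match) == 1
                orig = match[0]
                assert got.gene == orig.gene
                assert got.consequence == orig.consequence
                assert got.child.dp == orig.child.dp
                assert got.child.alt_dp == orig.child.alt_dp
                assert got.gnomad_nonneuro_af == pytest.approx(
                    orig.gnomad_nonneuro_af, abs=1e-6
                )
            total += len(records)
        assert total == len(cohort.variants)


class TestCaseControlCounts:
    TABLE = default_gene_table(n_genes=2000, seed=3)

    def test_null_ratio_centered_on_sample_sizes(self):
        df = simulate_case_control_counts(
            self.TABLE, n_cases=3000, n_controls=6000,
            hyperparams=HYPER, pi_sim=0.0, seed=11, baseline_scale=20.0,
        )
        assert not df.is_risk.any()
        ratio = df.x_ca_ptv.sum() / df.x_co_ptv.sum()
        # ratio of two Poisson totals (expected ~2400 and ~4800 events),
        # expectation n_cases/n_controls
        assert ratio == pytest.approx(0.5, rel=0.05)

    def test_degenerate_unit_effect_matches_null(self):
        from trioburden.gene_association import Category, GammaPrior

        flat = TadaHyperparameters(
            pi=0.5,
            priors={
                Category.DN_MISD: GammaPrior(1.0, 1e7),
                Category.DN_PTV: GammaPrior(1.0, 1e7),
                Category.CC_MISD: GammaPrior(1.0, 1e7),
                Category.CC_PTV: GammaPrior(1.0, 1e7),
            },
        )
        df = simulate_case_control_counts(
            self.TABLE, 3000, 6000, flat, pi_sim=0.5, seed=11,
            baseline_scale=20.0,
        )
        ratio = df.x_ca_ptv.sum() / df.x_co_ptv.sum()
        assert ratio == pytest.approx(0.5, rel=0.05)

    def test_risk_gene_enrichment_matches_analytic_expectation(self):
        """Mean case count in risk genes exceeds non-risk genes by a factor
        close to the prior-mean relative risk (counts are placed
        proportionally to mu, so compare per-gene rate-normalized means)."""
        df = simulate_case_control_counts(
            default_gene_table(n_genes=10_000, seed=4),
            n_cases=5000, n_controls=5000,
            hyperparams=TadaHyperparameters(
                pi=0.05,
            ),
            pi_sim=0.05, seed=21, baseline_scale=2.0,
        )
        table = default_gene_table(n_genes=10_000, seed=4)
        mu = table.mu_ptv.to_numpy()
        risk = df.is_risk.to_numpy()
        # expected count per gene under null is n_cases*scale*mu; relative
        # risk gamma has prior mean 1.78
        norm = df.x_ca_ptv.to_numpy() / (5000 * 2.0 * mu)
        observed = norm[risk].mean() / norm[~risk].mean()
        expected = HYPER.priors[Category.CC_PTV].mean
        assert observed == pytest.approx(expected, rel=0.15)

    def test_invalid_sample_sizes(self):
        with pytest.raises(ValueError):
            simulate_case_control_counts(
                self.TABLE, 0, 100, HYPER, 0.1, seed=0
            )


class TestDenovoGeneCounts:
    def test_risk_genes_enriched(self):
        table = default_gene_table(n_genes=3000, seed=5)
        risk = table.gene.iloc[:150].tolist()
        df = simulate_denovo_gene_counts(table, 3000, HYPER, risk, seed=9)
        assert df[df.is_risk].x_dn_ptv.sum() > 0
        mu = table.mu_ptv.to_numpy()
        norm = df.x_dn_ptv.to_numpy() / (2 * 3000 * mu)
        risk_mask = df.is_risk.to_numpy()
        assert norm[risk_mask].mean() > 5 * norm[~risk_mask].mean()
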