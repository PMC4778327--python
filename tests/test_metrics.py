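import numpy as np
import pandas as pd
import pytest

from dashkit import datasets
from dashkit.fixtures import make_enrichment_table, random_dna
from dashkit.metrics import (
    duplicate_fraction,
    enrichment_fit,
    flag_offtarget_genes,
    fold_change,
    fpkm,
    make_depletion_report,
    pct_reduction,
)


class TestFpkm:
    def test_arithmetic(self):
        assert fpkm(10, 1000, 10**6) == pytest.approx(10.0)
        assert fpkm(0, 500, 10**6) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            fpkm(1, 0, 10**6)
        with pytest.raises(ValueError):
            fpkm(1, 100, 0)

    def test_algebraic_inverse_recovers_counts(self, rng):
        for _ in range(20):
            counts = int(rng.integers(1, 10_000))
            length = int(rng.integers(200, 20_000))
            total = int(rng.integers(10**5, 10**7))
            value = fpkm(counts, length, total)
            assert value * length * total / 1e9 == pytest.approx(counts)

    def test_linearity(self):
        assert fpkm(20, 1000, 10**6) == 2 * fpkm(10, 1000, 10**6)
        assert fpkm(10, 2000, 10**6) == fpkm(10, 1000, 10**6) / 2


class TestFoldChangeAndReduction:
    def test_pathogen_gene_enrichment(self):
        """1.5% -> 15.4% pathogen reads is a 10.3x increase."""
        assert fold_change(1.5, 15.4) == pytest.approx(10.3, abs=0.1)

    def test_targeted_percentage_collapse(self):
        """61% -> 0.055% targeted reads is a 99.9% reduction."""
        assert pct_reduction(61, 0.055) == pytest.approx(99.9, abs=0.1)

    def test_identity_cases(self):
        assert fold_change(3.0, 3.0) == 1.0
        assert pct_reduction(5.0, 5.0) == 0.0
        assert pct_reduction(5.0, 0.0) == 100.0

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            fold_change(0, 1)
        with pytest.raises(ValueError):
            pct_reduction(0, 1)


class TestEnrichmentFit:
    def test_exact_doubling(self):
        x = np.array([1.0, 5.0, 20.0, 100.0])
        slope, r2 = enrichment_fit(x, 2 * x)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_identity_line(self):
        x = np.linspace(1, 50, 30)
        slope, _ = enrichment_fit(x, x)
        assert slope == pytest.approx(1.0)

    def test_nonpositive_pairs_ignored(self):
        slope, _ = enrichment_fit([1.0, 2.0, 0.0], [3.0, 6.0, 5.0])
        assert slope == pytest.approx(3.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            enrichment_fit([1.0], [2.0])

    def test_recovers_planted_enrichment(self):
        """Seeded 1000-gene synthetic table with a planted 2.38x
        enrichment: slope recovered within 5%."""
        table = make_enrichment_table(seed=20160304)
        slope, r2 = enrichment_fit(table["fpkm_untreated"], table["fpkm_dashed"])
        assert slope == pytest.approx(2.38, rel=0.05)
        assert r2 > 0.9


class TestDuplicateFraction:
    def test_identical_reads(self):
        assert duplicate_fraction(["ACGT"] * 10) == pytest.approx(0.9)

    def test_all_unique(self, rng):
        reads = [random_dna(rng, 50) for _ in range(100)]
        assert duplicate_fraction(reads) == 0.0

    def test_planted_duplicate_fraction(self, rng):
        """Library with exactly 27% planted duplicates."""
        uniques = [random_dna(rng, 60) for _ in range(730)]
        dups = [uniques[i % 100] for i in range(270)]
        reads = uniques + dups
        assert duplicate_fraction(reads) == pytest.approx(0.27)

    def test_prefix_comparison(self):
        reads = ["AAAACCCC", "AAAAGGGG"]
        assert duplicate_fraction(reads) == 0.0
        assert duplicate_fraction(reads, prefix_len=4) == pytest.approx(0.5)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            duplicate_fraction([])


def replicate_tables(rng, n_genes=300, reps=3, cv=0.1):
    base = rng.lognormal(4.0, 1.0, n_genes) + 20
    idx = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    control = pd.DataFrame(
        {f"c{r}": base * rng.normal(1, cv, n_genes) for r in range(reps)}, index=idx)
    treated = pd.DataFrame(
        {f"t{r}": base * rng.normal(1, cv, n_genes) for r in range(reps)}, index=idx)
    return control.clip(lower=0.01), treated.clip(lower=0.01)


class TestFlagOfftargetGenes:
    def test_single_depleted_gene_is_flagged(self, rng):
        control, treated = replicate_tables(rng)
        treated.loc["g0"] = control.loc["g0"].values / 100.0
        out = flag_offtarget_genes(control, treated, targeted=set())
        assert out.loc["g0", "flagged"]
        assert out["flagged"].sum() == 1

    def test_noisy_gene_excluded_regardless_of_change(self, rng):
        control, treated = replicate_tables(rng)
        # replicate SD = 0.6 x mean in the control condition
        control.loc["g1"] = [40.0, 100.0, 160.0]  # mean 100, sd 60
        treated.loc["g1"] = [0.5, 0.5, 0.5]
        out = flag_offtarget_genes(control, treated, targeted=set())
        assert out.loc["g1", "noisy"]
        assert not out.loc["g1", "flagged"]

    def test_targeted_genes_never_flagged(self, rng):
        control, treated = replicate_tables(rng)
        treated.loc["g2"] = control.loc["g2"].values / 1000.0
        out = flag_offtarget_genes(control, treated, targeted={"g2"})
        assert out.loc["g2", "targeted"]
        assert not out.loc["g2", "flagged"]
        assert np.isnan(out.loc["g2", "log2_fc"])

    def test_null_table_flags_expected_tail_mass(self):
        """Under a no-change null the 2-SD rule flags roughly the lower
        Gaussian tail (~2.3%), and never much more."""
        rng = np.random.default_rng(77)
        control, treated = replicate_tables(rng, n_genes=2000, cv=0.08)
        out = flag_offtarget_genes(control, treated, targeted=set())
        tested = out["log2_fc"].notna().sum()
        frac = out["flagged"].sum() / tested
        assert 0.0 <= frac <= 0.06
        assert frac == pytest.approx(0.023, abs=0.02)

    def test_replicate_requirement(self, rng):
        control, treated = replicate_tables(rng)
        with pytest.raises(ValueError):
            flag_offtarget_genes(control[["c0"]], treated, targeted=set())

    def test_low_confidence_annotation(self, rng):
        control, treated = replicate_tables(rng)
        control.loc["g3"] = [5.0, 5.2, 4.8]
        out = flag_offtarget_genes(control, treated, targeted=set())
        assert out.loc["g3", "low_confidence"]


class TestDepletionReport:
    def test_worked_clinical_example(self):
        """The bundled three-patient summary reproduces its printed
        aggregate statistics when run back through the ops."""
        csf = datasets.csf_depletion_summary()
        p2 = csf.loc[2]
        pre = p2["fpkm_12s_untreated"] + p2["fpkm_16s_untreated"]
        post = p2["fpkm_12s_dashed"] + p2["fpkm_16s_dashed"]
        assert pct_reduction(pre, post) == pytest.approx(81.4, abs=0.2)

    def test_report_assembly(self, rng):
        fpkm_un = pd.Series([1000.0, 500.0, 10.0, 20.0, 30.0],
                            index=pd.Index(list("abcde"), name="gene_id"))
        fpkm_da = pd.Series([10.0, 5.0, 20.0, 40.0, 60.0], index=fpkm_un.index)
        report = make_depletion_report(fpkm_un, fpkm_da, targeted={"a", "b"})
        agg = report.aggregates
        assert agg["targeted_pct_untreated"] == pytest.approx(100 * 1500 / 1560)
        assert agg["enrichment_slope"] == pytest.approx(2.0)
        assert report.per_gene.loc["a", "fold_change"] == pytest.approx(0.01)
        assert "pct_reduction" in report.summary()
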