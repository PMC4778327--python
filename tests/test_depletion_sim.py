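import itertools
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from dashkit.depletion_sim import (
    Fragment,
    allele_enrichment,
    ddpcr_concentration,
    ddpcr_mutant_fraction,
    deplete_library,
    fragment_is_cleavable,
    is_pam_ablating,
    simulate_droplets,
    solve_cleavage_efficiency,
)
from dashkit.fixtures import (
    KRAS_MUT_AMPLICON,
    KRAS_WT_AMPLICON,
    SyntheticDesign,
    kras_g12d_guide,
    make_library_and_panel,
)
from dashkit.guide_select import GuidePanel


@pytest.fixture(scope="module")
def kras_panel():
    return GuidePanel(sites=[kras_g12d_guide()], spacing_bp=50, slack=10, regions=[])


class TestDepleteLibrary:
    def test_forced_cleavage_and_pam_requirement(self, kras_panel):
        frags = [
            Fragment(id="wt", seq=KRAS_WT_AMPLICON, origin="wt"),
            Fragment(id="mut", seq=KRAS_MUT_AMPLICON, origin="mut"),
        ]
        out = deplete_library(frags, kras_panel, efficiency=1.0, seed=0)
        assert [f.id for f in out.survivors] == ["mut"]
        assert out.n_cut == 1

    def test_zero_efficiency_is_identity(self, kras_panel):
        frags = [Fragment(id=f"f{i}", seq=KRAS_WT_AMPLICON) for i in range(20)]
        out = deplete_library(frags, kras_panel, efficiency=0.0, seed=0)
        assert out.survivors == frags

    def test_conservation_and_determinism(self):
        frags, panel = make_library_and_panel(SyntheticDesign(seed=5, n_fragments=2000))
        a = deplete_library(frags, panel, efficiency=0.7, seed=9)
        b = deplete_library(frags, panel, efficiency=0.7, seed=9)
        assert a.n_input == a.n_cut + len(a.survivors)
        assert [f.id for f in a.survivors] == [f.id for f in b.survivors]
        c = deplete_library(frags, panel, efficiency=0.7, seed=10)
        assert [f.id for f in c.survivors] != [f.id for f in a.survivors]

    def test_survival_matches_closed_form(self):
        """Post-depletion targeted fraction agrees with
        f(1-e) / (f(1-e) + 1-f) within 3 binomial SE at n = 10^4."""
        design = SyntheticDesign(seed=17, n_fragments=10_000, abundant_fraction=0.61)
        frags, panel = make_library_and_panel(design)
        f = sum(fr.origin == "targeted" for fr in frags) / len(frags)
        e = 0.999
        out = deplete_library(frags, panel, efficiency=e, seed=4)
        post = sum(fr.origin == "targeted" for fr in out.survivors) / len(out.survivors)
        expected = f * (1 - e) / (f * (1 - e) + 1 - f)
        se = math.sqrt(expected * (1 - expected) / len(out.survivors))
        assert abs(post - expected) <= 3 * se

    def test_untargeted_fragments_mostly_survive(self):
        frags, panel = make_library_and_panel(SyntheticDesign(seed=23, n_fragments=3000))
        out = deplete_library(frags, panel, efficiency=1.0, seed=0)
        # background genes share no 23-mers with the panel
        assert out.origin_survival["untargeted"] == 1.0
        assert out.origin_survival["targeted"] < 0.35

    def test_cleavability_requires_pam(self, kras_panel):
        protos = kras_panel.protospacers()
        assert fragment_is_cleavable(KRAS_WT_AMPLICON, protos)
        assert not fragment_is_cleavable(KRAS_MUT_AMPLICON, protos)


class TestAlleleModel:
    def test_no_cleavage_is_identity(self):
        m = 0.25
        model = allele_enrichment(m, 0.0, 0.0)
        assert model.m_post == pytest.approx(m)
        assert model.fold == pytest.approx(1.0)

    def test_no_mutant_stays_zero(self):
        assert allele_enrichment(0.0, 0.9).m_post == 0.0

    def test_total_cleavage_errors(self):
        with pytest.raises(ValueError):
            allele_enrichment(0.5, 1.0, 1.0)

    def test_monotone_in_e_and_e_mut(self):
        """Enrichment grows with wild-type cleavage and shrinks with
        residual mutant cleavage."""
        m = 0.01
        es = np.linspace(0, 0.99, 25)
        folds = [allele_enrichment(m, e).fold for e in es]
        assert all(a < b for a, b in zip(folds, folds[1:]))
        emuts = np.linspace(0, 0.9, 19)
        folds2 = [allele_enrichment(m, 0.95, em).fold for em in emuts]
        assert all(a > b for a, b in zip(folds2, folds2[1:]))

    def test_solver_matches_root_finding_oracle(self):
        """Closed-form inversion agrees with numerical root finding."""
        for m, m_post in [(0.001, 0.06), (0.01, 0.30), (0.1, 0.81)]:
            e = solve_cleavage_efficiency(m, m_post)
            e_oracle = brentq(
                lambda e_: allele_enrichment(m, e_).m_post - m_post, 0.0, 1.0 - 1e-12,
            )
            assert e == pytest.approx(e_oracle, abs=1e-9)
            assert allele_enrichment(m, e).m_post == pytest.approx(m_post)

    def test_low_frequency_mixture_reaches_60_fold(self):
        """e inverted at a 0.1% -> 6% observation gives ~60x enrichment and
        e ~ 0.984."""
        e = solve_cleavage_efficiency(0.001, 0.06)
        assert e == pytest.approx(0.984, abs=0.001)
        assert allele_enrichment(0.001, e).fold == pytest.approx(60, rel=0.01)


class TestIsPamAblating:
    def test_g12d_like_change_ablates(self):
        ablating, lost = is_pam_ablating("GGT", "GAT", "T", "G")
        assert ablating and lost

    def test_synonymous_glycine_keeps_pam(self):
        ablating, _ = is_pam_ablating("GGT", "GGC", "T", "G")
        assert not ablating

    def test_proline_minus_strand_pam(self):
        ablating, lost = is_pam_ablating("CCA", "CTA", "T", "T")
        assert ablating
        assert all(strand == "-" for strand, _ in lost)

    def test_exhaustive_codon_snv_table_matches_brute_force(self):
        """All 64 codons x 9 SNVs, fixed neutral flanks: ablation iff a
        codon-overlapping GG (or CC) present in ref is destroyed in alt."""
        bases = "ACGT"
        flank5, flank3 = "T", "A"  # no cross-boundary GG/CC possible

        def oracle(ref, alt):
            # independent enumeration on explicit double-stranded context
            def pams(codon):
                ctx = flank5 + codon + flank3
                out = set()
                for p in range(3):
                    if ctx[p + 1:p + 3] == "GG":
                        out.add(("+", p, p + 1, p + 2))
                    if ctx[p:p + 2] == "CC":
                        out.add(("-", p, p, p + 1))
                return out

            lost = pams(ref) - pams(alt)
            return any({g1, g2} & {1, 2, 3} for _, _, g1, g2 in lost)

        for codon in ("".join(c) for c in itertools.product(bases, repeat=3)):
            for pos in range(3):
                for b in bases:
                    if b == codon[pos]:
                        continue
                    alt = codon[:pos] + b + codon[pos + 1:]
                    got, _ = is_pam_ablating(codon, alt, flank5, flank3)
                    assert got == oracle(codon, alt), (codon, alt)

    def test_glycine_codons_always_targetable(self):
        """Any non-synonymous hit to the GG of a glycine codon ablates."""
        for third in "ACGT":
            codon = "GG" + third
            for pos in (0, 1):
                for b in "ACT":
                    alt = codon[:pos] + b + codon[pos + 1:]
                    assert is_pam_ablating(codon, alt, "T", "A")[0], (codon, alt)


class TestDdpcr:
    def test_no_positive_droplets(self):
        assert ddpcr_concentration(0, 10_000) == 0.0

    def test_half_positive_is_ln2(self):
        assert ddpcr_concentration(5000, 10_000) == pytest.approx(math.log(2))

    def test_saturation_errors(self):
        with pytest.raises(ValueError):
            ddpcr_concentration(10_000, 10_000)

    def test_simulated_droplets_recover_fraction(self):
        """Seeded droplet simulation recovers the true mutant fraction
        within 3 SE of the Poisson estimator."""
        lam_mut, lam_wt, n = 0.02, 0.38, 20_000
        pos_mut, pos_wt = simulate_droplets(lam_mut, lam_wt, n, seed=13)
        frac = ddpcr_mutant_fraction(pos_mut, pos_wt, n)
        true_frac = lam_mut / (lam_mut + lam_wt)
        # delta-method SE on the estimated fraction, dominated by lam_mut
        se_lam_mut = math.sqrt(math.expm1(lam_mut) / n)
        se_frac = se_lam_mut / (lam_mut + lam_wt)
        assert abs(frac - true_frac) <= 3 * se_frac
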