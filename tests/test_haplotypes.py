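"""EM haplotype estimation and LD against closed forms and a grid oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import candigene as cg
from candigene.haplotypes import EstimationError


def panel_from_genotypes(geno, phenotype=None, alleles=("A", "a")):
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    snps = [
        cg.SnpMeta(f"s{j}", "1", 100 + j, alleles[0].upper(), alleles[1].lower()[0])
        for j in range(m)
    ]
    # use distinct per-SNP letters so haplotype strings are readable
    snps = [
        cg.SnpMeta(f"s{j}", "1", 100 + j, "ACGT"[j % 4], "acgt"[j % 4])
        for j in range(m)
    ]
    if phenotype is None:
        phenotype = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
    return cg.GenotypePanel(
        snps=snps,
        samples=[f"i{i}" for i in range(n)],
        genotypes=geno,
        phenotype=np.asarray(phenotype, dtype=np.int8),
    )


class TestEm:
    def test_all_homozygous_equals_direct_counting(self):
        """With no heterozygotes, phase is known; EM = direct count."""
        geno = [[0, 0]] * 6 + [[2, 2]] * 3 + [[0, 2]] * 1
        panel = panel_from_genotypes(geno)
        em = cg.em_haplotype_freqs(panel, ("s0", "s1"))
        d = em.as_dict()
        assert d["AC"] == pytest.approx(12 / 20, abs=1e-6)
        assert d["ac"] == pytest.approx(6 / 20, abs=1e-6)
        assert d["Ac"] == pytest.approx(2 / 20, abs=1e-6)
        assert em.converged

    def test_double_heterozygotes_converge_to_symmetric_solution(self):
        panel = panel_from_genotypes([[1, 1]] * 10)
        em = cg.em_haplotype_freqs(panel, ("s0", "s1"))
        d = em.as_dict()
        assert d["AC"] == pytest.approx(d["ac"], abs=1e-6)
        assert d["Ac"] == pytest.approx(d["aC"], abs=1e-6)
        assert sum(d.values()) == pytest.approx(1.0, abs=1e-9)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 3, size=(40, 3))
        panel = panel_from_genotypes(geno)
        em = cg.em_haplotype_freqs(panel, ("s0", "s1", "s2"))
        trace = np.array(em.loglik_trace)
        assert (np.diff(trace) >= -1e-9).all()

    def test_missing_genotypes_are_summed_over(self):
        """Individuals with <=2 missing block SNPs still contribute."""
        geno = [[0, 0], [0, cg.MISSING], [cg.MISSING, 0], [0, 0]]
        panel = panel_from_genotypes(geno)
        em = cg.em_haplotype_freqs(panel, ("s0", "s1"))
        assert em.n_individuals == 4
        assert em.as_dict()["AC"] == pytest.approx(1.0, abs=1e-6)

    def test_no_usable_individuals_is_an_error(self):
        geno = [[cg.MISSING, cg.MISSING]] * 4
        panel = panel_from_genotypes(geno)
        with pytest.raises(EstimationError):
            cg.em_haplotype_freqs(panel, ("s0", "s1"))

    def test_em_matches_grid_search_mle(self):
        """EM agrees with exhaustive ML over a 0.01-step frequency simplex.

        Two SNPs, small panels: the likelihood only depends on the four
        haplotype frequencies, so a dense grid is a complete independent
        oracle for the maximiser.
        """
        pairs = [(0, 0), (1, 1), (0, 1), (1, 0), (2, 2), (1, 1), (2, 1), (0, 0)]
        for n_rows in (5, 8):
            geno = np.array(pairs[:n_rows])
            panel = panel_from_genotypes(geno)
            em = cg.em_haplotype_freqs(panel, ("s0", "s1"))

            # grid over f = (AB, Ab, aB, ab), step 0.01
            step = 100
            best_ll, best_f = -np.inf, None
            pair_sets = []
            for g in geno:
                compat = []
                for h1 in range(4):
                    for h2 in range(h1, 4):
                        dos = [
                            ((h1 >> j) & 1) + ((h2 >> j) & 1) for j in range(2)
                        ]
                        if dos == list(g):
                            compat.append((h1, h2))
                pair_sets.append(compat)
            for i in range(step + 1):
                for j in range(step + 1 - i):
                    for k in range(step + 1 - i - j):
                        f = np.array([i, j, k, step - i - j - k]) / step
                        ll = 0.0
                        ok = True
                        for compat in pair_sets:
                            p = sum(
                                (2.0 if h1 != h2 else 1.0) * f[h1] * f[h2]
                                for h1, h2 in compat
                            )
                            if p <= 0:
                                ok = False
                                break
                            ll += np.log(p)
                        if ok and ll > best_ll:
                            best_ll, best_f = ll, f
            np.testing.assert_allclose(em.frequencies, best_f, atol=0.02)

    def test_recovery_from_generating_pool(self):
        """Estimated frequencies land within 0.02 of the generating pool."""
        block = cg.HaplotypeBlock(
            ("s1", "s2", "s3"),
            ("ACA", "ATT", "ACT", "ATA", "GTA", "GCT"),
            (0.587, 0.211, 0.121, 0.048, 0.018, 0.015),
        )
        conf = cg.SimulationConfig(blocks=[block], missing_rate=0.0, seed=9)
        panel = cg.simulate_genotypes(conf, n=1000)
        em = cg.em_haplotype_freqs(panel, ("s1", "s2", "s3"))
        d = em.as_dict()
        for hap, f in zip(block.haplotypes, block.frequencies):
            assert d.get(hap, 0.0) == pytest.approx(f, abs=0.02)


class TestHaplotypeAssociation:
    def test_identical_groups_give_null_tests(self):
        geno = [[0, 0], [1, 1], [2, 2], [0, 1]]
        panel = panel_from_genotypes(geno * 2, phenotype=[1, 1, 1, 1, 0, 0, 0, 0])
        rows = cg.haplotype_association(panel, ("s0", "s1"))
        for r in rows:
            assert r.chi2 == pytest.approx(0.0, abs=1e-9)
            assert r.p == pytest.approx(1.0, abs=1e-9)

    def test_rows_sorted_by_pooled_frequency(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(60, 2))
        panel = panel_from_genotypes(geno)
        rows = cg.haplotype_association(panel, ("s0", "s1"))
        freqs = [r.freq_pooled for r in rows]
        assert freqs == sorted(freqs, reverse=True)

    def test_case_enriched_haplotype_detected(self):
        """A haplotype at 0.30 in cases vs 0.15 in controls is significant."""
        case_block = cg.HaplotypeBlock(
            ("s1", "s2"), ("AC", "Ac", "aC", "ac"), (0.30, 0.35, 0.20, 0.15)
        )
        ctrl_block = cg.HaplotypeBlock(
            ("s1", "s2"), ("AC", "Ac", "aC", "ac"), (0.15, 0.42, 0.28, 0.15)
        )
        hits = 0
        for seed in range(5):
            cases = cg.simulate_genotypes(
                cg.SimulationConfig(blocks=[case_block], missing_rate=0, seed=seed),
                n=500,
            )
            ctrls = cg.simulate_genotypes(
                cg.SimulationConfig(blocks=[ctrl_block], missing_rate=0, seed=100 + seed),
                n=500,
            )
            panel = cg.GenotypePanel(
                snps=cases.snps,
                samples=[f"ca{i}" for i in range(500)] + [f"co{i}" for i in range(500)],
                genotypes=np.vstack([cases.genotypes, ctrls.genotypes]),
                phenotype=np.r_[np.ones(500), np.zeros(500)].astype(np.int8),
            )
            rows = {r.haplotype: r for r in cg.haplotype_association(panel, ("s1", "s2"))}
            if rows["AC"].p < 0.001:
                hits += 1
        assert hits >= 5 * 0.95 - 1  # >=95% nominal over 5 seeds -> allow one miss


class TestLd:
    def test_complete_ld(self):
        block = cg.HaplotypeBlock(("s1", "s2"), ("AC", "ac"), (0.5, 0.5))
        panel = cg.simulate_genotypes(
            cg.SimulationConfig(blocks=[block], missing_rate=0, seed=1), n=400
        )
        ld = cg.pairwise_ld(panel, "s1", "s2")
        assert ld.d_prime == pytest.approx(1.0, abs=1e-9)
        assert ld.r2 == pytest.approx(1.0, abs=1e-9)

    def test_equilibrium_pool_gives_zero_d(self):
        d, dp, r2 = cg.ld_from_haplotype_freqs(0.35, 0.5, 0.7)
        assert (d, dp, r2) == (0.0, 0.0, 0.0)

    def test_closed_form_hand_computation(self):
        """Pool with pA=pB=0.5 and p_AB=0.40: D=0.15, D'=0.6, r2=0.36."""
        d, dp, r2 = cg.ld_from_haplotype_freqs(0.40, 0.5, 0.5)
        assert d == pytest.approx(0.15)
        assert dp == pytest.approx(0.600)
        assert r2 == pytest.approx(0.36)

    def test_independent_blocks_have_near_zero_r2(self):
        blocks = [
            cg.HaplotypeBlock(("x",), ("A", "a"), (0.6, 0.4)),
            cg.HaplotypeBlock(("y",), ("C", "c"), (0.7, 0.3)),
        ]
        panel = cg.simulate_genotypes(
            cg.SimulationConfig(blocks=blocks, missing_rate=0, seed=2), n=5000
        )
        ld = cg.pairwise_ld(panel, "x", "y")
        # r2-hat ~ 1/n under independence; 3 SE on r with n chromosomes
        assert ld.r2 < 9 / 10000 * 5

    def test_monomorphic_pair_flagged_in_matrix(self):
        geno = [[0, 0], [0, 1], [0, 2], [0, 1]]
        panel = panel_from_genotypes(geno)
        results = cg.ld_matrix(panel, ("s0", "s1"))
        assert len(results) == 1 and not results[0].defined
        with pytest.raises(EstimationError):
            cg.pairwise_ld(panel, "s0", "s1")

    def test_matrix_is_symmetric_and_complete(self):
        rng = np.random.default_rng(8)
        geno = rng.integers(0, 3, size=(80, 3))
        panel = panel_from_genotypes(geno)
        results = cg.ld_matrix(panel)
        assert len(results) == 3  # C(3,2)
        a_b = cg.pairwise_ld(panel, "s0", "s1")
        b_a = cg.pairwise_ld(panel, "s1", "s0")
        assert a_b.d_prime == pytest.approx(b_a.d_prime, abs=1e-9)
        assert a_b.r2 == pytest.approx(b_a.r2, abs=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.tuples(*[st.floats(0.01, 1.0)] * 4).map(
            lambda t: tuple(x / sum(t) for x in t)
        )
    )
    def test_r2_never_exceeds_d_prime(self, pool):
        """0 <= r2 <= D' <= 1 for every valid two-locus pool."""
        p_ab, p_a_b, p_b_a, _ = pool
        p_a = p_ab + p_a_b
        p_b = p_ab + p_b_a
        if min(p_a, 1 - p_a, p_b, 1 - p_b) < 1e-6:
            return
        _, dp, r2 = cg.ld_from_haplotype_freqs(p_ab, p_a, p_b)
        assert 0.0 <= r2 <= dp + 1e-9 <= 1.0 + 1e-9
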