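"""Analytic F5 progeny variance: Haldane mapping, the two-locus selfing
recursion, kernels, and consistency with Monte-Carlo meiosis."""

import numpy as np
import pandas as pd
import pytest

from crossplan.data_model import EffectVector, GeneticMap, GenotypeMatrix
from crossplan.progeny_variance import (
    all_pairs,
    batch_cross_variances,
    build_kernel,
    cross_variance,
    haldane_r,
    ril_cov_factor,
)
from crossplan.simulate import ril_f5_batch


class TestHaldane:
    def test_zero_distance(self):
        assert haldane_r(0.0) == 0.0

    def test_approaches_half_from_below(self):
        assert 0.49999 < haldane_r(10.0) < 0.5

    def test_closed_form_value(self):
        assert haldane_r(0.1) == pytest.approx(0.0906346, abs=1e-6)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_r(-0.1)


class TestRilCovFactor:
    def test_perfect_linkage_finite_selfing(self):
        """At r = 0 loci cosegregate; F5 residual heterozygosity leaves a
        dose variance of 15/16."""
        assert ril_cov_factor(0.0, 4) == pytest.approx(15 / 16, abs=1e-9)

    def test_perfect_linkage_complete_inbreeding(self):
        assert ril_cov_factor(0.0, None) == 1.0

    def test_unlinked_loci_have_zero_covariance(self):
        assert ril_cov_factor(0.5, 4) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("r", [0.05, 0.1, 0.25, 0.4])
    def test_haldane_waddington_limit(self, r):
        """Many selfing generations approach (1-2r)/(1+2r)."""
        expected = (1 - 2 * r) / (1 + 2 * r)
        assert ril_cov_factor(r, 50) == pytest.approx(expected, abs=1e-6)

    def test_non_increasing_in_r(self):
        r = np.linspace(0, 0.5, 21)
        c = ril_cov_factor(r, 4)
        assert np.all(np.diff(c) <= 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ril_cov_factor(0.6, 4)

    def test_matches_monte_carlo_dose_covariance(self, two_locus_map):
        """C(r(0.2 M), 4 selfings) against the empirical dose covariance of
        simulated F5 RILs (coupling-phase parents)."""
        n = 120_000
        prog = ril_f5_batch(
            np.array([2, 2], np.int8), np.array([0, 0], np.int8),
            n, two_locus_map, seed=21,
        ).astype(float)
        emp = np.cov(prog[:, 0], prog[:, 1])[0, 1]
        expected = ril_cov_factor(haldane_r(0.2), 4)
        # bootstrap-free SE: var of the product term dominates; be generous
        prod = (prog[:, 0] - prog[:, 0].mean()) * (prog[:, 1] - prog[:, 1].mean())
        se = prod.std(ddof=1) / np.sqrt(n)
        assert abs(emp - expected) < 3 * se


def _chromosome_map(n, length=1.2, chrom="chr1", seed=0):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.uniform(0, length, n))
    return GeneticMap(pd.DataFrame({
        "chrom": [chrom] * n,
        "locus_id": [f"{chrom}_l{i}" for i in range(n)],
        "pos_morgans": pos,
    }))


class TestKernel:
    def test_zero_effects_zero_kernel(self):
        gmap = _chromosome_map(10)
        eff = EffectVector(gmap.locus_ids, np.zeros(10))
        kern = build_kernel(eff, gmap)
        assert np.allclose(kern.blocks["chr1"][1], 0.0)

    def test_diagonal_is_beta_squared_times_c0(self):
        gmap = _chromosome_map(10, seed=1)
        beta = np.random.default_rng(2).standard_normal(10)
        eff = EffectVector(gmap.locus_ids, beta)
        kern = build_kernel(eff, gmap)
        np.testing.assert_allclose(
            np.diag(kern.blocks["chr1"][1]), beta**2 * (15 / 16), atol=1e-12
        )
        kern_inf = build_kernel(eff, gmap, mode="f_inf")
        np.testing.assert_allclose(
            np.diag(kern_inf.blocks["chr1"][1]), beta**2, atol=1e-12
        )

    def test_matches_entrywise_loop(self):
        gmap = _chromosome_map(30, seed=3)
        rng = np.random.default_rng(4)
        beta = rng.standard_normal(30)
        eff = EffectVector(gmap.locus_ids, beta)
        kern = build_kernel(eff, gmap)
        K = kern.blocks["chr1"][1]
        pos = gmap.table["pos_morgans"].to_numpy()
        for k in range(0, 30, 7):
            for l in range(0, 30, 5):
                r = haldane_r(abs(pos[k] - pos[l]))
                assert K[k, l] == pytest.approx(
                    beta[k] * beta[l] * ril_cov_factor(r, 4), rel=1e-9
                )


class TestCrossVariance:
    def test_identical_parents_zero_variance(self, small_panel):
        eff = small_panel["effects"]
        kern = build_kernel(eff, small_panel["map"])
        sub = small_panel["founders"].subset_loci(eff.locus_ids)
        s2, s = cross_variance(sub.doses[0], sub.doses[0], kern)
        assert s2 == 0.0 and s == 0.0

    def test_single_segregating_locus_full_inbreeding(self):
        """One differing locus with beta = 2: progeny TBV in {0, 4}
        equiprobable at complete inbreeding, so sigma2 = 4."""
        gmap = _chromosome_map(1)
        eff = EffectVector(gmap.locus_ids, [2.0])
        kern = build_kernel(eff, gmap, mode="f_inf")
        s2, _ = cross_variance(np.array([2]), np.array([0]), kern)
        assert s2 == pytest.approx(4.0)

    def test_two_coupled_loci_full_inbreeding(self):
        """Two perfectly linked coupling-phase loci with beta = (1, 1)
        cosegregate: TBV in {0, 4} equiprobable, sigma2 = 4."""
        gmap = GeneticMap(pd.DataFrame({
            "chrom": ["1", "1"], "locus_id": ["a", "b"], "pos_morgans": [0.3, 0.3],
        }))
        eff = EffectVector(["a", "b"], [1.0, 1.0])
        kern = build_kernel(eff, gmap, mode="f_inf")
        s2, _ = cross_variance(np.array([2, 2]), np.array([0, 0]), kern)
        assert s2 == pytest.approx(4.0)

    def test_symmetric_in_parent_order(self, small_panel):
        eff = small_panel["effects"]
        kern = build_kernel(eff, small_panel["map"])
        sub = small_panel["founders"].subset_loci(eff.locus_ids)
        a, b = sub.doses[3], sub.doses[7]
        assert cross_variance(a, b, kern)[0] == pytest.approx(
            cross_variance(b, a, kern)[0]
        )

    def test_coupling_variance_decreases_with_recombination(self):
        """All-coupling parents: shrinking the map (less recombination)
        never decreases sigma2."""
        rng = np.random.default_rng(8)
        beta = np.abs(rng.standard_normal(12))
        prev = None
        for scale in (1.0, 0.5, 0.1):
            gmap = _chromosome_map(12, length=1.2 * scale, seed=9)
            eff = EffectVector(gmap.locus_ids, beta)
            kern = build_kernel(eff, gmap)
            s2, _ = cross_variance(np.full(12, 2), np.zeros(12, int), kern)
            if prev is not None:
                assert s2 >= prev - 1e-9
            prev = s2

    def test_heterozygous_parent_rejected(self, small_panel):
        eff = small_panel["effects"]
        kern = build_kernel(eff, small_panel["map"])
        n = len(eff.locus_ids)
        with pytest.raises(ValueError, match="inbred"):
            cross_variance(np.ones(n, int), np.zeros(n, int), kern)

    def test_matches_monte_carlo_meiosis(self, small_panel):
        """Analytic sigma2 within 3 SE of the empirical TBV variance of
        simulated F5 progeny (the central cross-module consistency check)."""
        founders = small_panel["founders"]
        gmap = small_panel["map"]
        eff = small_panel["effects"]
        kern = build_kernel(eff, gmap)
        qtl_cols = [founders.locus_ids.index(l) for l in eff.locus_ids]
        sub = founders.subset_loci(eff.locus_ids)
        n = 30_000
        for i, j in [(0, 1), (10, 41)]:
            s2, _ = cross_variance(sub.doses[i], sub.doses[j], kern)
            prog = ril_f5_batch(founders.doses[i], founders.doses[j], n, gmap,
                                seed=100 + i)
            tbv = prog[:, qtl_cols] @ eff.values
            emp = tbv.var(ddof=1)
            centered = (tbv - tbv.mean()) ** 2
            se = centered.std(ddof=1) / np.sqrt(n)
            assert abs(emp - s2) < 3 * se


class TestBatch:
    def test_single_pair_equals_cross_variance(self, small_panel):
        eff = small_panel["effects"]
        kern = build_kernel(eff, small_panel["map"])
        f = small_panel["founders"]
        sub = f.subset_loci(eff.locus_ids)
        table = batch_cross_variances(f, kern, [(f.ids[2], f.ids[5])])
        s2, _ = cross_variance(sub.doses[2], sub.doses[5], kern)
        assert table["sigma2"].iloc[0] == pytest.approx(s2, abs=1e-9)

    def test_hundred_pairs_match_singles(self, small_panel):
        eff = small_panel["effects"]
        kern = build_kernel(eff, small_panel["map"])
        f = small_panel["founders"]
        sub = f.subset_loci(eff.locus_ids)
        pairs = all_pairs(f.ids)[:100]
        table = batch_cross_variances(f, kern, pairs)
        singles = np.array([
            cross_variance(sub.row(a), sub.row(b), kern)[0] for a, b in pairs
        ])
        assert np.max(np.abs(table["sigma2"].to_numpy() - singles)) < 1e-9

    def test_additive_over_chromosomes_without_transchrom_term(self, small_panel):
        eff = small_panel["effects"]
        gmap = small_panel["map"]
        f = small_panel["founders"]
        kern = build_kernel(eff, gmap)
        sub = f.subset_loci(eff.locus_ids)
        d = sub.doses[0], sub.doses[9]
        total, _ = cross_variance(*d, kern, ignore_transchrom=True)
        per_chrom = 0.0
        for chrom, (idx, K) in kern.blocks.items():
            dc = (d[0][idx] - d[1][idx]) / 2.0
            per_chrom += dc @ K @ dc
        assert total == pytest.approx(per_chrom, rel=1e-12)

    def test_unknown_individual_rejected(self, small_panel):
        eff = small_panel["effects"]
        kern = build_kernel(eff, small_panel["map"])
        with pytest.raises(KeyError, match="nobody"):
            batch_cross_variances(small_panel["founders"], kern, [("nobody", "L0001")])

    def test_pair_enumeration_count_835(self):
        assert len(all_pairs([f"x{i}" for i in range(835)])) == 348_195
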