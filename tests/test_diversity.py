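"""Heterozygosities, F_IS permutation test, Weir-Cockerham theta, nested AMOVA."""

import numpy as np
import pytest

from popgenkit import (
    Hierarchy,
    SimParams,
    fis_test,
    global_fst,
    heterozygosities,
    nested_amova,
    pairwise_fst,
    simulate_dataset,
)
from popgenkit.diversity import weir_cockerham_components

from conftest import make_table


def wc_theta_bruteforce(pops):
    """Independent scalar evaluation of the 1984 single-locus a, b, c.

    ``pops`` is a list of genotype lists (dosages, no missing).  Written
    longhand from the printed component formulas, it is the oracle the
    vectorized implementation is checked against.
    """
    r = len(pops)
    n = [len(p) for p in pops]
    p_hat = [sum(g) / (2 * len(g)) for g in pops]
    h_hat = [sum(1 for g in pop if g == 1) / len(pop) for pop in pops]
    nbar = sum(n) / r
    nc = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p_hat)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_hat)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h_hat)) / (r * nbar)
    a = (
        nbar
        / nc
        * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    )
    b = (
        nbar
        / (nbar - 1)
        * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    )
    c = hbar / 2
    return a, b, c


class TestHeterozygosity:
    def test_observed_fraction(self):
        t = make_table([[0, 1, 2]])
        div = heterozygosities(t, {"g": ["s1", "s2", "s3"]})
        assert div.per_group.loc["g", "h_obs"] == pytest.approx(1 / 3)

    def test_expected_with_small_sample_correction(self):
        # p = 0.5, n = 3 diploids: H_E = (6/5) * 0.5 = 0.6
        t = make_table([[0, 1, 2]])
        div = heterozygosities(t, {"g": ["s1", "s2", "s3"]})
        assert div.per_group.loc["g", "h_exp"] == pytest.approx(0.6)
        un = heterozygosities(t, {"g": ["s1", "s2", "s3"]}, corrected=False)
        assert un.per_group.loc["g", "h_exp"] == pytest.approx(0.5)

    def test_monomorphic_locus_zero(self):
        t = make_table([[0, 0, 0]])
        div = heterozygosities(t, {"g": ["s1", "s2", "s3"]})
        assert div.per_group.loc["g", "h_obs"] == 0
        assert div.per_group.loc["g", "h_exp"] == 0

    def test_group_relabeling_invariance(self, study_dataset):
        table, frame, _ = study_dataset
        sites = frame.sites()
        a = heterozygosities(table, sites)
        renamed = {f"x_{k}": v for k, v in sites.items()}
        b = heterozygosities(table, renamed)
        np.testing.assert_allclose(
            a.per_group[["h_obs", "h_exp"]].to_numpy(),
            b.per_group[["h_obs", "h_exp"]].to_numpy(),
        )

    def test_he_exceeds_ho_under_inbreeding(self, study_dataset):
        table, frame, _ = study_dataset  # simulated with F_IS = 0.12
        div = heterozygosities(table, frame.sites())
        assert div.overall_h_exp > div.overall_h_obs


class TestFisTest:
    def test_all_heterozygous_flagged(self):
        t = make_table([[1] * 20])
        res = fis_test(t, {"g": [f"s{i + 1}" for i in range(20)]}, n_perm=500, seed=0)
        assert res.fis.iloc[0] < 0
        assert res.negative_flag.iloc[0]

    def test_all_homozygous_polymorphic_not_flagged(self):
        t = make_table([[0] * 5 + [2] * 5])
        res = fis_test(t, {"g": [f"s{i + 1}" for i in range(10)]}, n_perm=500, seed=0)
        assert res.fis.iloc[0] == pytest.approx(1.0)
        assert not res.negative_flag.iloc[0]

    def test_null_pvalues_superuniform(self):
        # HWE genotypes: flagged fraction stays near alpha and p-values
        # are (super-)uniform
        rng = np.random.default_rng(5)
        p = rng.uniform(0.2, 0.8, 1000)
        u = rng.random((1000, 50, 2))
        geno = ((u[..., 0] < p[:, None]).astype(int) + (u[..., 1] < p[:, None])).astype(
            np.int8
        )
        t = make_table(geno)
        res = fis_test(t, {"g": t.sample_ids}, n_perm=300, seed=1)
        frac = res.negative_flag.mean()
        assert frac <= 0.075
        assert res.p_negative.mean() > 0.4

    def test_permutation_matches_bruteforce_at_tiny_n(self):
        # one group of 4 individuals, 1 het among A=3 alt alleles: compare
        # the sampled null of heterozygote counts with exhaustive pairing
        from itertools import permutations

        genotypes = [2, 1, 0, 0]  # A = 3 alt alleles among 8 slots
        t = make_table([genotypes])
        res = fis_test(t, {"g": t.sample_ids}, n_perm=5000, seed=3)
        alleles = [1, 1, 1, 0, 0, 0, 0, 0]
        hets = []
        for perm in set(permutations(alleles)):
            h = sum(1 for i in range(4) if perm[2 * i] != perm[2 * i + 1])
            hets.append(h)
        hets = np.array(hets)
        # observed het count = 1; exact p(het >= 1) under pairing null
        p_exact = (hets >= 1).mean()
        assert res.p_negative.iloc[0] == pytest.approx(p_exact, abs=0.03)


class TestWeirCockerham:
    def test_fixed_difference_theta_one(self):
        t = make_table([[0, 0, 2, 2]])
        theta = pairwise_fst(
            t, {"p1": ["s1", "s2"], "p2": ["s3", "s4"]}
        ).theta
        assert theta.loc["p1", "p2"] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "pops",
        [
            [[0, 1], [1, 2]],
            [[0, 0, 1], [2, 1]],
            [[1, 1], [1, 1]],
            [[0, 2, 1, 1], [2, 2, 0], [1, 0]],
        ],
    )
    def test_matches_bruteforce_components(self, pops):
        genotypes = [g for pop in pops for g in pop]
        t = make_table([genotypes])
        start = 0
        grouping = {}
        for i, pop in enumerate(pops):
            grouping[f"p{i}"] = t.sample_ids[start : start + len(pop)]
            start += len(pop)
        a, b, c = wc_theta_bruteforce(pops)
        if len(pops) == 2:
            theta = pairwise_fst(t, grouping).theta.iloc[0, 1]
        else:
            theta = global_fst(t, grouping)
        expected = a / (a + b + c) if (a + b + c) != 0 else np.nan
        if np.isnan(expected):
            assert np.isnan(theta)
        else:
            assert theta == pytest.approx(expected, rel=1e-12)

    def test_panmictic_theta_near_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 1000)
        geno = (
            (rng.random((1000, 60)) < p[:, None]).astype(int)
            + (rng.random((1000, 60)) < p[:, None])
        ).astype(np.int8)
        t = make_table(geno)
        theta = pairwise_fst(
            t, {"a": t.sample_ids[:30], "b": t.sample_ids[30:]}
        ).theta.iloc[0, 1]
        assert abs(theta) < 0.01

    def test_symmetry_and_zero_diagonal(self, study_dataset):
        table, frame, _ = study_dataset
        m = pairwise_fst(table, frame.clusters()).theta.to_numpy()
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 0)


class TestNestedAmova:
    def test_fixed_cluster_difference(self):
        # two clusters fixed for alternative alleles, monomorphic within
        geno = [[0] * 8 + [2] * 8] * 5
        t = make_table(np.array(geno, dtype=np.int8))
        h = Hierarchy(
            cluster_sites={"c1": ["p1", "p2"], "c2": ["p3", "p4"]},
            site_samples={
                "p1": t.sample_ids[:4],
                "p2": t.sample_ids[4:8],
                "p3": t.sample_ids[8:12],
                "p4": t.sample_ids[12:],
            },
        )
        res = nested_amova(t, h)
        assert res.f_stats["F_CT"] == pytest.approx(1.0, abs=1e-10)
        assert res.percent["within_individual"] == pytest.approx(0.0, abs=1e-10)

    def test_panmictic_all_indices_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.2, 0.8, 1500)
        geno = (
            (rng.random((1500, 80)) < p[:, None]).astype(int)
            + (rng.random((1500, 80)) < p[:, None])
        ).astype(np.int8)
        t = make_table(geno)
        sites = {f"p{i}": t.sample_ids[10 * i : 10 * (i + 1)] for i in range(8)}
        h = Hierarchy(
            cluster_sites={"c1": ["p0", "p1", "p2", "p3"], "c2": ["p4", "p5", "p6", "p7"]},
            site_samples=sites,
        )
        res = nested_amova(t, h)
        for f in ("F_IS", "F_SC", "F_CT", "F_IT"):
            assert abs(res.f_stats[f]) < 0.02

    def test_percentages_sum_to_100(self, study_dataset):
        table, frame, _ = study_dataset
        res = nested_amova(table, frame.hierarchy())
        assert res.percent.sum() == pytest.approx(100.0, abs=1e-6)

    def test_f_equals_component_ratios(self, study_dataset):
        table, frame, _ = study_dataset
        res = nested_amova(table, frame.hierarchy())
        wi, ai, ap, ag = res.components
        tot = res.components.sum()
        assert res.f_stats["F_CT"] == pytest.approx(ag / tot)
        assert res.f_stats["F_SC"] == pytest.approx(ap / (tot - ag))
        assert res.f_stats["F_IS"] == pytest.approx(ai / (ai + wi))
        assert res.f_stats["F_IT"] == pytest.approx(1 - wi / tot)

    def test_two_group_consistency_with_pairwise_theta(self):
        """F_SC-level AMOVA on two populations in one cluster equals
        Weir-Cockerham theta: both are the same moment decomposition."""
        rng = np.random.default_rng(3)
        p1, p2 = 0.3, 0.7
        g1 = ((rng.random((200, 12)) < p1).astype(int) + (rng.random((200, 12)) < p1))
        g2 = ((rng.random((200, 12)) < p2).astype(int) + (rng.random((200, 12)) < p2))
        t = make_table(np.hstack([g1, g2]).astype(np.int8))
        grouping = {"a": t.sample_ids[:12], "b": t.sample_ids[12:]}
        theta = pairwise_fst(t, grouping).theta.iloc[0, 1]
        h = Hierarchy(
            cluster_sites={"c": ["a", "b"]},
            site_samples={"a": grouping["a"], "b": grouping["b"]},
        )
        res = nested_amova(t, h)
        assert res.f_stats["F_SC"] == pytest.approx(theta, abs=1e-8)

    def test_structured_fct_permutation_significant(self, study_dataset):
        table, frame, _ = study_dataset
        res = nested_amova(table.subset_loci(np.arange(200)), frame.hierarchy(),
                           n_perm=99, seed=0)
        assert res.p_values["F_CT"] <= 0.05
        assert res.p_values["F_IS"] <= 0.05

    def test_parameter_recovery_single_seed(self):
        params = SimParams(n_loci=2000, seed=11)
        table, frame, _ = simulate_dataset(params)
        res = nested_amova(table, frame.hierarchy())
        assert res.f_stats["F_CT"] == pytest.approx(0.17, abs=0.03)
        assert res.f_stats["F_SC"] == pytest.approx(0.05, abs=0.03)
        assert res.f_stats["F_IS"] == pytest.approx(0.12, abs=0.03)
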