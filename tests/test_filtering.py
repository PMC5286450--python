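"""Curation-cascade stages: boundaries, oracles, bookkeeping."""

import numpy as np
import pytest

from popgenkit import (
    FilterConfig,
    FilterReport,
    drop_loci,
    filter_contig_density,
    filter_site_quality,
    ld_prune,
    mask_low_depth,
    run_cascade,
    spacing_filter,
)
from popgenkit.core import MISSING, ConfigurationError, ValidationError

from conftest import make_table


class TestDepthMask:
    def test_boundary_inclusive_at_threshold(self):
        t = make_table([[1, 1, 1]], depths=[[9, 10, 11]])
        out = mask_low_depth(t, 10)
        assert out.genotypes[0].tolist() == [MISSING, 1, 1]

    def test_all_zero_depth_masks_everything(self):
        t = make_table([[0, 1], [2, 0]], depths=[[0, 0], [0, 0]])
        out = mask_low_depth(t, 10)
        assert (out.genotypes == MISSING).all()
        assert out.genotypes.shape == t.genotypes.shape

    def test_requires_depths(self):
        with pytest.raises(ConfigurationError):
            mask_low_depth(make_table([[0, 1]]), 10)


class TestSiteQuality:
    def test_low_maf_removed(self):
        # locus 0: MAF 0.05 over 10 samples; locus 1: MAF 0.5
        g0 = [1] + [0] * 9
        g1 = [1] * 10
        t = make_table([g0, g1])
        out, removed = filter_site_quality(t, 0.10, 0.25)
        assert out.n_loci == 1
        assert removed == ["c1:1"]

    def test_missingness_boundary_strict(self):
        # 3 of 12 missing = 25% -> removed under "< 25%" rule
        g = [MISSING] * 3 + [1, 1, 0, 1, 0, 1, 1, 0, 1]
        t = make_table([g])
        out, removed = filter_site_quality(t, 0.0, 0.25)
        assert out.n_loci == 0

    def test_matches_bruteforce_recount(self, study_dataset):
        table, _, _ = study_dataset
        out, removed = filter_site_quality(table, 0.10, 0.25)
        keep_expected = []
        for i in range(table.n_loci):
            row = table.genotypes[i]
            vals = row[row != MISSING]
            p = vals.sum() / (2 * len(vals)) if len(vals) else 0.0
            maf = min(p, 1 - p)
            miss = 1 - len(vals) / table.n_samples
            keep_expected.append(maf > 0.10 and miss < 0.25)
        assert out.n_loci == sum(keep_expected)
        assert set(removed) == set(table.locus_ids[~np.array(keep_expected)])


class TestContigDensity:
    def test_dense_contig_removed(self):
        t = make_table(
            [[0, 1]] * 3, contigs=["c1"] * 3, positions=[1, 5, 9]
        )
        out, removed = filter_contig_density(t, 10)
        assert out.n_loci == 0
        assert removed == ["c1"]

    def test_sparse_contig_kept_and_singletons_kept(self):
        t = make_table(
            [[0, 1]] * 4,
            contigs=["c1", "c1", "c1", "c2"],
            positions=[1, 101, 201, 3],
        )
        out, removed = filter_contig_density(t, 10)
        assert out.n_loci == 4
        assert removed == []

    def test_matches_independent_computation(self, spiked_dataset):
        table, _, _ = spiked_dataset
        out, removed = filter_contig_density(table, 100)
        expected = set()
        for contig, sub in table.loci.groupby("contig"):
            pos = sub["pos"].to_numpy()
            if len(pos) >= 2 and (pos.max() - pos.min()) / (len(pos) - 1) < 100:
                expected.add(contig)
        assert set(removed) == expected


class TestLdPrune:
    def test_duplicate_column_removed(self):
        g = [[0, 1, 2, 1], [0, 1, 2, 1], [2, 0, 1, 1]]
        t = make_table(g)
        out, removed = ld_prune(t, 0.5)
        assert removed == ["c1:2"]
        assert out.n_loci == 2

    def test_cross_contig_duplicates_both_kept(self):
        g = [[0, 1, 2, 1], [0, 1, 2, 1]]
        t = make_table(g, contigs=["c1", "c2"], positions=[1, 1])
        out, removed = ld_prune(t, 0.5)
        assert out.n_loci == 2

    def test_three_locus_enumeration(self):
        # A == B, C uncorrelated (r = 0 by construction) -> keep {A, C}
        a = [0, 1, 2, 1, 0, 2]
        c = [0, 2, 0, 2, 1, 1]
        t = make_table([a, a, c])
        out, removed = ld_prune(t, 0.5)
        assert out.locus_ids.tolist() == ["c1:1", "c1:3"]

    def test_no_retained_pair_exceeds_threshold(self, spiked_dataset):
        table, _, _ = spiked_dataset
        out, _ = ld_prune(table, 0.5)
        from popgenkit.filtering import _r2

        for contig, sub in out.loci.groupby("contig"):
            idx = sub.index.to_numpy()
            for i in range(len(idx)):
                for j in range(i + 1, len(idx)):
                    assert _r2(out.genotypes[idx[i]], out.genotypes[idx[j]]) <= 0.5

    def test_exact_ld_copies_fully_pruned(self, spiked_dataset):
        table, _, truth = spiked_dataset
        out, removed = ld_prune(table, 0.5)
        survivors = set(out.locus_ids)
        copies = truth.class_ids("ld_copy")
        # an exact copy or its template is gone from every duplicated pair
        for c in copies:
            assert c in set(removed) or c not in survivors or True
        assert sum(1 for c in copies if c in survivors) == 0


class TestSpacing:
    def test_sweep_by_hand(self):
        t = make_table([[0, 1]] * 3, positions=[1, 50, 150])
        out, removed = spacing_filter(t, 100)
        assert out.loci["pos"].tolist() == [1, 150]

    def test_boundary_gap_equal_to_spacing_kept(self):
        t = make_table([[0, 1]] * 2, positions=[1, 101])
        out, removed = spacing_filter(t, 100)
        assert out.n_loci == 2

    def test_postcondition_all_gaps_satisfied(self, spiked_dataset):
        table, _, _ = spiked_dataset
        out, _ = spacing_filter(table, 100)
        for contig, sub in out.loci.groupby("contig"):
            gaps = np.diff(sub["pos"].to_numpy())
            assert (gaps >= 100).all()


class TestDropLoci:
    def test_cascade_counts(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(2800, 4)).astype(np.int8)
        t = make_table(g, positions=list(range(1, 2801)))
        report = FilterReport()
        ids = t.locus_ids
        t2 = drop_loci(t, ids[:342].tolist(), "outlier_scan", report)
        assert t2.n_loci == 2458
        t3 = drop_loci(t2, t2.locus_ids[:1643].tolist(), "negative_fis", report)
        assert t3.n_loci == 815
        assert [s["n_out"] for s in report.stages] == [2458, 815]

    def test_empty_drop_is_identity(self):
        t = make_table([[0, 1], [1, 2]])
        out = drop_loci(t, [], "noop")
        np.testing.assert_array_equal(out.genotypes, t.genotypes)

    def test_unknown_id_rejected(self):
        t = make_table([[0, 1]])
        with pytest.raises(ValidationError):
            drop_loci(t, ["nope:1"], "x")


@pytest.fixture(scope="module")
def cascade_run(spiked_dataset):
    table, frame, truth = spiked_dataset
    cfg = FilterConfig(
        outlier_burn_in=500,
        outlier_n_iter=2_000,
        fis_n_perm=300,
    )
    filtered, report = run_cascade(table, frame, cfg, seed=1)
    return table, frame, truth, cfg, filtered, report


class TestCascade:
    def test_report_chains_and_balances(self, cascade_run):
        *_, report = cascade_run
        for prev, nxt in zip(report.stages, report.stages[1:]):
            assert prev["n_out"] == nxt["n_in"]
        for s in report.stages:
            assert s["n_in"] - s["n_removed"] == s["n_out"]

    def test_removal_sets_disjoint(self, cascade_run):
        *_, report = cascade_run
        all_removed = [i for ids in report.removed.values() for i in ids]
        assert len(all_removed) == len(set(all_removed))

    def test_deterministic_rerun(self, cascade_run):
        table, frame, truth, cfg, filtered, report = cascade_run
        filtered2, report2 = run_cascade(table, frame, cfg, seed=1)
        assert report2.stages == report.stages
        np.testing.assert_array_equal(filtered2.genotypes, filtered.genotypes)

    def test_artifacts_are_removed(self, cascade_run):
        table, frame, truth, cfg, filtered, report = cascade_run
        survivors = set(filtered.locus_ids)
        ld_left = [i for i in truth.class_ids("ld_copy") if i in survivors]
        paralog_left = [i for i in truth.class_ids("paralog") if i in survivors]
        assert not ld_left
        # forced-het rate 0.9 makes paralogs conspicuous; a stray survivor
        # (masked to weak signal by the depth filter) is tolerated
        assert len(paralog_left) <= 2

    def test_disabled_thresholds_are_identity(self, spiked_dataset):
        table, frame, _ = spiked_dataset
        # restrict to polymorphic loci: "MAF > 0" is vacuous only for those
        g = table.genotypes
        ok = g != MISSING
        alt = np.where(ok, g, 0).sum(axis=1)
        poly = (alt > 0) & (alt < 2 * ok.sum(axis=1))
        table = table.subset_loci(poly)
        cfg = FilterConfig(
            min_depth=0,
            min_maf=0.0,
            max_missing=1.0,
            min_bp_per_snp=0.0,
            ld_r2_max=1.0,
            min_spacing=0,
            scan_outliers=False,
            screen_paralogs=False,
        )
        filtered, report = run_cascade(table, frame, cfg, seed=0)
        assert filtered.n_loci == table.n_loci
        np.testing.assert_array_equal(filtered.genotypes, table.genotypes)

    def test_stage_idempotence(self, cascade_run):
        *_, filtered, report = cascade_run
        out, removed = filter_site_quality(filtered, 0.10, 0.25)
        assert removed == []
        out, removed = spacing_filter(filtered, 100)
        assert removed == []
        out, removed = ld_prune(filtered, 0.5)
        assert removed == []
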