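import itertools

import numpy as np
import pytest
from sklearn.pipeline import Pipeline

import prsrank as pr
from prsrank.errors import ValidationError
from prsrank.ld import _pairwise_r2

from .util import make_geno, make_table


def brute_force_min_cover(r2, threshold):
    """Smallest tag set such that every SNP reaches r² >= threshold with a tag."""
    p = r2.shape[0]
    adj = r2 >= threshold
    np.fill_diagonal(adj, True)
    for k in range(1, p + 1):
        for tags in itertools.combinations(range(p), k):
            if adj[:, list(tags)].any(axis=1).all():
                return k
    return p


class TestComputeR2:
    def test_identical_columns(self):
        g = make_geno(np.column_stack([[0, 1, 2, 2], [0, 1, 2, 2]]))
        ld = pr.compute_r2(g)["all"]
        assert ld.r2[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_alleles_are_one_signal(self):
        g = make_geno(np.column_stack([[0, 1, 2, 2], [2, 1, 0, 0]]))
        assert pr.compute_r2(g)["all"].r2[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # x=(0,1,2,1,0), y=(0,0,2,2,1): cov=2, Sxx=2.8, Syy=4 -> r2 = 4/11.2
        g = make_geno(np.column_stack([[0, 1, 2, 1, 0], [0, 0, 2, 2, 1]]))
        assert pr.compute_r2(g)["all"].r2[0, 1] == pytest.approx(4 / 11.2, abs=1e-12)

    def test_monomorphic_flagged_r2_zero(self):
        g = make_geno(np.column_stack([[1, 1, 1, 1], [0, 1, 2, 0]]))
        ld = pr.compute_r2(g)["all"]
        assert ld.monomorphic[0] and not ld.monomorphic[1]
        assert ld.r2[0, 1] == 0.0

    def test_chromosome_partition(self):
        table = make_table([0.1] * 4, chroms=["1", "1", "2", "2"])
        g = make_geno(np.random.default_rng(0).integers(0, 3, (30, 4)), snp_ids=table.snp_ids)
        per_chrom = pr.compute_r2(g, table)
        assert set(per_chrom) == {"1", "2"}
        assert all(len(m.snp_ids) == 2 for m in per_chrom.values())

    def test_pairwise_complete_matches_loop_oracle(self, rng):
        n, p = 40, 6
        d = rng.integers(0, 3, (n, p))
        miss = rng.random((n, p)) < 0.2
        got = _pairwise_r2(d, miss)
        for i in range(p):
            for j in range(i + 1, p):
                ok = ~miss[:, i] & ~miss[:, j]
                x, y = d[ok, i].astype(float), d[ok, j].astype(float)
                if ok.sum() < 2 or x.std() == 0 or y.std() == 0:
                    expected = 0.0
                else:
                    expected = np.corrcoef(x, y)[0, 1] ** 2
                assert got[i, j] == pytest.approx(expected, abs=1e-10)

    def test_symmetry_and_bounds(self, small_cohort):
        _, table, geno, _, _ = small_cohort
        for mat in pr.compute_r2(geno, table).values():
            np.testing.assert_allclose(mat.r2, mat.r2.T, atol=1e-12)
            assert mat.r2.min() >= 0 and mat.r2.max() <= 1
            np.testing.assert_allclose(np.diag(mat.r2), 1.0)


class TestGreedyTag:
    def test_no_ld_every_snp_is_its_own_tag(self):
        ld = pr.LDMatrix(["a", "b", "c"], np.eye(3))
        assert sorted(pr.greedy_tag(ld, 0.8).tag_ids) == ["a", "b", "c"]

    def test_single_block_single_tag(self):
        ld = pr.LDMatrix([f"s{i}" for i in range(5)], np.ones((5, 5)))
        ts = pr.greedy_tag(ld, 0.8)
        assert len(ts) == 1 and len(ts.cover_map) == 4

    def test_overlapping_blocks_match_brute_force(self, rng):
        for _ in range(20):
            d = rng.integers(0, 3, (25, 6))
            r2 = _pairwise_r2(d)
            ts = pr.greedy_tag(pr.LDMatrix([f"s{i}" for i in range(6)], r2), 0.8)
            assert len(ts) <= brute_force_min_cover(r2, 0.8) + 1

    def test_coverage_postcondition(self, medium_cohort):
        _, table, geno, _, _ = medium_cohort
        ld = pr.compute_r2(geno, table)
        ts = pr.greedy_tag(ld, 0.8)
        by_chrom = {s: m for m in ld.values() for s in m.snp_ids}
        for snp, tag in ts.cover_map.items():
            m = by_chrom[snp]
            i, j = m.snp_ids.index(snp), m.snp_ids.index(tag)
            assert m.r2[i, j] >= 0.8

    def test_threshold_monotonicity(self, medium_cohort):
        _, table, geno, _, _ = medium_cohort
        ld = pr.compute_r2(geno, table)
        counts = [len(pr.greedy_tag(ld, t)) for t in (0.9, 0.8, 0.5, 0.2)]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_tie_break(self):
        # two disjoint perfect pairs: the lower-position SNP of each pair wins
        r2 = np.eye(4)
        r2[0, 1] = r2[1, 0] = 1.0
        r2[2, 3] = r2[3, 2] = 1.0
        ld = pr.LDMatrix(["d", "c", "b", "a"], r2, pos=np.array([40, 30, 20, 10]))
        assert pr.greedy_tag(ld, 0.8).tag_ids == ["a", "c"]

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            pr.greedy_tag(pr.LDMatrix(["a"], np.eye(1)), 0.0)


class TestLDTagger:
    def test_block_recovery_on_calibrated_ld(self):
        cfg = pr.SynthConfig(
            n_individuals=800, n_snps=200, n_blocks=40, within_block_r2=0.98, seed=21
        )
        table, geno = pr.generate_panel(cfg)
        tagger = pr.LDTagger(r2_threshold=0.8, effect_table=table).fit(geno)
        assert len(tagger.tags_) == cfg.n_blocks
        assert tagger.support_.sum() == cfg.n_blocks

    def test_sklearn_api_and_pipeline(self, small_cohort):
        _, table, geno, _, _ = small_cohort
        tagger = pr.LDTagger(r2_threshold=0.8, effect_table=table)
        assert tagger.get_params()["r2_threshold"] == 0.8
        pipe = Pipeline(
            [("tag", tagger), ("score", pr.PolygenicScorer(table))]
        )
        scores = pipe.fit_transform(geno)
        assert scores.shape == (geno.n_individuals,)
        tagged = tagger.transform(geno)
        assert tagged.n_snps == len(tagger.tags_)

    def test_transform_on_plain_array(self):
        X = np.random.default_rng(1).integers(0, 3, (50, 8))
        tagger = pr.LDTagger(r2_threshold=0.8).fit(X)
        Xt = tagger.transform(X.astype(float))
        assert Xt.shape[1] == tagger.support_.sum()
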