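import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtcontinuity.exceptions import NoInformativeSitesError, PartitionError
from mtcontinuity.popgen import (
    DistanceMatrix,
    HaplogroupFreqTable,
    beta_hpd,
    fst_permutation_test,
    haplogroup_ci,
    haplotype_diversity,
    haplotype_sharing,
    kin_candidates,
    nmds,
    pairwise_distances,
    pca_haplogroups,
    phi_st,
    slatkin_linearize,
)

from conftest import aln_from_strings


def amova_phi_oracle(d, labels):
    """Brute-force two-level AMOVA from first principles (explicit loops)."""
    labels = list(labels)
    N = len(labels)
    names = sorted(set(labels))
    groups = [[i for i, l in enumerate(labels) if l == g] for g in names]
    ss_total = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            ss_total += d[i][j]
    ss_total /= N
    ss_within = 0.0
    for g in groups:
        s = 0.0
        for a in range(len(g)):
            for b in range(a + 1, len(g)):
                s += d[g[a]][g[b]]
        ss_within += s / len(g)
    ss_among = ss_total - ss_within
    df_among = len(groups) - 1
    df_within = N - len(groups)
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within else 0.0
    n_c = (N - sum(len(g) ** 2 for g in groups) / N) / df_among
    sigma_a = (ms_among - ms_within) / n_c
    if sigma_a + ms_within <= 0:
        return 0.0
    return sigma_a / (sigma_a + ms_within)


class TestPairwiseDistances:
    def test_identical_sequences_zero(self):
        d = pairwise_distances(aln_from_strings(["ACGT", "ACGT"]))
        assert d.d[0, 1] == 0

    def test_single_mismatch(self):
        d = pairwise_distances(aln_from_strings(["ACGT", "ACGA"]))
        assert d.d[0, 1] == 1

    def test_complete_deletion_drops_column_with_missing(self):
        aln = aln_from_strings(["ACNT", "ACGT", "TCGT"])
        d = pairwise_distances(aln, "complete_deletion")
        # column 3 removed; s1 vs s3 differ only at position 1
        assert d.d[0, 2] == 1
        assert d.d[0, 1] == 0
        assert d.d[1, 2] == 1

    def test_pairwise_deletion_keeps_per_pair_columns(self):
        aln = aln_from_strings(["ACNT", "ACGT", "TCGT"])
        d = pairwise_distances(aln, "pairwise_deletion")
        assert d.d[0, 1] == 0  # N column skipped for this pair only
        assert d.d[1, 2] == 1

    def test_all_columns_missing_rejected(self):
        aln = aln_from_strings(["NN", "AC"])
        with pytest.raises(NoInformativeSitesError):
            pairwise_distances(aln, "complete_deletion")


class TestPhiSt:
    def test_identical_composition_near_zero(self):
        # both groups hold the same two haplotypes: no among-group variance
        aln = aln_from_strings(["AAAA", "AATT", "AAAA", "AATT"])
        d = pairwise_distances(aln)
        phi = phi_st(d, [["s1", "s2"], ["s3", "s4"]])
        assert phi <= 0.0 + 1e-12

    def test_fully_differentiated_pair_is_one(self):
        aln = aln_from_strings(["AAAAA", "AAAAA", "TTTTA", "TTTTA"])
        d = pairwise_distances(aln)
        assert phi_st(d, [["s1", "s2"], ["s3", "s4"]]) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle_on_random_toys(self):
        rng = np.random.default_rng(5)
        for n in (4, 5, 6, 7, 8):
            seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(n)]
            aln = aln_from_strings(seqs)
            d = pairwise_distances(aln)
            for k in range(2, n - 1):
                for combo in itertools.combinations(range(n), k):
                    rest = [i for i in range(n) if i not in combo]
                    if len(rest) < 2:
                        continue
                    ids_a = [aln.sample_ids[i] for i in combo]
                    ids_b = [aln.sample_ids[i] for i in rest]
                    labels = ["A" if i in combo else "B" for i in range(n)]
                    assert phi_st(d, [ids_a, ids_b]) == pytest.approx(
                        amova_phi_oracle(d.d, labels), abs=1e-10
                    )

    def test_undersized_group_rejected(self):
        aln = aln_from_strings(["AAAA", "AATT", "TTTT"])
        d = pairwise_distances(aln)
        with pytest.raises(PartitionError):
            phi_st(d, [["s1"], ["s2", "s3"]])

    def test_overlapping_groups_rejected(self):
        aln = aln_from_strings(["AAAA", "AATT", "TTTT", "TTAA"])
        d = pairwise_distances(aln)
        with pytest.raises(PartitionError):
            phi_st(d, [["s1", "s2"], ["s2", "s3"]])


class TestSlatkin:
    def test_known_values(self):
        assert slatkin_linearize(0.0) == 0.0
        assert slatkin_linearize(0.5) == pytest.approx(1.0)
        assert slatkin_linearize(0.15) == pytest.approx(0.15 / 0.85)

    def test_negative_clamped_to_zero(self):
        assert slatkin_linearize(-0.03) == 0.0

    def test_at_or_above_one_capped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            v = slatkin_linearize(1.0)
        assert v == pytest.approx(0.999999 / (1 - 0.999999))

    def test_strictly_increasing_and_tangent_at_zero(self):
        xs = np.linspace(0, 0.99, 50)
        ys = [slatkin_linearize(x) for x in xs]
        assert all(b > a for a, b in zip(ys, ys[1:]))
        assert slatkin_linearize(1e-6) == pytest.approx(1e-6, rel=1e-4)
        assert all(y >= x for x, y in zip(xs, ys))


class TestPermutationTest:
    def test_maximally_differentiated_gives_minimal_p(self):
        aln = aln_from_strings(
            ["AAAAAAAA", "AAAAAAAA", "AAAAAAAT",
             "TTTTTTTT", "TTTTTTTA", "TTTTTTTT"]
        )
        d = pairwise_distances(aln)
        res = fst_permutation_test(
            d, [["s1", "s2", "s3"], ["s4", "s5", "s6"]], n_perm=999, seed=0
        )
        # only label-preserving (or swapped) permutations reach the observed
        assert res.p_value < 0.15
        assert res.fst > 0.9

    def test_zero_permutations_rejected(self):
        aln = aln_from_strings(["AAAA", "AATT", "TTTT", "TTAA"])
        d = pairwise_distances(aln)
        with pytest.raises(ValueError):
            fst_permutation_test(d, [["s1", "s2"], ["s3", "s4"]], n_perm=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(8)]
        aln = aln_from_strings(seqs)
        d = pairwise_distances(aln)
        part = [aln.sample_ids[:4], aln.sample_ids[4:]]
        a = fst_permutation_test(d, part, n_perm=300, seed=42)
        b = fst_permutation_test(d, part, n_perm=300, seed=42)
        assert a.p_value == b.p_value

    def test_null_p_values_uniform(self):
        """Exchangeable labels => permutation p-values are uniform (KS)."""
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(10)]
            aln = aln_from_strings(seqs)
            d = pairwise_distances(aln)
            res = fst_permutation_test(
                d, [aln.sample_ids[:5], aln.sample_ids[5:]], n_perm=199, seed=seed
            )
            ps.append(res.p_value)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 1e-3


class TestHaplotypeDiversity:
    def test_all_identical_zero(self):
        assert haplotype_diversity(aln_from_strings(["ACGT"] * 5)) == 0.0

    def test_all_distinct_one(self):
        aln = aln_from_strings(["AAAA", "AAAT", "AATT", "ATTT"])
        assert haplotype_diversity(aln) == pytest.approx(1.0)

    def test_hand_computed_211_classes(self):
        aln = aln_from_strings(["AAAA", "AAAA", "AATT", "TTTT"])
        assert haplotype_diversity(aln) == pytest.approx(
            (4 / 3) * (1 - (0.25 + 0.0625 + 0.0625))
        )

    def test_matches_exhaustive_draw_probability_small_n(self):
        # Hd must equal P(two draws without replacement differ), exactly
        rng = np.random.default_rng(9)
        for n in range(2, 7):
            for _ in range(5):
                seqs = ["".join(rng.choice(list("AC"), size=4)) for _ in range(n)]
                aln = aln_from_strings(seqs)
                diff = sum(
                    seqs[i] != seqs[j]
                    for i in range(n) for j in range(n) if i != j
                )
                assert haplotype_diversity(aln) == pytest.approx(
                    diff / (n * (n - 1))
                )

    def test_missing_columns_excluded_before_classing(self):
        # the N column would split the classes if it were kept
        aln = aln_from_strings(["ANAA", "ACAA", "TGAA"])
        assert haplotype_diversity(aln) == pytest.approx(
            (3 / 2) * (1 - ((2 / 3) ** 2 + (1 / 3) ** 2))
        )

    def test_fewer_than_two_rejected(self):
        with pytest.raises(PartitionError):
            haplotype_diversity(aln_from_strings(["ACGT"]))


class TestHaplotypeSharing:
    def test_no_shared_haplotypes(self):
        aln = aln_from_strings(["AAAA", "AATT", "TTTT", "TTAA"])
        res = haplotype_sharing(aln, ["s1", "s2"], ["s3", "s4"])
        assert res.shared_pairs == 0 and res.normalized == 0.0

    def test_nmax_for_41_samples(self):
        seqs = [f"{'A'*i}{'T'*(41-i)}" for i in range(41)]
        aln = aln_from_strings(seqs)
        res = haplotype_sharing(aln, aln.sample_ids[:20], aln.sample_ids[20:])
        assert res.nmax == 820

    def test_one_shared_pair_of_six(self):
        aln = aln_from_strings(
            ["AAAA", "AATT", "AAAA", "TTTT"], ids=["a1", "a2", "b1", "b2"]
        )
        res = haplotype_sharing(aln, ["a1", "a2"], ["b1", "b2"])
        assert res.shared_pairs == 1
        assert res.normalized == pytest.approx(1 / 6)
        assert res.distinct_shared == 1

    def test_overlapping_groups_rejected(self):
        aln = aln_from_strings(["AAAA", "AATT", "TTTT"])
        with pytest.raises(PartitionError):
            haplotype_sharing(aln, ["s1", "s2"], ["s2", "s3"])


class TestHaplogroupCI:
    def test_zero_count_interval_starts_at_zero(self):
        lo, hi = beta_hpd(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(stats.beta.ppf(0.95, 1, 11))

    def test_full_count_interval_ends_at_one(self):
        lo, hi = beta_hpd(10, 10)
        assert hi == 1.0

    def test_symmetric_posterior_symmetric_interval(self):
        lo, hi = beta_hpd(5, 10)
        assert lo + hi == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        for k, n in [(2, 12), (7, 20), (1, 5)]:
            lo, hi = beta_hpd(k, n)
            post = stats.beta(k + 1, n - k + 1)
            ls = np.linspace(0, post.ppf(0.05), 4000)
            us = post.ppf(post.cdf(ls) + 0.95)
            best = np.argmin(us - ls)
            assert lo == pytest.approx(ls[best], abs=2e-3)
            assert hi == pytest.approx(us[best], abs=2e-3)
            assert post.cdf(hi) - post.cdf(lo) == pytest.approx(0.95, abs=1e-6)

    def test_count_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            haplogroup_ci({"H": 11}, n=10)

    def test_table_invariants(self):
        counts = pd.DataFrame(
            {"A": [3, 0], "C": [2, 5], "D": [0, 4]}, index=["pop1", "pop2"]
        )
        table = HaplogroupFreqTable(counts)
        assert np.allclose(table.freqs.sum(axis=1), 1.0)
        assert (table.ci_low.values <= table.freqs.values + 1e-12).all()
        assert (table.freqs.values <= table.ci_high.values + 1e-12).all()


class TestPCA:
    def _table(self):
        return pd.DataFrame(
            {
                "A": [0.5, 0.3, 0.5, 0.1],
                "C": [0.3, 0.4, 0.3, 0.6],
                "D": [0.2, 0.3, 0.2, 0.3],
            },
            index=["p1", "p2", "p3", "p4"],
        )

    def test_identical_populations_coincide(self):
        res = pca_haplogroups(self._table(), scale_unit=False)
        np.testing.assert_allclose(
            res.coordinates.loc["p1"], res.coordinates.loc["p3"], atol=1e-12
        )

    def test_variance_conservation(self):
        tab = self._table()
        res = pca_haplogroups(tab, scale_unit=False)
        X = tab.values - tab.values.mean(axis=0)
        total_var = (X**2).sum() / (X.shape[0] - 1)
        assert res.eigenvalues.sum() == pytest.approx(total_var)
        assert res.pct_variance.sum() == pytest.approx(100.0)

    def test_rank_one_table_loads_on_pc1(self):
        base = np.array([0.5, 0.3, 0.2])
        direction = np.array([0.1, -0.05, -0.05])
        F = pd.DataFrame(
            [base + t * direction for t in (-1.0, 0.0, 1.0, 2.0)],
            columns=["A", "C", "D"],
        )
        res = pca_haplogroups(F, scale_unit=False)
        assert res.pct_variance[0] == pytest.approx(100.0)

    def test_constant_column_dropped_with_warning(self):
        F = self._table()
        F["E"] = 0.25
        with pytest.warns(RuntimeWarning, match="constant"):
            res = pca_haplogroups(F, scale_unit=True)
        assert "E" not in res.loadings.index

    def test_too_few_populations_rejected(self):
        with pytest.raises(ValueError):
            pca_haplogroups(self._table().iloc[:2])


class TestNMDS:
    def test_recovers_perfectly_embeddable_distances(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        res = nmds(D, k=2, n_restarts=8, seed=1)
        assert res.stress < 1e-3

    def test_three_equidistant_points_form_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = nmds(D, k=2, n_restarts=4, seed=0)
        Y = res.coordinates.values
        dists = sorted(
            np.linalg.norm(Y[i] - Y[j]) for i in range(3) for j in range(i + 1, 3)
        )
        assert dists[2] / dists[0] == pytest.approx(1.0, abs=0.01)

    def test_duplicate_population_coincident(self):
        D = np.array(
            [[0, 0, 1, 1.2], [0, 0, 1, 1.2], [1, 1, 0, 0.8], [1.2, 1.2, 0.8, 0]]
        )
        res = nmds(D, k=2, n_restarts=6, seed=3)
        Y = res.coordinates.values
        assert np.linalg.norm(Y[0] - Y[1]) < 0.05 * np.linalg.norm(Y[0] - Y[2])

    def test_stress_never_increases(self):
        rng = np.random.default_rng(4)
        D = rng.uniform(0.2, 2.0, size=(6, 6))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        res = nmds(D, k=2, n_restarts=3, seed=5)
        hist = res.stress_history
        assert all(b <= a + 1e-8 for a, b in zip(hist, hist[1:]))

    def test_negative_entries_clamped(self):
        D = np.array([[0, -0.01, 0.5], [-0.01, 0, 0.4], [0.5, 0.4, 0]])
        res = nmds(D, k=2, n_restarts=2, seed=0)
        assert np.isfinite(res.stress)

    def test_dimension_error(self):
        with pytest.raises(ValueError):
            nmds(np.zeros((3, 3)), k=3)


class TestKinCandidates:
    def _meta(self, sites):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i+1}" for i in range(len(sites))],
                "site": sites,
                "spatial_group": "YAK",
                "temporal_group": "Late",
                "age_bp": 3000.0,
                "d13C": np.nan,
                "d15N": np.nan,
                "haplogroup": ["C4b"] * len(sites),
            }
        )

    def test_triple_burial_gives_three_pairs(self):
        aln = aln_from_strings(["AAAA", "AAAA", "AAAA", "TTTT"])
        meta = self._meta(["Kamenka", "Kamenka", "Kamenka", "Other"])
        pairs = kin_candidates(aln, meta)
        assert len(pairs) == 3
        assert {frozenset((p.sample_a, p.sample_b)) for p in pairs} == {
            frozenset(x) for x in [("s1", "s2"), ("s1", "s3"), ("s2", "s3")]
        }

    def test_same_haplotype_different_site_excluded(self):
        aln = aln_from_strings(["AAAA", "AAAA"])
        meta = self._meta(["a", "b"])
        assert kin_candidates(aln, meta, same_site_only=True) == []
        assert len(kin_candidates(aln, meta, same_site_only=False)) == 1

    def test_all_distinct_empty(self):
        aln = aln_from_strings(["AAAA", "AATT", "TTTT"])
        meta = self._meta(["x", "x", "x"])
        # identical haplogroup labels only back up samples missing sequence
        assert kin_candidates(aln, meta) == []

    def test_haplogroup_fallback_for_samples_without_sequence(self):
        aln = aln_from_strings(["AAAA", "AATT"])
        meta = self._meta(["x", "x", "x", "x"])
        pairs = kin_candidates(aln, meta)
        assert len(pairs) == 1
        assert pairs[0].basis == "haplogroup"
        assert {pairs[0].sample_a, pairs[0].sample_b} == {"s3", "s4"}
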