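import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import critical_r_bisect, pearson_brute, pearson_pvalue_integral
from coordscan.coordination import (
    CorrelationError,
    CorrelationProfile,
    coordination,
    coordination_scan,
    correlated_gene_set,
    correlated_gene_table,
    correlation_profile,
    critical_r,
    pearson_pvalue,
    pearson_r,
    permutation_pvalue,
)
from coordscan.expression_io import ExpressionMatrix
from coordscan.synthetic import F1_MODULE_IDS

# frozen from the pure-python oracle: pearson_brute((1..6), (2,1,4,3,6,5)) = 14.5/17.5
ORACLE_R_SHUFFLED = 14.5 / 17.5


class TestPearsonR:
    def test_self_correlation(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_sign_reversal(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_shuffled_sequence_oracle(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]
        assert pearson_brute(x, y) == pytest.approx(ORACLE_R_SHUFFLED, abs=1e-15)
        assert pearson_r(x, y) == pytest.approx(ORACLE_R_SHUFFLED, abs=1e-12)
        assert round(pearson_r(x, y), 4) == 0.8286

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert pearson_r(x, y) == pytest.approx(pearson_r(y, x), abs=1e-15)

    def test_constant_vector_error(self):
        with pytest.raises(CorrelationError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch(self):
        with pytest.raises(CorrelationError, match="mismatch"):
            pearson_r([1, 2, 3], [1, 2, 3, 4])

    def test_too_short(self):
        with pytest.raises(CorrelationError, match="at least 3"):
            pearson_r([1, 2], [3, 4])

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=10),
        st.floats(0.1, 50),
        st.floats(-20, 20),
    )
    @settings(max_examples=100)
    def test_positive_affine_invariance(self, x, slope, intercept):
        x = np.asarray(x)
        if np.ptp(x) < 1e-6:
            return
        y = np.arange(len(x), dtype=float)
        r0 = pearson_r(x, y)
        r1 = pearson_r(slope * x + intercept, y)
        assert r1 == pytest.approx(r0, abs=1e-8)


class TestPearsonPvalue:
    def test_null_center(self):
        assert pearson_pvalue(0.0, 6) == pytest.approx(1.0)
        assert pearson_pvalue(0.0, 100) == pytest.approx(1.0)

    def test_degenerate_limit(self):
        assert pearson_pvalue(1.0, 5) == 0.0
        assert pearson_pvalue(-1.0, 5) == 0.0

    def test_integration_oracle_value(self):
        # numeric integration of the t density at df=4 gives ~0.0415
        expected = pearson_pvalue_integral(ORACLE_R_SHUFFLED, 6)
        assert expected == pytest.approx(0.042, abs=1e-3)
        assert pearson_pvalue(ORACLE_R_SHUFFLED, 6) == pytest.approx(expected, abs=1e-10)

    def test_vectorized(self):
        r = np.array([0.0, 0.5, -0.5, 1.0])
        p = pearson_pvalue(r, 10)
        assert p.shape == (4,)
        assert p[1] == pytest.approx(p[2])
        assert p[3] == 0.0

    def test_small_n_error(self):
        with pytest.raises(CorrelationError):
            pearson_pvalue(0.5, 2)

    def test_invalid_r(self):
        with pytest.raises(CorrelationError):
            pearson_pvalue(1.5, 10)

    def test_agrees_with_exhaustive_permutation_n5(self):
        # at n=5 all 120 permutations are enumerable; the analytic t-based p
        # should track the exact permutation p closely for Gaussian draws
        rng = np.random.default_rng(42)
        diffs = []
        for _ in range(30):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            r_obs = abs(pearson_r(x, y))
            count = sum(
                abs(pearson_r(x, np.asarray(perm))) >= r_obs - 1e-12
                for perm in itertools.permutations(y)
            )
            p_exact = count / 120
            diffs.append(abs(p_exact - pearson_pvalue(pearson_r(x, y), 5)))
        assert np.mean(diffs) < 0.06
        assert max(diffs) < 0.2


class TestCriticalR:
    def test_alpha_near_one(self):
        assert critical_r(6, 0.9999) == pytest.approx(0.0, abs=1e-3)

    def test_n6_alpha005_bisection_oracle(self):
        expected = critical_r_bisect(6, 0.05)
        assert expected == pytest.approx(0.811, abs=1e-3)
        assert critical_r(6, 0.05) == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_n(self):
        assert critical_r(10, 0.05) < critical_r(6, 0.05)
        rs = [critical_r(n, 0.05) for n in range(3, 40)]
        assert all(a > b for a, b in zip(rs, rs[1:]))

    @pytest.mark.parametrize("n", [4, 6, 12, 30])
    @pytest.mark.parametrize("alpha", [0.001, 0.01, 0.05, 0.5])
    def test_round_trip(self, n, alpha):
        assert pearson_pvalue(critical_r(n, alpha), n) == pytest.approx(alpha, abs=1e-9)

    def test_bad_args(self):
        with pytest.raises(CorrelationError):
            critical_r(2, 0.05)
        with pytest.raises(CorrelationError):
            critical_r(6, 0.0)


class TestCorrelationProfile:
    def test_self_entry_and_length(self, f1_matrix):
        prof = correlation_profile(f1_matrix, "RASSF1")
        assert prof.r_values.size == f1_matrix.n_genes
        assert prof.r_values[f1_matrix.gene_index("RASSF1")] == 1.0
        assert np.all(np.abs(prof.r_values) <= 1.0)

    def test_unknown_gene(self, f1_matrix):
        with pytest.raises(KeyError, match="NOPE"):
            correlation_profile(f1_matrix, "NOPE")

    def test_constant_gene_rejected(self):
        vals = np.arange(12, dtype=float).reshape(4, 3)
        vals[1] = 5.0
        m = ExpressionMatrix(tuple("ABCD"), ("S1", "S2", "S3"), vals)
        with pytest.raises(CorrelationError, match="filter_invariant_genes"):
            correlation_profile(m, "A")

    def test_f1_module_entries_exceed_critical(self, f1_matrix):
        # brute-force per-pair oracle confirms every module gene's correlation
        # with the planted target clears the significance threshold
        prof = correlation_profile(f1_matrix, "RASSF1")
        crit = critical_r(f1_matrix.n_samples, 0.05)
        target_row = f1_matrix.row("RASSF1")
        for g in F1_MODULE_IDS:
            oracle = pearson_brute(list(target_row), list(f1_matrix.row(g)))
            entry = prof.r_values[f1_matrix.gene_index(g)]
            assert entry == pytest.approx(oracle, abs=1e-10)
            assert entry > crit

    def test_matches_brute_force_on_random_entries(self, f1_matrix):
        prof = correlation_profile(f1_matrix, "HSPA5")
        rng = np.random.default_rng(1)
        rows = f1_matrix.values
        base = f1_matrix.gene_index("HSPA5")
        for j in rng.choice(f1_matrix.n_genes, size=25, replace=False):
            if j == base:
                continue
            oracle = pearson_brute(list(rows[base]), list(rows[j]))
            assert prof.r_values[j] == pytest.approx(oracle, abs=1e-10)


def _profile(gene, gene_ids, values, n=12):
    return CorrelationProfile(gene=gene, gene_ids=gene_ids, r_values=np.array(values), n_samples=n)


class TestCoordination:
    def test_identical_profiles(self, f1_matrix):
        prof = correlation_profile(f1_matrix, "HSPA5")
        res = coordination(prof, prof)
        assert res.coordination_r == pytest.approx(1.0)

    def test_negation_example(self):
        ids = ("A", "B", "C", "D", "E")
        a = _profile("A", ids, [1.0, 0.7, 0.9, 0.1, -0.5])
        b = _profile("B", ids, [0.3, 1.0, -0.9, -0.1, 0.5])
        res = coordination(a, b)
        assert res.coordination_r == pytest.approx(-1.0)
        assert res.n_points == 3

    def test_symmetry(self, f1_matrix):
        for ga, gb in [("HSPA5", "RASSF1"), ("ATF4", "DDIT3"), ("BG0001", "DNAJC3")]:
            pa = correlation_profile(f1_matrix, ga)
            pb = correlation_profile(f1_matrix, gb)
            assert coordination(pa, pb).coordination_r == pytest.approx(
                coordination(pb, pa).coordination_r, abs=1e-12
            )

    def test_gene_order_mismatch(self):
        a = _profile("A", ("A", "B", "C"), [1.0, 0.5, 0.2])
        b = _profile("B", ("A", "C", "B"), [0.5, 1.0, 0.2])
        with pytest.raises(CorrelationError, match="gene order"):
            coordination(a, b)

    def test_f1_pair_matches_brute_force(self, f1_matrix):
        # rebuild both profiles entry-by-entry with the pure-python oracle,
        # drop the two self-entries and correlate
        ga, gb = "HSPA5", "RASSF1"
        rows = {g: list(f1_matrix.row(g)) for g in (ga, gb)}
        prof_a, prof_b = [], []
        for g in f1_matrix.gene_ids:
            if g in (ga, gb):
                continue
            other = list(f1_matrix.row(g))
            prof_a.append(pearson_brute(rows[ga], other))
            prof_b.append(pearson_brute(rows[gb], other))
        oracle = pearson_brute(prof_a, prof_b)
        res = coordination(
            correlation_profile(f1_matrix, ga), correlation_profile(f1_matrix, gb)
        )
        assert res.coordination_r == pytest.approx(oracle, abs=1e-10)
        assert res.n_points == f1_matrix.n_genes - 2
        assert res.p_analytic == pytest.approx(
            pearson_pvalue(oracle, res.n_points), abs=1e-12
        )


@pytest.fixture(scope="module")
def small_matrix():
    rng = np.random.default_rng(7)
    vals = rng.normal(size=(40, 10))
    return ExpressionMatrix(
        tuple(f"G{i:03d}" for i in range(40)),
        tuple(f"S{i}" for i in range(10)),
        vals,
    )


class TestPermutationPvalue:
    def test_bounds(self, small_matrix):
        res = permutation_pvalue(small_matrix, "G000", "G001", 99, seed=3)
        assert 1 / 100 <= res.p_permutation <= 1.0

    def test_determinism(self, small_matrix):
        r1 = permutation_pvalue(small_matrix, "G000", "G001", 199, seed=11)
        r2 = permutation_pvalue(small_matrix, "G000", "G001", 199, seed=11)
        assert r1.p_permutation == r2.p_permutation
        assert r1.coordination_r == r2.coordination_r

    def test_min_permutations(self, small_matrix):
        with pytest.raises(CorrelationError, match="99"):
            permutation_pvalue(small_matrix, "G000", "G001", 10, seed=0)

    def test_signal_pair_significant(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=10)
        vals = rng.normal(scale=0.3, size=(30, 10))
        vals[0] += u
        vals[1] += u
        vals[2] += u
        vals[3] += u
        m = ExpressionMatrix(
            tuple(f"G{i:03d}" for i in range(30)), tuple(f"S{i}" for i in range(10)), vals
        )
        res = permutation_pvalue(m, "G000", "G001", 199, seed=1)
        assert res.p_permutation <= 0.05


@pytest.fixture(scope="module")
def f1_scan(f1_matrix):
    return coordination_scan(f1_matrix, list(F1_MODULE_IDS))


class TestCoordinationScan:
    def test_scores_in_range(self, f1_scan):
        t = f1_scan.table
        assert (t["mean_coordination"].abs() <= 1).all()
        assert (t["min_coordination"].abs() <= 1).all()

    def test_panel_excluded(self, f1_scan):
        assert not set(F1_MODULE_IDS) & set(f1_scan.candidates)
        assert len(f1_scan.candidates) == 2008 - 6

    def test_planted_target_rank_one(self, f1_scan):
        assert f1_scan.top_candidate() == "RASSF1"
        assert int(f1_scan.table.iloc[0]["rank"]) == 1

    def test_dense_ranks(self, f1_scan):
        ranks = f1_scan.table["rank"].to_numpy()
        assert ranks[0] == 1
        assert np.all(np.diff(ranks) >= 0)
        assert ranks.max() == f1_scan.table["mean_coordination"].nunique()

    def test_missing_panel_gene(self, f1_matrix):
        with pytest.raises(CorrelationError, match="GHOST"):
            coordination_scan(f1_matrix, ["HSPA5", "GHOST"])

    def test_empty_panel(self, f1_matrix):
        with pytest.raises(CorrelationError, match="at least one"):
            coordination_scan(f1_matrix, [])

    def test_mean_min_consistent_with_pair_columns(self, f1_scan):
        t = f1_scan.table
        pair_cols = [f"coord_{g}" for g in F1_MODULE_IDS]
        np.testing.assert_allclose(
            t[pair_cols].mean(axis=1), t["mean_coordination"], atol=1e-12
        )
        np.testing.assert_allclose(
            t[pair_cols].min(axis=1), t["min_coordination"], atol=1e-12
        )


class TestCorrelatedGeneSet:
    def test_query_excluded(self, f1_matrix):
        genes = correlated_gene_set(f1_matrix, "RASSF1")
        assert "RASSF1" not in genes

    def test_alpha_one_positive_equals_r_positive(self, f1_matrix):
        genes = correlated_gene_set(f1_matrix, "RASSF1", alpha=1.0)
        prof = correlation_profile(f1_matrix, "RASSF1")
        expected = {
            g
            for g, r in zip(f1_matrix.gene_ids, prof.r_values)
            if r > 0 and g != "RASSF1"
        }
        assert set(genes) == expected

    def test_alpha005_count_matches_brute_force(self, f1_matrix):
        genes = correlated_gene_set(f1_matrix, "RASSF1", alpha=0.05)
        target = list(f1_matrix.row("RASSF1"))
        n = f1_matrix.n_samples
        count = 0
        for g in f1_matrix.gene_ids:
            if g == "RASSF1":
                continue
            r = pearson_brute(target, list(f1_matrix.row(g)))
            if r > 0 and pearson_pvalue_integral(r, n) < 0.05:
                count += 1
        assert len(genes) == count

    def test_sorted_by_descending_r(self, f1_matrix):
        table = correlated_gene_table(f1_matrix, "RASSF1", alpha=0.05)
        rs = table["r"].to_numpy()
        assert np.all(np.diff(rs) <= 1e-15)

    def test_direction_both_superset(self, f1_matrix):
        pos = set(correlated_gene_set(f1_matrix, "RASSF1", alpha=0.2))
        both = set(correlated_gene_set(f1_matrix, "RASSF1", alpha=0.2, direction="both"))
        assert pos <= both

    def test_unknown_gene(self, f1_matrix):
        with pytest.raises(KeyError, match="NOPE"):
            correlated_gene_set(f1_matrix, "NOPE")

    def test_bad_direction(self, f1_matrix):
        with pytest.raises(CorrelationError, match="direction"):
            correlated_gene_set(f1_matrix, "RASSF1", direction="negative")
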