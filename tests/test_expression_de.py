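"""TPM, library equalization, qCML dispersion, the exact NB test, BH
adjustment, fold-change gating and centroid clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, kstest, nbinom, poisson

from hemolnc.expression_de import (
    bh_fdr,
    centroid_linkage,
    cluster_heatmap,
    compute_tpm,
    equalize_libraries,
    estimate_common_dispersion,
    exact_test,
    pearson_distance_matrix,
    run_de,
    signed_fold_change,
)


def nb_counts(rng, mu, phi, size):
    if phi == 0:
        return rng.poisson(mu, size=size)
    r = 1 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

class TestTpm:
    def test_worked_two_feature_example(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["a", "b"])
        lengths = pd.Series({"a": 1000.0, "b": 2000.0})
        tpm = compute_tpm(counts, lengths)
        assert tpm.loc["a", "s"] == pytest.approx(666_666.67, abs=0.01)
        assert tpm.loc["b", "s"] == pytest.approx(333_333.33, abs=0.01)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 4)))
        lengths = pd.Series(rng.integers(200, 3000, size=50).astype(float))
        assert np.allclose(compute_tpm(counts, lengths).sum(axis=0), 1e6, rtol=1e-6)

    def test_single_feature_gets_full_million(self):
        counts = pd.DataFrame({"s": [7]}, index=["a"])
        assert compute_tpm(counts, pd.Series({"a": 500.0})).loc["a", "s"] == 1e6

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(20, 3)), index=[f"f{i}" for i in range(20)]
        )
        lengths = pd.Series(rng.integers(200, 2000, size=20).astype(float), index=counts.index)
        tpm = compute_tpm(counts, lengths)
        perm = rng.permutation(counts.index)
        tpm_perm = compute_tpm(counts.loc[perm], lengths)
        assert np.allclose(tpm.loc[perm].to_numpy(), tpm_perm.to_numpy())

    def test_nonpositive_length_rejected(self):
        counts = pd.DataFrame({"s": [1]}, index=["a"])
        with pytest.raises(ValueError, match="positive"):
            compute_tpm(counts, pd.Series({"a": 0.0}))


# ---------------------------------------------------------------------------
# Library equalization
# ---------------------------------------------------------------------------

class TestEqualize:
    def test_equal_libraries_are_untouched(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [20, 10]})
        eq, factors = equalize_libraries(counts)
        assert (eq == counts).all().all()
        assert np.allclose(factors, 1.0)

    def test_geometric_mean_target(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            {"a": rng.integers(0, 2000, 500), "b": rng.integers(0, 8000, 500)}
        )
        eq, _ = equalize_libraries(counts)
        target = np.exp(np.mean(np.log(counts.sum(axis=0))))
        # rounding scatters each column sum around the common target
        assert np.abs(eq.sum(axis=0) - target).max() < 0.001 * target

    def test_zeros_stay_zero(self):
        counts = pd.DataFrame({"a": [0, 100, 0], "b": [0, 0, 400]})
        eq, _ = equalize_libraries(counts)
        assert (eq.to_numpy()[counts.to_numpy() == 0] == 0).all()

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            equalize_libraries(pd.DataFrame({"a": [0, 0], "b": [1, 2]}))


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

class TestDispersion:
    @staticmethod
    def _simulate(rng, phi, n=2000):
        mu = np.exp(rng.uniform(np.log(20), np.log(1000), n))
        counts = pd.DataFrame(
            nb_counts(rng, mu[:, None], phi, (n, 6)), columns=list("abcdef")
        )
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        return counts, groups

    def test_recovers_moderate_dispersion(self):
        rng = np.random.default_rng(10)
        counts, groups = self._simulate(rng, 0.2)
        est = estimate_common_dispersion(counts, groups)
        assert 0.15 <= est.phi <= 0.25

    def test_poisson_data_drives_phi_to_boundary(self):
        rng = np.random.default_rng(11)
        counts, groups = self._simulate(rng, 0.0)
        est = estimate_common_dispersion(counts, groups)
        assert est.phi <= 0.01

    def test_invariant_to_duplicating_features(self):
        rng = np.random.default_rng(12)
        counts, groups = self._simulate(rng, 0.3, n=300)
        doubled = pd.concat([counts, counts], ignore_index=True)
        a = estimate_common_dispersion(counts, groups).phi
        b = estimate_common_dispersion(doubled, groups).phi
        assert a == pytest.approx(b, abs=1e-6)

    def test_all_zero_matrix_rejected(self):
        counts = pd.DataFrame(np.zeros((5, 4), dtype=int), columns=list("abcd"))
        groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        with pytest.raises(ValueError):
            estimate_common_dispersion(counts, groups)


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

def enumeration_oracle(a, b, n_a, n_b, phi):
    """Tabulate the conditional pmf directly from the NB/Poisson pmf."""
    t = a + b
    x = np.arange(t + 1)
    mu = t / (n_a + n_b)
    if phi == 0:
        fa, fb = poisson.pmf(x, n_a * mu), poisson.pmf(t - x, n_b * mu)
    else:
        p = 1 / (1 + phi * mu)
        fa, fb = nbinom.pmf(x, n_a / phi, p), nbinom.pmf(t - x, n_b / phi, p)
    joint = fa * fb
    joint /= joint.sum()
    return float(min(joint[joint <= joint[a] * (1 + 1e-12)].sum(), 1.0))


class TestExactTest:
    def test_symmetric_split_gives_p_one(self):
        assert exact_test(np.array([5, 5, 5]), np.array([5, 5, 5]), 0.1) == pytest.approx(1.0)

    def test_zero_total_gives_p_one(self):
        assert exact_test(np.zeros(3), np.zeros(3), 0.1) == 1.0

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a = rng.integers(0, 50, 3)
            b = rng.integers(0, 50, 3)
            assert exact_test(a, b, 0.2) == pytest.approx(exact_test(b, a, 0.2), rel=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 1.0])
    def test_matches_enumeration_oracle_spot_grid(self, phi):
        for t in range(0, 31, 5):
            for a in range(0, t + 1, 3):
                got = exact_test(np.array([a, 0, 0]), np.array([t - a, 0, 0]), phi)
                assert got == pytest.approx(enumeration_oracle(a, t - a, 3, 3, phi), abs=1e-10)

    def test_poisson_limit_equals_conditional_binomial(self):
        for t in range(1, 31):
            pm = binom.pmf(np.arange(t + 1), t, 0.5)
            for a in range(t + 1):
                expected = min(pm[pm <= pm[a] * (1 + 1e-12)].sum(), 1.0)
                got = exact_test(np.array([a, 0, 0]), np.array([t - a, 0, 0]), 1e-9)
                assert got == pytest.approx(expected, abs=1e-6)

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(14)
        mu = np.exp(rng.uniform(np.log(20), np.log(1000), 2000))
        counts = nb_counts(rng, mu[:, None], 0.2, (2000, 6))
        pvals = np.array(
            [exact_test(row[:3], row[3:], 0.2) for row in counts]
        )
        assert kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# BH and fold change
# ---------------------------------------------------------------------------

def bh_reference(p):
    """Hand-coded step-up oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestBH:
    def test_closed_form_triple(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(15)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            assert np.allclose(bh_fdr(p), bh_reference(p), atol=1e-12)

    def test_adjusted_values_bounded_by_p_and_one(self):
        rng = np.random.default_rng(16)
        p = rng.uniform(size=500)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def test_fold_change_sign_inverts_on_swap():
    rng = np.random.default_rng(17)
    for _ in range(50):
        a, b = rng.uniform(0, 1000, 2)
        fc = signed_fold_change(a, b)
        assert abs(fc) >= 1.0
        assert signed_fold_change(b, a) == pytest.approx(-fc, rel=1e-12)


# ---------------------------------------------------------------------------
# run_de
# ---------------------------------------------------------------------------

class TestRunDe:
    def test_planted_strong_signals_recovered(self):
        rng = np.random.default_rng(18)
        n = 400
        mu = np.exp(rng.uniform(np.log(100), np.log(1000), n))
        lfc = np.zeros(n)
        de_idx = rng.choice(n, size=60, replace=False)
        lfc[de_idx] = rng.uniform(2, 4, size=60) * rng.choice([-1, 1], size=60)
        cols = {}
        for j in range(3):
            cols[f"control_{j}"] = nb_counts(rng, mu, 0.2, n)
        for j in range(3):
            cols[f"LPS_{j}"] = nb_counts(rng, mu * 2.0**lfc, 0.2, n)
        counts = pd.DataFrame(cols, index=[f"f{i}" for i in range(n)])
        lengths = pd.Series(1000.0, index=counts.index)
        conditions = pd.Series(
            {c: ("control" if c.startswith("control") else "LPS") for c in counts.columns}
        )
        res = run_de(counts, lengths, conditions)["LPS"]
        recall = res["de_flag"].to_numpy()[de_idx].mean()
        assert recall >= 0.8
        # direction must match the planted sign
        called = res.iloc[de_idx]
        ok = (np.sign(called["fc"]) == np.sign(lfc[de_idx])) | ~called["de_flag"]
        assert ok.all()

    def test_missing_control_errors(self, synth):
        conditions = synth.cfg.sample_conditions()
        with pytest.raises(ValueError, match="control"):
            run_de(synth.counts, synth.lengths, conditions, control="mock")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def naive_centroid_merges(dist):
    """Brute-force centroid agglomeration oracle (squared-distance LW)."""
    d2 = dist.astype(float) ** 2
    n = d2.shape[0]
    clusters = {i: (i, 1) for i in range(n)}
    D = {frozenset((i, j)): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(clusters) > 1:
        best = min(
            D.items(),
            key=lambda kv: (kv[1], sorted(clusters[s][0] for s in kv[0])),
        )
        si, sj = sorted(best[0], key=lambda s: clusters[s][0])
        dij = D.pop(frozenset((si, sj)))
        (idi, ni), (idj, nj) = clusters[si], clusters[sj]
        merges.append((min(idi, idj), max(idi, idj), np.sqrt(max(dij, 0.0))))
        for sk in list(clusters):
            if sk in (si, sj):
                continue
            dik = D.pop(frozenset((si, sk)))
            djk = D.pop(frozenset((sj, sk)))
            D[frozenset((si, sk))] = (
                (ni * dik + nj * djk) / (ni + nj) - ni * nj * dij / (ni + nj) ** 2
            )
        clusters[si] = (nxt, ni + nj)
        del clusters[sj]
        nxt += 1
    return merges


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        rows = np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4], [9, 1, 5, 2]])
        link = centroid_linkage(pearson_distance_matrix(rows))
        assert link[0, 0] == 0 and link[0, 1] == 1
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_sit_at_distance_two(self):
        rows = np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1]])
        d = pearson_distance_matrix(rows)
        assert d[0, 1] == pytest.approx(2.0)

    def test_zero_variance_row_warns_and_gets_max_distance(self):
        rows = np.array([[1.0, 1, 1, 1], [1.0, 2, 3, 4]])
        with pytest.warns(UserWarning, match="zero-variance"):
            d = pearson_distance_matrix(rows)
        assert d[0, 1] == 2.0

    def test_merge_sequence_matches_naive_oracle(self):
        rng = np.random.default_rng(19)
        rows = rng.normal(size=(8, 4))
        dist = pearson_distance_matrix(rows)
        link = centroid_linkage(dist)
        oracle = naive_centroid_merges(dist)
        for (a, b, h), row in zip(oracle, link):
            assert (a, b) == (row[0], row[1])
            assert h == pytest.approx(row[2], abs=1e-10)

    def test_cluster_heatmap_orders_all_features(self):
        rng = np.random.default_rng(20)
        df = pd.DataFrame(rng.normal(size=(10, 4)), index=[f"f{i}" for i in range(10)])
        link, order, norm = cluster_heatmap(df)
        assert sorted(order) == sorted(df.index)
        assert norm.shape == df.shape
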