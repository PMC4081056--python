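import math
import zlib
from collections import Counter

import numpy as np
import pytest

from decoygen import (
    compressibility,
    cpg_ratio,
    entropy,
    gc_content,
    gc_skew,
    linguistic_complexity,
    markov_entropy,
    metric_matrix,
    metrics_vector,
    pam_silhouette,
    pca_project,
    wootton_federhen,
)
from decoygen.metrics import MetricsVector, pam_cluster

# ---------------------------------------------------------------------------
# brute-force oracles (naive counting / factored formulas)
# ---------------------------------------------------------------------------


def oracle_cwf(seq):
    counts = Counter(seq)
    N = len(seq)
    log_fact = lambda n: sum(math.log(i) for i in range(2, n + 1))
    return (log_fact(N) - sum(log_fact(c) for c in counts.values())) / (
        N * math.log(4)
    )


def oracle_ce(seq):
    N = len(seq)
    return -sum(
        (c / N) * math.log(c / N, 4) for c in Counter(seq).values()
    )


def oracle_cm(seq, m):
    N = len(seq)
    words = Counter(seq[i : i + m] for i in range(N - m + 1))
    d = N - m - 1
    return -sum((c / d) * math.log(c / d) / (m * math.log(4)) for c in words.values())


def oracle_cl(seq, m):
    N = len(seq)
    num = sum(len({seq[i : i + w] for i in range(N - w + 1)}) for w in range(1, m + 1))
    den = sum(min(4**w, N - w + 1) for w in range(1, m + 1))
    return num / den


def random_dna(n, rng):
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, n)])


class TestCompositionExamples:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 0.5), ("AAAA", 0.0), ("GGCC", 1.0)]
    )
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "seq,expected", [("GGGG", 1.0), ("GGCC", 0.0), ("GCC", -1 / 3)]
    )
    def test_gc_skew(self, seq, expected):
        assert gc_skew(seq) == pytest.approx(expected)

    @pytest.mark.parametrize("seq,expected", [("CG", 1.0), ("CGCG", 0.5), ("GC", 0.0)])
    def test_cpg_ratio(self, seq, expected):
        assert cpg_ratio(seq) == pytest.approx(expected)

    def test_cpg_length_normalized_variant_is_explicit(self):
        assert cpg_ratio("CGCG", length_normalized=True) == pytest.approx(2.0)


class TestComplexityExamples:
    def test_cwf_uniform_four(self):
        assert wootton_federhen("ACGT") == pytest.approx(math.log(24, 4) / 4)

    def test_cwf_homopolymer_is_zero(self):
        assert wootton_federhen("AAAA") == 0.0

    @pytest.mark.parametrize("seq,expected", [("ACGT", 1.0), ("AAAA", 0.0), ("AACC", 0.5)])
    def test_entropy(self, seq, expected):
        assert entropy(seq) == pytest.approx(expected)

    def test_markov_entropy_homopolymer_near_zero(self):
        # exactly zero up to the printed N-m-1 denominator convention
        assert markov_entropy("A" * 1000, 6) == pytest.approx(0.0, abs=1e-3)

    def test_linguistic_homopolymer_hand_count(self):
        assert linguistic_complexity("A" * 10, 2) == pytest.approx(2 / 13)

    def test_linguistic_complete_vocabulary_is_one(self):
        # all 4 monomers and all 16 dimers present -> cl_2 == 1
        seq = "AACAGATCCGCTGGTTA"
        assert linguistic_complexity(seq, 2) == pytest.approx(1.0)

    def test_compressibility_orders_homopolymer_below_random(self):
        rng = np.random.default_rng(0)
        assert compressibility("A" * 10_000) < compressibility(random_dna(10_000, rng))

    def test_compressibility_deterministic(self):
        rng = np.random.default_rng(1)
        s = random_dna(5000, rng)
        assert compressibility(s) == compressibility(s)


class TestOracleAgreement:
    def test_all_metrics_match_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            seq = random_dna(int(rng.integers(50, 2000)), rng)
            v = metrics_vector(seq)
            n = Counter(seq)
            N = len(seq)
            assert v.gc == pytest.approx((n["G"] + n["C"]) / N, rel=1e-9)
            assert v.gcs == pytest.approx(
                (n["G"] - n["C"]) / (n["G"] + n["C"]), rel=1e-9
            )
            ncg = sum(1 for i in range(N - 1) if seq[i : i + 2] == "CG")
            assert v.cpg == pytest.approx(ncg / (n["G"] * n["C"]), rel=1e-9)
            assert v.cwf == pytest.approx(oracle_cwf(seq), rel=1e-9)
            assert v.ce == pytest.approx(oracle_ce(seq), rel=1e-9)
            for m in (6, 8, 12):
                assert getattr(v, f"cm_{m}") == pytest.approx(oracle_cm(seq, m), rel=1e-9)
                assert getattr(v, f"cl_{m}") == pytest.approx(oracle_cl(seq, m), rel=1e-9)
            assert v.cz == len(zlib.compress(seq.encode(), 6)) / N

    def test_cwf_never_exceeds_entropy(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            seq = random_dna(int(rng.integers(10, 500)), rng)
            assert wootton_federhen(seq) <= entropy(seq) + 1e-12


class TestMatrixAndProjection:
    def test_matrix_columns_are_zscored(self):
        rng = np.random.default_rng(4)
        seqs = [random_dna(500, rng) for _ in range(8)]
        df = metric_matrix(seqs, [str(i) for i in range(8)])
        assert list(df.columns) == MetricsVector.column_names()
        np.testing.assert_allclose(df.mean(axis=0), 0.0, atol=1e-9)

    def test_identical_rows_project_identically(self):
        X = np.tile([1.0, 2.0, 3.0], (4, 1))
        X[2:] += 1.0
        coords, _ = pca_project(X, 2)
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-12)

    def test_explained_variance_non_increasing_and_reconstruction(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 6))
        coords, evr = pca_project(X, 6)
        assert all(a >= b for a, b in zip(evr, evr[1:]))
        # full-rank projection is lossless: distances preserved
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(coords), pdist(X), atol=1e-8)


class TestPAM:
    def test_three_blobs_recovered_with_high_silhouette(self):
        rng = np.random.default_rng(6)
        X = np.vstack(
            [rng.normal(c, 0.1, size=(15, 3)) for c in ((0, 0, 0), (5, 5, 5), (-5, 5, 0))]
        )
        labels, sil = pam_silhouette(X, 3)
        truth = np.repeat([0, 1, 2], 15)
        for t in range(3):
            assert len(set(labels[truth == t])) == 1
        assert len(set(labels)) == 3
        assert sil > 0.8

    def test_identical_rows_degenerate_flagged(self):
        X = np.ones((6, 4))
        with pytest.warns(UserWarning, match="degenerate"):
            labels, sil = pam_silhouette(X, 3)
        assert math.isnan(sil)

    def test_silhouette_in_unit_interval(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 5))
        _, sil = pam_silhouette(X, 3)
        assert -1.0 <= sil <= 1.0

    def test_pam_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 4))
        np.testing.assert_array_equal(pam_cluster(X, 3), pam_cluster(X, 3))
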