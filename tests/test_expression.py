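"""Quantile normalization, gene z-scores, subtype calling and correlation ranking."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from pdoniche.expression import (
    BASAL_LIKE,
    CLASSICAL,
    ExpressionMatrix,
    GeneSignature,
    MoffittSubtypeClassifier,
    QuantileNormalizer,
    correlate_with_score,
    extract_top_bottom,
    log2_quantile_normalize,
    moffitt_classify,
    quantile_normalize_columns,
    zscore_by_gene,
)


def em(values, genes=None, samples=None, scale="raw"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=genes, columns=samples), scale=scale)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalization:
    def test_hand_oracle_2x2(self):
        # raw [[4,16],[16,4]] -> log2 [[2,4],[4,2]]; both columns already hold
        # the reference sorted values (2,4), so rank-preserving mapping keeps them
        out = log2_quantile_normalize(em([[4, 16], [16, 4]]))
        np.testing.assert_allclose(out.values, [[2, 4], [4, 2]])
        assert out.scale == "log2_quantile"

    def test_identical_columns_unchanged_by_quantile_step(self):
        raw = np.array([[2.0, 2.0], [8.0, 8.0], [32.0, 32.0]])
        out = log2_quantile_normalize(em(raw))
        np.testing.assert_allclose(out.values, np.log2(raw))

    def test_columns_share_sorted_multiset_and_means(self, rng):
        X = rng.lognormal(2, 1, size=(60, 5))
        norm = quantile_normalize_columns(X)
        ref = np.sort(norm[:, 0])
        for j in range(norm.shape[1]):
            np.testing.assert_allclose(np.sort(norm[:, j]), ref, atol=1e-12)
        np.testing.assert_allclose(norm.mean(axis=0), norm.mean(axis=0)[0])

    def test_idempotent_on_own_output(self, rng):
        X = rng.lognormal(2, 1, size=(40, 4))
        once = quantile_normalize_columns(X)
        np.testing.assert_allclose(quantile_normalize_columns(once), once,
                                   atol=1e-12)

    def test_tie_policy_mean_of_occupied_ranks(self):
        # col0 has a tie occupying ranks 1-2; reference = (1.5, 2.5, 4.5)
        X = np.array([[1.0, 2.0], [1.0, 4.0], [3.0, 6.0]])
        out = quantile_normalize_columns(X)
        np.testing.assert_allclose(out[:, 0], [2.0, 2.0, 4.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 2.5, 4.5])

    def test_matches_limma_normalize_quantiles(self, rng, tmp_path):
        """Independent oracle: limma::normalizeQuantiles on a random matrix."""
        X = rng.lognormal(3, 0.8, size=(20, 5)).round(6)
        inp = tmp_path / "x.csv"
        pd.DataFrame(X).to_csv(inp, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.csv("{inp}"))
            write.csv(normalizeQuantiles(x, ties=TRUE), "{tmp_path}/out.csv",
                      row.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        expected = pd.read_csv(tmp_path / "out.csv").to_numpy()
        np.testing.assert_allclose(quantile_normalize_columns(X), expected,
                                   atol=1e-8)

    def test_nonpositive_value_error_names_gene_and_sample(self):
        m = em([[1.0, 2.0], [3.0, -1.0]], genes=["gA", "gB"], samples=["s1", "s2"])
        with pytest.raises(ValueError, match="gB.*s2"):
            log2_quantile_normalize(m)

    def test_already_normalized_input_rejected(self):
        with pytest.raises(ValueError, match="already"):
            log2_quantile_normalize(em([[1.0, 2.0]], scale="log2"))

    def test_estimator_roundtrip_and_params(self, rng):
        X = rng.lognormal(0, 1, size=(6, 30))  # samples x genes orientation
        qn = QuantileNormalizer().fit(X)
        assert qn.get_params() == {}
        out = qn.transform(X)
        ref = np.sort(out[0])
        for row in out:
            np.testing.assert_allclose(np.sort(row), ref, atol=1e-12)


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------

class TestZScore:
    def test_hand_values_and_centering(self):
        m = em([[1.0, 3.0], [2.0, 2.0]], scale="log2")
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_by_gene(m)
        np.testing.assert_allclose(z.iloc[0], [-0.70710678, 0.70710678])
        np.testing.assert_allclose(z.iloc[1], [0.0, 0.0])
        np.testing.assert_allclose(z.sum(axis=1), 0.0, atol=1e-12)

    def test_requires_log_scale_and_two_samples(self):
        with pytest.raises(ValueError, match="log2"):
            zscore_by_gene(em([[1.0, 2.0]], scale="raw"))
        with pytest.raises(ValueError, match="2 samples"):
            zscore_by_gene(em([[1.0]], scale="log2"))


# ---------------------------------------------------------------------------
# subtype classification
# ---------------------------------------------------------------------------

class TestMoffittClassify:
    def toy(self):
        # basal rows [1,3],[2,6]; classical rows [5,1],[8,2]
        return em([[1, 3], [2, 6], [5, 1], [8, 2]],
                  genes=["b1", "b2", "c1", "c2"], samples=["s1", "s2"],
                  scale="log2")

    def test_hand_oracle_two_samples(self):
        scores = moffitt_classify(
            self.toy(), GeneSignature("basal", ["b1", "b2"]),
            GeneSignature("classical", ["c1", "c2"]))
        s1, s2 = scores
        assert s1.total_score == pytest.approx(-2.8284271, abs=1e-6)
        assert s1.label == CLASSICAL
        assert s2.total_score == pytest.approx(+2.8284271, abs=1e-6)
        assert s2.label == BASAL_LIKE

    def test_boundary_zero_is_basal_like(self):
        # identical gene sets for both signatures force total = 0 everywhere
        m = em([[1, 3], [2, 6]], genes=["g1", "g2"], scale="log2")
        sig = GeneSignature("both", ["g1", "g2"])
        for s in moffitt_classify(m, sig, sig):
            assert s.total_score == pytest.approx(0.0, abs=1e-12)
            assert s.label == BASAL_LIKE

    def test_invariant_to_sample_order_and_extra_genes(self, rng):
        X = rng.normal(7, 1, size=(10, 5))
        genes = [f"g{i}" for i in range(10)]
        m = em(X, genes=genes, scale="log2")
        basal = GeneSignature("basal", genes[:3])
        classical = GeneSignature("classical", genes[3:6])
        base = {s.sample_id: s.label for s in moffitt_classify(m, basal, classical)}

        perm = m.data[["s3", "s0", "s4", "s1", "s2"]]
        m2 = ExpressionMatrix(perm, scale="log2")
        assert {s.sample_id: s.label
                for s in moffitt_classify(m2, basal, classical)} == base

        extra = pd.concat([m.data, pd.DataFrame(
            rng.normal(0, 1, size=(4, 5)), columns=m.data.columns,
            index=[f"x{i}" for i in range(4)])])
        m3 = ExpressionMatrix(extra, scale="log2")
        assert {s.sample_id: s.label
                for s in moffitt_classify(m3, basal, classical)} == base

    def test_signature_with_no_matched_gene_errors(self):
        with pytest.raises(ValueError, match="no basal signature gene"):
            moffitt_classify(self.toy(), GeneSignature("basal", ["nope"]),
                             GeneSignature("classical", ["c1"]))

    def test_estimator_predicts_new_samples_on_fitted_axis(self):
        m = self.toy()
        clf = MoffittSubtypeClassifier(
            basal_genes=["b1", "b2"], classical_genes=["c1", "c2"])
        labels = clf.fit_predict(m.data.T)
        assert list(labels) == [CLASSICAL, BASAL_LIKE]
        new = pd.DataFrame([[10.0, 10.0, 0.0, 0.0]], index=["s_new"],
                           columns=["b1", "b2", "c1", "c2"])
        assert clf.predict(new)[0] == BASAL_LIKE
        assert clf.get_params()["basal_genes"] == ["b1", "b2"]


# ---------------------------------------------------------------------------
# correlation ranking
# ---------------------------------------------------------------------------

class TestCorrelationRanking:
    def test_perfect_and_anti_correlated_genes(self):
        score = {"s0": 1.0, "s1": 2.0, "s2": 4.0}
        m = em([[1, 2, 4], [-1, -2, -4], [5, 5, 5]],
               genes=["pos", "neg", "flat"], scale="log2")
        rank = correlate_with_score(m, score)
        assert rank.entries[0][:2] == ("pos", pytest.approx(1.0))
        assert rank.entries[-1][:2] == ("neg", pytest.approx(-1.0))
        assert rank.n_excluded == 1  # flat gene dropped

    def test_agrees_with_bruteforce_on_random_matrices(self, rng):
        for _ in range(50):
            n_genes, n_samples = rng.integers(3, 12), int(rng.integers(3, 8))
            X = rng.normal(0, 1, size=(n_genes, n_samples))
            y = rng.normal(0, 1, size=n_samples)
            m = em(X, scale="log2")
            got = {g: r for g, r, _ in
                   correlate_with_score(m, dict(zip(m.sample_ids, y))).entries}
            for i, g in enumerate(m.gene_ids):
                x = X[i]
                num = np.sum((x - x.mean()) * (y - y.mean()))
                den = np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2))
                assert got[g] == pytest.approx(num / den, abs=1e-12)

    def test_extract_top_bottom_small_and_errors(self):
        score = {"s0": 1.0, "s1": 2.0, "s2": 4.0}
        m = em([[1, 2, 4], [4, 2, 1], [1, 2, 3]],
               genes=["best", "worst", "mid"], scale="log2")
        rank = correlate_with_score(m, score)
        top, bottom = extract_top_bottom(rank, k=1)
        assert top == ["best"] and bottom == ["worst"]
        with pytest.raises(ValueError, match="k="):
            extract_top_bottom(rank, k=2)

    def test_ties_broken_by_gene_id(self):
        score = {"s0": 1.0, "s1": 2.0, "s2": 4.0}
        X = np.array([[1, 2, 4]] * 3 + [[4, 2, 1]] * 3, dtype=float)
        m = em(X, genes=["zz", "aa", "mm", "z2", "a2", "m2"], scale="log2")
        rank = correlate_with_score(m, score)
        assert [g for g, _, _ in rank.entries[:3]] == ["aa", "mm", "zz"]
        top, bottom = extract_top_bottom(rank, k=3)
        assert top == ["aa", "mm", "zz"]
        assert bottom == ["a2", "m2", "z2"]

    def test_missing_scores_rejected(self):
        m = em(np.ones((2, 3)), scale="log2")
        with pytest.raises(ValueError, match="missing"):
            correlate_with_score(m, {"s0": 1.0})
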