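import numpy as np
import pandas as pd
import pytest

from ruvnb.evaluation import (
    OMEGA_CAP,
    canonical_correlations,
    control_cpm_ratio,
    factor_correlation,
    pca_scores,
    rle_matrix,
    rle_ncc,
    rle_quality,
    silhouette_by_label,
)
from ruvnb.io import ControlSet, CountMatrix


class TestRleMatrix:
    def test_hand_rows(self):
        logm = np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        out = rle_matrix(logm)
        np.testing.assert_allclose(out[0], [-1, 0, 1])
        np.testing.assert_allclose(out[1], 0)

    def test_row_medians_zero(self):
        rng = np.random.default_rng(0)
        out = rle_matrix(rng.normal(size=(30, 11)))
        np.testing.assert_allclose(np.median(out, axis=1), 0, atol=1e-12)


class TestRleQuality:
    def test_perfect_replicates_cap(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=20)
        logm = np.column_stack([col, col, col + 1, col + 1])  # identical within groups
        summ = rle_quality(rle_matrix(logm), np.array(["a", "a", "b", "b"]))
        assert summ.omega == OMEGA_CAP and summ.omega_capped

    def test_known_injected_variance(self):
        # per-sample shifts (0, 0.2) in both groups: V_med = 0.02 exactly,
        # V_iqr = 0, so omega = -ln 0.02
        rng = np.random.default_rng(2)
        col = rng.normal(size=50)
        logm = np.column_stack([col, col + 0.2, col, col + 0.2])
        summ = rle_quality(rle_matrix(logm), np.array(["a", "a", "b", "b"]))
        assert summ.v_med == pytest.approx(0.02, rel=1e-9)
        assert summ.v_iqr == pytest.approx(0.0, abs=1e-12)
        assert summ.omega == pytest.approx(-np.log(0.02), rel=1e-9)
        assert summ.omega == pytest.approx(3.912, abs=1e-3)

    def test_shift_variance_lowers_omega(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=80)
        base = np.column_stack([col] * 6)
        shifts = np.array([0, 0.05, 0.1, 0, 0.05, 0.1])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        low = rle_quality(rle_matrix(base + shifts * 4), groups)
        high = rle_quality(rle_matrix(base + shifts), groups)
        assert low.omega < high.omega

    def test_all_singleton_groups_rejected(self):
        with pytest.raises(ValueError):
            rle_quality(np.zeros((5, 3)), np.array(["a", "b", "c"]))


class TestRleNcc:
    def test_exact_factor_copy_gives_zero(self):
        rng = np.random.default_rng(4)
        n = 40
        batch = np.repeat(["x", "y"], n // 2)
        md = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                           "replicate_group": "g", "batch": batch})
        summary = np.column_stack([(batch == "x").astype(float), rng.normal(size=n)])
        assert rle_ncc(summary, md, ["batch"]) == pytest.approx(0.0, abs=1e-9)

    def test_independent_summaries_score_high(self):
        rng = np.random.default_rng(5)
        n = 200
        md = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                           "replicate_group": "g",
                           "batch": rng.choice(["x", "y", "z"], n)})
        summary = rng.normal(size=(n, 2))
        assert rle_ncc(summary, md, ["batch"]) >= 0.7

    def test_single_pair_reduces_to_pearson(self):
        rng = np.random.default_rng(6)
        n = 60
        batch = np.repeat(["x", "y"], n // 2)
        md = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                           "replicate_group": "g", "batch": batch})
        x = (batch == "x").astype(float) * 0.8 + rng.normal(size=n) * 0.3
        got = rle_ncc(np.column_stack([x, x]), md, ["batch"])
        r = abs(np.corrcoef(x, (batch == "x").astype(float))[0, 1])
        assert got == pytest.approx(1 - r, abs=1e-6)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        n = 50
        labels = rng.choice(["a", "b"], n)
        md1 = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                            "replicate_group": "g", "batch": labels})
        md2 = md1.assign(batch=np.where(labels == "a", "Q", "R"))
        summary = rng.normal(size=(n, 2))
        assert rle_ncc(summary, md1, ["batch"]) == pytest.approx(
            rle_ncc(summary, md2, ["batch"]), abs=1e-12
        )


class TestPca:
    def test_rank_one_data(self):
        rng = np.random.default_rng(8)
        direction = rng.normal(size=15)
        weights = rng.normal(size=8)
        m = np.outer(direction, weights)  # taxa x samples, rank 1
        scores, explained = pca_scores(m, n_components=3)
        assert explained[0] == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(explained) <= 1e-12).all()

    def test_duplicated_sample_identical_scores(self):
        rng = np.random.default_rng(9)
        m = rng.normal(size=(20, 7))
        m[:, 3] = m[:, 5]
        scores, _ = pca_scores(m, n_components=2)
        np.testing.assert_allclose(scores[3], scores[5], atol=1e-10)

    def test_constant_matrix_zero_scores(self):
        with pytest.warns(UserWarning):
            scores, explained = pca_scores(np.ones((5, 6)), n_components=2)
        assert not scores.any()


class TestSilhouette:
    def test_separated_clusters(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 0.05, size=(20, 3))
        b = rng.normal(5, 0.05, size=(20, 3)) + np.array([5, 0, 0])
        labels = np.array(["a"] * 20 + ["b"] * 20)
        assert silhouette_by_label(np.vstack([a, b]), labels) >= 0.9

    def test_permuted_labels_near_zero(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(200, 4))
        labels = rng.permutation(np.repeat(["a", "b"], 100))
        assert abs(silhouette_by_label(X, labels)) < 0.1

    def test_identical_points_different_labels_score_zero(self):
        X = np.zeros((2, 2))
        assert silhouette_by_label(X, np.array(["a", "b"])) == 0.0

    def test_agrees_with_bruteforce(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(25, 3))
        labels = rng.choice(["a", "b", "c"], 25)

        def brute(X, labels):
            n = len(X)
            vals = []
            for i in range(n):
                same = [j for j in range(n) if labels[j] == labels[i] and j != i]
                if not same:
                    vals.append(0.0)
                    continue
                a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
                b = min(
                    np.mean([np.linalg.norm(X[i] - X[j]) for j in range(n) if labels[j] == g])
                    for g in set(labels) - {labels[i]}
                )
                vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
            return float(np.mean(vals))

        assert silhouette_by_label(X, labels) == pytest.approx(brute(X, labels), abs=1e-12)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            silhouette_by_label(np.zeros((3, 2)), np.array(["a"] * 3))


class TestFactorCorrelation:
    def _md(self, n, batch):
        return pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                             "replicate_group": "g", "batch": batch})

    def test_numeric_self_correlation(self):
        rng = np.random.default_rng(13)
        w = rng.normal(size=30)
        md = self._md(30, np.repeat(["x", "y"], 15))
        out = factor_correlation(w[:, None], md, {"log_geomean": w})
        assert out[("W1", "log_geomean")] == pytest.approx(1.0, abs=1e-12)

    def test_independent_factor_low(self):
        rng = np.random.default_rng(14)
        n = 200
        md = self._md(n, rng.choice(["x", "y"], n))
        out = factor_correlation(rng.normal(size=(n, 1)), md)
        assert out[("W1", "batch")] < 0.25

    def test_injected_batch_detected(self):
        rng = np.random.default_rng(15)
        n = 60
        batch = np.repeat(["x", "y"], n // 2)
        W = np.column_stack(
            [rng.normal(size=n), (batch == "x") * 2.0 + rng.normal(size=n) * 0.3]
        )
        out = factor_correlation(W, self._md(n, batch))
        assert out[("W2", "batch")] >= 0.8

    def test_degenerate_column_zero(self):
        md = self._md(10, np.repeat(["x", "y"], 5))
        out = factor_correlation(np.zeros((10, 1)), md)
        assert out[("W1", "batch")] == 0.0


class TestControlCpmRatio:
    def _setup(self, spiked_cpm, unspiked_cpm):
        counts = np.zeros((2, 4), dtype=int)
        counts[0] = [spiked_cpm, spiked_cpm, unspiked_cpm, unspiked_cpm]
        counts[1] = 10_000  # filler keeps library sizes comparable
        cm = CountMatrix(["ctl", "fill"], list("abcd"), counts)
        md = pd.DataFrame({"sample_id": list("abcd"), "replicate_group": "g",
                           "spiked": [True, True, False, False]})
        return cm, md

    def test_forty_six_fold_screen(self):
        cm, md = self._setup(92, 2)
        ratio = control_cpm_ratio(cm, md, ControlSet(frozenset({"ctl"}), "spike_in"))
        assert ratio["ctl"] == pytest.approx(46.0, rel=0.01)

    def test_identity_and_absent(self):
        cm, md = self._setup(5, 5)
        cs = ControlSet(frozenset({"ctl", "fill"}), "spike_in")
        ratio = control_cpm_ratio(cm, md, cs)
        assert ratio["ctl"] == pytest.approx(1.0, rel=0.01)
        cm2, md2 = self._setup(0, 0)
        r2 = control_cpm_ratio(cm2, md2, ControlSet(frozenset({"ctl"}), "spike_in"))
        assert np.isnan(r2["ctl"])  # 0/0 flagged as undefined

    def test_missing_flag_rejected(self):
        cm, md = self._setup(1, 1)
        with pytest.raises(ValueError):
            control_cpm_ratio(cm, md.drop(columns=["spiked"]),
                              ControlSet(frozenset({"ctl"}), "spike_in"))


def test_canonical_correlations_bounds():
    rng = np.random.default_rng(16)
    X = rng.normal(size=(50, 3))
    rho = canonical_correlations(X, X @ rng.normal(size=(3, 2)))
    assert (rho <= 1 + 1e-12).all() and rho[0] == pytest.approx(1.0, abs=1e-8)
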