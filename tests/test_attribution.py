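import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ruvnb.attribution import (
    affected_abundance_proportion,
    cumulative_pseudo_r2,
    top_affected,
    veall_zimmermann_r2,
)
from ruvnb.io import CountMatrix


def vz_oracle(l1, l0, n):
    """Independently coded published correction formula."""
    g2 = 2 * (l1 - l0)
    aldrich_nelson = g2 / (g2 + n)
    attainable_max = (2 * l0 - n) / (2 * l0)
    return min(max(aldrich_nelson * attainable_max, 0.0), 1.0)


class TestVeallZimmermann:
    def test_hand_computed_value(self):
        # G2 = 40, R2_AN = 40/90, correction (−250)/(−200) = 1.25
        assert veall_zimmermann_r2(-80.0, -100.0, 50) == pytest.approx(
            0.5555555556, abs=1e-6
        )

    def test_null_identity_and_saturation(self):
        assert veall_zimmermann_r2(-100.0, -100.0, 30) == 0.0
        assert veall_zimmermann_r2(-1e-9, -500.0, 30) == pytest.approx(1.0, abs=1e-3)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            l0 = -rng.uniform(10, 1000)
            l1 = l0 + rng.uniform(0, -l0 * 0.9)
            n = int(rng.integers(5, 500))
            assert veall_zimmermann_r2(l1, l0, n) == pytest.approx(
                vz_oracle(l1, l0, n), abs=1e-12
            )

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(-1000, -10),
        st.floats(0.01, 5.0),
        st.floats(0.01, 5.0),
        st.integers(5, 200),
    )
    def test_monotone_in_model_loglik(self, l0, d1, d2, n):
        lo, hi = l0 + min(d1, d2), l0 + max(d1, d2)
        assert veall_zimmermann_r2(hi, l0, n) >= veall_zimmermann_r2(lo, l0, n)

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            veall_zimmermann_r2(1.0, 0.5, 10)


@pytest.fixture(scope="module")
def w_design():
    rng = np.random.default_rng(7)
    W = rng.normal(size=(40, 3))
    W -= W.mean(axis=0)
    return W


def _nb_matrix(rng, eta, phi):
    mu = np.exp(eta)  # (T, N)
    r = (1.0 / phi)[:, None]
    return rng.negative_binomial(r, r / (r + mu))


class TestCumulativeR2:
    def test_single_factor_taxa_attributed_to_it(self, w_design):
        rng = np.random.default_rng(8)
        T = 40
        alpha = np.zeros((3, T))
        alpha[2] = 1.5
        zeta = rng.normal(3.5, 0.8, size=T)
        phi = rng.uniform(0.05, 0.4, size=T)
        eta = zeta[:, None] + (w_design @ alpha).T
        Y = _nb_matrix(rng, eta, phi)
        cm = CountMatrix([f"t{i}" for i in range(T)], [f"s{j}" for j in range(40)], Y)
        attr = cumulative_pseudo_r2(cm, w_design)
        frac = np.mean(attr.delta_r2[attr.ok].argmax(axis=1) == 2)
        assert frac >= 0.95

    def test_zero_design_gives_tiny_increments(self, w_design):
        rng = np.random.default_rng(9)
        Y = rng.poisson(30, size=(25, 40))
        cm = CountMatrix([f"t{i}" for i in range(25)], [f"s{j}" for j in range(40)], Y)
        attr = cumulative_pseudo_r2(cm, np.zeros_like(w_design))
        assert (attr.delta_r2 < 0.02).all()

    def test_cumulative_nondecreasing_and_sums(self, w_design):
        rng = np.random.default_rng(10)
        Y = rng.poisson(20, size=(15, 40))
        cm = CountMatrix([f"t{i}" for i in range(15)], [f"s{j}" for j in range(40)], Y)
        attr = cumulative_pseudo_r2(cm, w_design)
        assert (np.diff(attr.cumulative_r2, axis=1) >= -1e-8).all()
        np.testing.assert_allclose(
            attr.delta_r2.sum(axis=1), attr.cumulative_r2[:, -1], atol=1e-12
        )

    def test_sign_flip_invariance(self, w_design):
        rng = np.random.default_rng(11)
        Y = rng.poisson(25, size=(10, 40))
        cm = CountMatrix([f"t{i}" for i in range(10)], [f"s{j}" for j in range(40)], Y)
        a = cumulative_pseudo_r2(cm, w_design)
        flipped = w_design.copy()
        flipped[:, 1] *= -1
        b = cumulative_pseudo_r2(cm, flipped)
        np.testing.assert_allclose(a.delta_r2, b.delta_r2, atol=1e-6)


class TestTopAffected:
    def _attr(self):
        rng = np.random.default_rng(12)
        T = 30
        from ruvnb.attribution import AttributionResult

        delta = rng.uniform(0, 0.5, size=(T, 2))
        return AttributionResult(
            taxa_ids=[f"t{i:02d}" for i in range(T)],
            delta_r2=delta,
            delta_r2_raw=delta,
            cumulative_r2=np.cumsum(delta, axis=1),
            ok=np.ones(T, dtype=bool),
        )

    def test_full_cut_is_permutation(self):
        attr = self._attr()
        top = top_affected(attr, factor=0, n_top=30)
        assert sorted(top["taxon_id"]) == sorted(attr.taxa_ids)
        assert (np.diff(top["delta_r2"]) <= 1e-12).all()

    def test_singleton_class_merged_into_others(self):
        attr = self._attr()
        classes = {t: "common" for t in attr.taxa_ids}
        classes[attr.taxa_ids[0]] = "rare_class"
        top = top_affected(attr, factor=0, n_top=30, classes=classes)
        assert "rare_class" not in set(top["class"])
        assert (top["class"] == "others").sum() == 1

    def test_class_enrichment_recovered(self, w_design):
        rng = np.random.default_rng(13)
        T = 100
        alpha = np.zeros((3, T))
        labeled = np.arange(50)
        alpha[1, labeled] = 1.8  # only "A"-class taxa respond to factor 2
        zeta = rng.normal(3.0, 0.5, size=T)
        phi = rng.uniform(0.05, 0.3, size=T)
        Y = _nb_matrix(rng, zeta[:, None] + (w_design @ alpha).T, phi)
        cm = CountMatrix([f"t{i}" for i in range(T)], [f"s{j}" for j in range(40)], Y)
        classes = {f"t{i}": ("A" if i < 50 else "B") for i in range(T)}
        attr = cumulative_pseudo_r2(cm, w_design, taxon_class=classes)
        top = top_affected(attr, factor=1, n_top=50)
        assert (top["class"] == "A").sum() >= 45


class TestAbundanceProportion:
    def test_bounds_and_construction(self):
        counts = np.array([[25, 50], [75, 150]])
        cm = CountMatrix(["a", "b"], ["s1", "s2"], counts)
        assert affected_abundance_proportion(cm, {"a"}) == pytest.approx(0.25)
        assert affected_abundance_proportion(cm, {"a", "b"}) == 1.0
        assert affected_abundance_proportion(cm, set()) == 0.0

    def test_unknown_taxon_rejected(self):
        cm = CountMatrix(["a", "b"], ["s1", "s2"], np.ones((2, 2), dtype=int))
        with pytest.raises(KeyError):
            affected_abundance_proportion(cm, {"zzz"})
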