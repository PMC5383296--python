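"""Synthetic chemotype/decoy generator: determinism, oracles, dials."""

import numpy as np
import pytest

from screenratio.classifiers import ClassifierSpec, fit, predict
from screenratio.fingerprints import FingerprintMatrix, bulk_tanimoto
from screenratio.metrics import confusion, mcc
from screenratio.synthetic import (
    ChemotypeModel,
    chemotype_of,
    default_model,
    expected_template_tanimoto,
    make_chemotypes,
    sample_actives,
    sample_decoys,
    similarity_density,
)


class TestChemotypes:
    def test_density_within_binomial_bounds(self):
        t = make_chemotypes(1, 64, 0.25, seed=1)
        assert t.shape == (1, 64)
        # Binomial(64, 0.25): mean 16, sd ~3.46; 4 sigma bounds
        assert 16 - 4 * 3.47 <= t.sum() <= 16 + 4 * 3.47

    def test_deterministic_under_seed(self):
        assert np.array_equal(
            make_chemotypes(5, 128, 0.3, seed=42), make_chemotypes(5, 128, 0.3, seed=42)
        )

    def test_degenerate_density_rejected(self):
        with pytest.raises(ValueError):
            make_chemotypes(1, 64, 0.0, seed=1)
        with pytest.raises(ValueError):
            make_chemotypes(0, 64, 0.3, seed=1)
        assert make_chemotypes(2, 8, 0.0, seed=1, allow_empty=True).sum() == 0

    def test_model_validation(self):
        t = make_chemotypes(2, 32, 0.3, seed=0)
        probs = np.full(32, 0.2)
        with pytest.raises(ValueError):  # near flip must exceed active flip
            ChemotypeModel(t, 0.3, probs, 0.1, 0.2, seed=0)
        with pytest.raises(ValueError):  # active flip below 0.5
            ChemotypeModel(t, 0.5, probs, 0.1, 0.5, seed=0)
        with pytest.raises(ValueError):  # prob vector length must match width
            ChemotypeModel(t, 0.1, probs[:-1], 0.1, 0.3, seed=0)


class TestActives:
    def test_zero_flip_reproduces_template(self):
        t = make_chemotypes(3, 64, 0.3, seed=5)
        model = ChemotypeModel(t, 0.0, np.full(64, 0.2), 0.0, 0.3, seed=5)
        acts = sample_actives(model, 50)
        chemo = chemotype_of(acts.ids)
        assert np.array_equal(acts.bits, t[chemo])

    def test_chemotype_counts_within_binomial_bounds(self):
        model = default_model(k=2, d=64, seed=3)
        acts = sample_actives(model, 1000)
        counts = np.bincount(chemotype_of(acts.ids), minlength=2)
        sd = np.sqrt(1000 * 0.5 * 0.5)
        assert all(abs(c - 500) <= 4 * sd for c in counts)

    def test_template_tanimoto_matches_closed_form(self):
        model = default_model(k=1, d=166, active_flip_prob=0.12, seed=11)
        acts = sample_actives(model, 4000)
        sims = bulk_tanimoto(acts.bits, model.templates)[:, 0]
        m = int(model.templates[0].sum())
        expected = expected_template_tanimoto(m, 166, 0.12)
        # Monte-Carlo error of the mean ~ sd/sqrt(n); allow 5 standard errors
        tol = 5 * sims.std() / np.sqrt(len(sims)) + 0.01  # +first-order approx slack
        assert abs(sims.mean() - expected) < tol

    def test_determinism(self, small_model):
        a1 = sample_actives(small_model, 77)
        a2 = sample_actives(small_model, 77)
        assert a1.ids == a2.ids
        assert np.array_equal(a1.bits, a2.bits)


class TestDecoys:
    def test_no_near_actives_when_fraction_zero(self):
        model = default_model(k=2, d=64, near_active_fraction=0.0, seed=9)
        dec = sample_decoys(model, 500)
        assert not any("_H" in cid for cid in dec.ids)

    def test_near_active_count_within_binomial_bounds(self):
        model = default_model(k=2, d=64, near_active_fraction=0.1, seed=9)
        dec = sample_decoys(model, 10000)
        n_hard = sum("_H" in cid for cid in dec.ids)
        sd = np.sqrt(10000 * 0.1 * 0.9)
        assert abs(n_hard - 1000) <= 4 * sd

    def test_limiting_case_decoys_match_active_distribution(self):
        # all decoys near-active with the active flip rate: statistically
        # indistinguishable from actives (compare mean template similarity)
        t = make_chemotypes(1, 128, 0.3, seed=2)
        m_act = ChemotypeModel(t, 0.15, np.full(128, 0.2), 0.0, 0.5, seed=2)
        m_dec = ChemotypeModel(t, 0.1, np.full(128, 0.2), 1.0, 0.15, seed=2)
        acts = sample_actives(m_act, 2000)
        decs = sample_decoys(m_dec, 2000)
        sa = bulk_tanimoto(acts.bits, t)[:, 0]
        sd_ = bulk_tanimoto(decs.bits, t)[:, 0]
        se = np.sqrt(sa.var() / 2000 + sd_.var() / 2000)
        assert abs(sa.mean() - sd_.mean()) < 5 * se

    def test_determinism(self, small_model):
        d1 = sample_decoys(small_model, 300)
        d2 = sample_decoys(small_model, 300)
        assert d1.ids == d2.ids
        assert np.array_equal(d1.bits, d2.bits)


class TestSimilarityDensity:
    def test_trivial_values(self, small_pools):
        actives, _ = small_pools
        assert similarity_density(actives, actives, 1.0) == 1.0
        assert similarity_density(actives, actives, 0.0) == 1.0

    def test_agrees_with_exhaustive_enumeration(self):
        acts = FingerprintMatrix(
            ["a1", "a2"],
            np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.uint8),
            "hashed-path",
        )
        screen = FingerprintMatrix(
            ["d1", "d2", "d3", "d4"],
            np.array(
                [[1, 1, 0, 0],   # identical to a1 -> max sim 1
                 [1, 0, 0, 0],   # sim 1/2 to a1
                 [0, 1, 1, 0],   # sim 1/3 to both
                 [0, 0, 0, 0]],  # sim 0 to both (nonzero actives)
                dtype=np.uint8,
            ),
            "hashed-path",
        )
        # brute force: max sims are {1, 0.5, 1/3, 0}; fraction >= 0.5 is 2/4
        assert similarity_density(acts, screen, 0.5) == pytest.approx(0.5)
        assert similarity_density(acts, screen, 0.4) == pytest.approx(0.5)
        assert similarity_density(acts, screen, 1 / 3) == pytest.approx(0.75)

    def test_monotone_in_cutoff_and_near_fraction(self):
        fractions = (0.0, 0.3, 0.8)
        densities = []
        for naf in fractions:
            vals = []
            for rep in range(20):
                model = default_model(
                    k=3, d=64, near_active_fraction=naf, seed=100 + rep
                )
                acts = sample_actives(model, 60)
                dec = sample_decoys(model, 400)
                vals.append(similarity_density(acts, dec, 0.6))
            densities.append(np.mean(vals))
            # non-increasing in the cutoff s, exact per sample
            model = default_model(k=3, d=64, near_active_fraction=naf, seed=100)
            acts = sample_actives(model, 60)
            dec = sample_decoys(model, 400)
            ds = [similarity_density(acts, dec, s) for s in (0.0, 0.3, 0.6, 0.9)]
            assert all(a >= b for a, b in zip(ds, ds[1:]))
        assert densities[0] <= densities[1] <= densities[2]

    def test_width_mismatch_rejected(self, small_pools):
        actives, _ = small_pools
        other = FingerprintMatrix(["x"], np.ones((1, 8), dtype=np.uint8), "hashed-path")
        with pytest.raises(ValueError):
            similarity_density(actives, other, 0.5)


def test_separability_dial_orders_classifier_performance():
    """Tight chemotype clusters (low flip) must be easier for 1-NN than
    nearly dissolved ones (flip 0.4), in expectation over replicates."""
    def mean_mcc(flip):
        vals = []
        for rep in range(5):
            model = default_model(
                k=3, d=64, active_flip_prob=flip, near_active_fraction=0.0,
                near_active_flip_prob=0.5, seed=500 + rep,
            )
            acts = sample_actives(model, 80)
            dec = sample_decoys(model, 800)
            X = np.vstack([acts.bits[:40], dec.bits[:400]])
            y = np.r_[np.ones(40, dtype=np.uint8), np.zeros(400, dtype=np.uint8)]
            state = fit(ClassifierSpec("knn1"), X, y)
            Xt = np.vstack([acts.bits[40:], dec.bits[400:]])
            yt = np.r_[np.ones(40, dtype=np.uint8), np.zeros(400, dtype=np.uint8)]
            vals.append(mcc(confusion(predict(state, Xt), yt)))
        return np.mean(vals)

    assert mean_mcc(0.05) > mean_mcc(0.4)
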