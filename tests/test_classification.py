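import numpy as np
import pytest

import whitefly_msi as wm
from whitefly_msi.classification import (
    apply_autoscale,
    classify_image_median,
    predict_labels,
)
from whitefly_msi.evaluation import GroupedSplit


class TestAutoscale:
    def test_two_point_column(self):
        scaled, _ = wm.autoscale(np.array([[2.0], [4.0]]))
        assert np.allclose(scaled[:, 0], [-1.0, 1.0])

    def test_constant_column_zeroed(self):
        scaled, stats = wm.autoscale(np.array([[3.0, 1.0], [3.0, 2.0]]))
        assert np.all(scaled[:, 0] == 0.0) and stats.std[0] == 1.0

    def test_stats_reuse_reproduces(self):
        x = np.random.default_rng(0).normal(size=(20, 4))
        scaled, stats = wm.autoscale(x)
        assert np.array_equal(apply_autoscale(x, stats), scaled)


def two_class_pixels(rng, n_images_per_class=8, px_per_image=30, separation=5.0, n_features=4):
    """Grouped pixel data: class means differ by `separation` noise sd."""
    feats, labels, ids = [], [], []
    for c, name in enumerate(["Other", "SSA1"]):
        for i in range(n_images_per_class):
            x = rng.normal(size=(px_per_image, n_features))
            x[:, 0] += c * separation
            feats.append(x)
            labels += [name] * px_per_image
            ids += [f"{name}_{i}"] * px_per_image
    return wm.LabelledPixels(
        features=np.vstack(feats),
        labels=np.asarray(labels, dtype=object),
        image_ids=np.asarray(ids, dtype=object),
    )


def split_of(pixels, seed=0):
    images = sorted(set(pixels.image_ids.tolist()))
    labels = [i.rsplit("_", 1)[0] for i in images]
    return wm.grouped_split(images, labels, seed=seed)


class TestPlsda:
    def samples(self, rng, n=60, sep=8.0):
        x = rng.normal(size=(2 * n, 3))
        x[n:, 0] += sep
        y = np.array(["A"] * n + ["B"] * n, dtype=object)
        ids = np.array([f"s{i}" for i in range(2 * n)], dtype=object)
        return wm.LabelledPixels(features=x, labels=y, image_ids=ids)

    def test_separable_perfect_training_accuracy(self):
        pixels = self.samples(np.random.default_rng(1))
        model = wm.fit_plsda(pixels, n_latent=1, n_train_per_class=20, seed=0)
        pred = predict_labels(model, pixels.features)
        assert (pred == pixels.labels).mean() == 1.0

    def test_permutation_null_near_chance(self):
        """Randomly permuted labels give holdout accuracy near 1/k."""
        rng = np.random.default_rng(2)
        accs = []
        for rep in range(30):
            pixels = self.samples(rng, n=40, sep=0.0)
            perm = rng.permutation(len(pixels.labels))
            shuffled = wm.LabelledPixels(
                features=pixels.features,
                labels=pixels.labels[perm],
                image_ids=pixels.image_ids,
            )
            model = wm.fit_plsda(shuffled, n_latent=2, n_train_per_class=20, seed=rep)
            holdout = ~np.isin(shuffled.image_ids, model.split_train_ids)
            pred = predict_labels(model, shuffled.features[holdout])
            accs.append((pred == shuffled.labels[holdout]).mean())
        n_total = 30 * 40  # holdout samples pooled over repeats
        assert abs(np.mean(accs) - 0.5) < 3 * np.sqrt(0.25 / n_total) + 0.01

    def test_multiclass(self):
        rng = np.random.default_rng(3)
        mus = [np.zeros(4), np.array([6.0, 0, 0, 0]), np.array([0, 6.0, 0, 0])]
        x = np.vstack([rng.normal(size=(30, 4)) + mu for mu in mus])
        y = np.array(sum(([c] * 30 for c in "ABC"), []), dtype=object)
        ids = np.array([f"s{i}" for i in range(90)], dtype=object)
        pixels = wm.LabelledPixels(x, y, ids)
        model = wm.fit_plsda(pixels, n_latent=2, n_train_per_class=15, seed=1)
        pred = predict_labels(model, x)
        assert (pred == y).mean() > 0.95

    def test_determinism(self):
        pixels = self.samples(np.random.default_rng(4))
        m1 = wm.fit_plsda(pixels, n_latent=2, n_train_per_class=20, seed=9)
        m2 = wm.fit_plsda(pixels, n_latent=2, n_train_per_class=20, seed=9)
        assert m1.split_train_ids == m2.split_train_ids
        assert np.array_equal(
            wm.predict_pixel_probs(m1, pixels.features),
            wm.predict_pixel_probs(m2, pixels.features),
        )

    def test_too_many_latent_errors(self):
        pixels = self.samples(np.random.default_rng(5))
        with pytest.raises(ValueError):
            wm.fit_plsda(pixels, n_latent=10, n_train_per_class=20)


class TestSvcGrouped:
    def test_separable_high_accuracy(self):
        rng = np.random.default_rng(6)
        pixels = two_class_pixels(rng, separation=5.0)
        split = split_of(pixels)
        model = wm.fit_svc_grouped(pixels, split, seed=0)
        in_test = np.isin(pixels.image_ids, split.test_image_ids)
        probs = wm.predict_pixel_probs(model, pixels.features[in_test])
        truth = pixels.labels[in_test] == "SSA1"
        assert ((probs > 0.5) == truth).mean() >= 0.99

    def test_null_near_chance(self):
        """Identical class distributions, balanced pixel counts -> ~50%."""
        rng = np.random.default_rng(7)
        pixels = two_class_pixels(rng, separation=0.0, n_images_per_class=10)
        split = split_of(pixels)
        model = wm.fit_svc_grouped(pixels, split, seed=0)
        in_test = np.isin(pixels.image_ids, split.test_image_ids)
        probs = wm.predict_pixel_probs(model, pixels.features[in_test])
        truth = pixels.labels[in_test] == "SSA1"
        acc = ((probs > 0.5) == truth).mean()
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / in_test.sum()) + 0.02

    def test_refit_identical(self):
        rng = np.random.default_rng(8)
        pixels = two_class_pixels(rng)
        split = split_of(pixels)
        p1 = wm.predict_pixel_probs(wm.fit_svc_grouped(pixels, split, seed=3), pixels.features)
        p2 = wm.predict_pixel_probs(wm.fit_svc_grouped(pixels, split, seed=3), pixels.features)
        assert np.array_equal(p1, p2)

    def test_leakage_guard(self):
        rng = np.random.default_rng(9)
        pixels = two_class_pixels(rng)
        with pytest.raises(ValueError, match="disjoint|leak"):
            bad = GroupedSplit(
                train_image_ids=("SSA1_0", "Other_0"),
                test_image_ids=("SSA1_0", "Other_1"),
                seed=0,
            )
            wm.fit_svc_grouped(pixels, bad, seed=0)

    def test_probabilities_normalised_and_duplication_stable(self):
        rng = np.random.default_rng(10)
        pixels = two_class_pixels(rng)
        model = wm.fit_svc_grouped(pixels, split_of(pixels), seed=0)
        x = pixels.features[:10]
        p1 = wm.predict_pixel_probs(model, x)
        assert np.all((p1 >= 0) & (p1 <= 1))
        p2 = wm.predict_pixel_probs(model, np.vstack([x, x]))
        assert np.array_equal(p2[:10], p2[10:])

    def test_margin_pixel_confident(self):
        rng = np.random.default_rng(11)
        pixels = two_class_pixels(rng, separation=5.0)
        model = wm.fit_svc_grouped(pixels, split_of(pixels), seed=0)
        far = np.zeros((1, 4))
        far[0, 0] = 5.0  # deep in SSA1 territory
        assert wm.predict_pixel_probs(model, far)[0] > 0.9


class TestMedianRule:
    def test_rule_instantiation(self):
        res = classify_image_median(np.array([0.4, 0.6, 0.7]))
        assert res.median_prob == pytest.approx(0.6) and res.decision == 1

    def test_boundary_is_class_zero(self):
        res = classify_image_median(np.array([0.5, 0.5, 0.5]))
        assert res.decision == 0 and not res.abstained

    def test_abstention_below_min_pixels(self):
        res = classify_image_median(np.random.default_rng(0).random(100), min_pixels=250)
        assert res.abstained and res.decision == -1

    def test_permutation_and_duplication_invariance(self):
        rng = np.random.default_rng(1)
        probs = rng.random(31)
        base = classify_image_median(probs)
        shuffled = classify_image_median(rng.permutation(probs))
        doubled = classify_image_median(np.concatenate([probs, probs]))
        assert base.decision == shuffled.decision == doubled.decision
        assert base.median_prob == shuffled.median_prob == doubled.median_prob

    def test_classify_images_counts(self):
        rng = np.random.default_rng(12)
        pixels = two_class_pixels(rng, n_images_per_class=3, px_per_image=20)
        model = wm.fit_svc_grouped(pixels, split_of(pixels), seed=0)
        results = wm.classify_images(model, pixels, min_pixels=0)
        assert len(results) == 6
        assert all(r.n_body_pixels == 20 for r in results)
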