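"""Substratum classification and kernel beta-diversity rasters."""

import numpy as np
import pytest

from benthoscape.grids import CategoricalRaster
from benthoscape.seafloor import (
    classify_seafloor,
    confusion_matrix,
    kernel_braycurtis,
    kernel_evenness,
    split_truth_pixels,
    train_substratum_classifier,
)

CS = 2.0


class TestClassifier:
    def test_linearly_separable_toy_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))])
        y = np.repeat([0, 1], 30)
        model = train_substratum_classifier(X, y, seed=0)
        assert (model.predict(X) == y).mean() == 1.0

    def test_same_data_same_seed_identical_predictions(self, rng):
        X = rng.normal(0, 1, (60, 3))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        a = train_substratum_classifier(X, y, seed=5).predict(X)
        b = train_substratum_classifier(X, y, seed=5).predict(X)
        assert np.array_equal(a, b)

    def test_xor_solved_by_radial_kernel(self, rng):
        X = rng.uniform(-1, 1, (200, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        model = train_substratum_classifier(X, y, seed=0)
        assert (model.predict(X) == y).mean() > 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_substratum_classifier(np.zeros((10, 2)), np.zeros(10), seed=0)


class TestSeafloorMap:
    def _setup(self, rng, noise=0.0):
        codes = np.zeros((20, 20), dtype=int)
        codes[:, 10:] = 1
        truth = CategoricalRaster(codes, ("A", "B"), CS)
        pc = codes.astype(float) * 4 + rng.normal(0, noise, codes.shape)
        pix = split_truth_pixels(truth, n_per_class=45, seed=1)
        Xtr = pc[pix.train_idx[:, 0], pix.train_idx[:, 1]][:, None]
        model = train_substratum_classifier(Xtr, pix.train_labels, seed=0)
        smap = classify_seafloor(model, pc[None], ("A", "B"), CS)
        return smap, pix

    def test_perfect_separability_full_accuracy(self, rng):
        smap, pix = self._setup(rng, noise=0.0)
        _, overall, per_class = confusion_matrix(smap, pix)
        assert overall == 1.0
        assert (per_class == 1.0).all()

    def test_confusion_rows_sum_to_validation_counts(self, rng):
        smap, pix = self._setup(rng, noise=2.0)
        cm, _, _ = confusion_matrix(smap, pix)
        counts = np.bincount(pix.valid_labels, minlength=2)
        assert np.array_equal(cm.sum(axis=1).to_numpy(), counts)

    def test_train_validation_disjoint(self, rng):
        _, pix = self._setup(rng)
        train = {tuple(rc) for rc in pix.train_idx}
        valid = {tuple(rc) for rc in pix.valid_idx}
        assert not train & valid

    def test_accuracy_degrades_with_noise(self, rng):
        accs = []
        for noise in (0.0, 3.0, 8.0):
            _, overall, _ = confusion_matrix(*self._setup(np.random.default_rng(7), noise))
            accs.append(overall)
        assert accs[0] >= accs[1] >= accs[2]


def _uniform_map(code=0, n=21, legend=("A", "B", "C", "D")):
    return CategoricalRaster(np.full((n, n), code), legend, CS)


class TestKernelBrayCurtis:
    def test_uniform_map_zero_everywhere(self):
        bc = kernel_braycurtis(_uniform_map(), radius_m=6.0)
        inner = bc[5:-5, 5:-5]
        assert np.allclose(inner[np.isfinite(inner)], 0.0)

    def test_disjoint_compositions_reach_100(self):
        codes = np.ones((21, 21), dtype=int)
        yy, xx = np.mgrid[0:21, 0:21]
        disc = (yy - 10) ** 2 + (xx - 10) ** 2 <= 3.0**2
        codes[disc] = 0
        bc = kernel_braycurtis(CategoricalRaster(codes, ("A", "B"), CS), radius_m=6.0)
        assert bc[10, 10] == pytest.approx(100.0)

    def test_half_half_annulus_gives_50(self):
        # focal disc pure A; annulus half A half B -> BC = 50
        x = np.array([1.0, 0.0])
        y = np.array([0.5, 0.5])
        assert 100 * np.abs(x - y).sum() / (x + y).sum() == pytest.approx(50.0)

    def test_brute_force_equivalence_on_random_map(self, rng):
        codes = rng.integers(0, 3, (20, 20))
        cmap = CategoricalRaster(codes, ("A", "B", "C"), CS)
        radius = 6.0
        bc = kernel_braycurtis(cmap, radius_m=radius)
        r = radius / CS
        r_out = r * np.sqrt(2.0)
        for i, j in [(10, 10), (8, 13), (12, 6)]:
            comp_in = np.zeros(3)
            comp_out = np.zeros(3)
            for ii in range(20):
                for jj in range(20):
                    d2 = (ii - i) ** 2 + (jj - j) ** 2
                    if d2 <= r**2:
                        comp_in[codes[ii, jj]] += 1
                    elif d2 <= r_out**2:
                        comp_out[codes[ii, jj]] += 1
            x = comp_in / comp_in.sum()
            y = comp_out / comp_out.sum()
            expected = 100 * np.abs(x - y).sum() / (x + y).sum()
            assert bc[i, j] == pytest.approx(expected, abs=1e-9)

    def test_relabeling_invariance(self, rng):
        codes = rng.integers(0, 3, (18, 18))
        a = kernel_braycurtis(CategoricalRaster(codes, ("A", "B", "C"), CS), 6.0)
        b = kernel_braycurtis(CategoricalRaster(2 - codes, ("C", "B", "A"), CS), 6.0)
        assert np.allclose(a, b, equal_nan=True)

    def test_range_and_radius_validation(self, rng):
        codes = rng.integers(0, 4, (25, 25))
        bc = kernel_braycurtis(CategoricalRaster(codes, ("A", "B", "C", "D"), CS), 6.0)
        ok = np.isfinite(bc)
        assert bc[ok].min() >= 0 and bc[ok].max() <= 100
        with pytest.raises(ValueError):
            kernel_braycurtis(_uniform_map(), radius_m=1.0)


class TestKernelEvenness:
    def test_single_class_kernel_is_zero(self):
        j = kernel_evenness(_uniform_map(), radius_m=6.0)
        assert np.allclose(j[np.isfinite(j)], 0.0)

    def test_equal_composition_reaches_one(self):
        # 21-cell disc (radius sqrt(5) cells) filled with exactly 7 cells
        # of each of three classes
        codes = np.zeros((15, 15), dtype=int)
        yy, xx = np.mgrid[0:15, 0:15]
        disc = np.argwhere((yy - 7) ** 2 + (xx - 7) ** 2 <= 5.0)
        assert len(disc) == 21
        for n, (i, j) in enumerate(disc):
            codes[i, j] = n % 3
        cmap = CategoricalRaster(codes, ("A", "B", "C"), CS)
        j = kernel_evenness(cmap, radius_m=CS * np.sqrt(5.0))
        assert j[7, 7] == pytest.approx(1.0)

    def test_hand_computed_four_to_one_split(self):
        # disc of radius 1 cell = 5 cells: 4 of class A, 1 of class B
        codes = np.zeros((11, 11), dtype=int)
        codes[5, 6] = 1
        cmap = CategoricalRaster(codes, ("A", "B"), CS)
        j = kernel_evenness(cmap, radius_m=CS)
        p = np.array([0.8, 0.2])
        expected = -(p * np.log(p)).sum() / np.log(2)
        assert j[5, 5] == pytest.approx(expected, rel=1e-9)

    def test_brute_force_equivalence_on_random_map(self, rng):
        codes = rng.integers(0, 4, (20, 20))
        cmap = CategoricalRaster(codes, ("A", "B", "C", "D"), CS)
        j = kernel_evenness(cmap, radius_m=6.0)
        r = 6.0 / CS
        for i, jj_ in [(10, 10), (7, 12)]:
            counts = np.zeros(4)
            for ii in range(20):
                for kk in range(20):
                    if (ii - i) ** 2 + (kk - jj_) ** 2 <= r**2:
                        counts[codes[ii, kk]] += 1
            p = counts[counts > 0] / counts.sum()
            expected = 0.0 if len(p) < 2 else -(p * np.log(p)).sum() / np.log(len(p))
            assert j[i, jj_] == pytest.approx(expected, abs=1e-9)

    def test_bounds(self, rng):
        codes = rng.integers(0, 4, (25, 25))
        j = kernel_evenness(CategoricalRaster(codes, ("A", "B", "C", "D"), CS), 6.0)
        ok = np.isfinite(j)
        assert j[ok].min() >= 0 and j[ok].max() <= 1 + 1e-12
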