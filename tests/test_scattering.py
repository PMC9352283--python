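"""Scattering transform: filter banks, invariants, feature extraction."""

import numpy as np
import pytest
from sklearn.base import clone

from speckleheart.scattering import (ScatteringConfig, ScatteringTransform,
                                     Scattering1D, build_filterbank,
                                     features_for_dataset,
                                     scattering_transform)
from speckleheart.signals import Waveform

SMALL = ScatteringConfig(M=12, N=6, P=3)


class TestFilterBank:
    def test_requested_filter_count(self):
        bank = build_filterbank(1500.0, 56, 20.0, 700.0)
        assert bank.n_filters == 56

    def test_centers_strictly_decreasing_below_nyquist(self):
        bank = build_filterbank(1500.0, 30, 20.0, 700.0)
        centers = np.array(bank.center_freqs)
        assert np.all(np.diff(centers) < 0)
        assert np.all(centers < 750.0)
        assert centers[0] == pytest.approx(700.0)
        assert centers[-1] == pytest.approx(20.0)

    @pytest.mark.parametrize("n_filters", [1, 9, 30, 56])
    def test_littlewood_paley_bound(self, n_filters):
        """Frequency-domain summation oracle: sum of squared magnitudes of
        all wavelets plus the low-pass never exceeds 1."""
        bank = build_filterbank(1500.0, n_filters, 20.0, 700.0)
        grid = np.linspace(0.0, 750.0, 30001)
        assert np.max(bank.littlewood_paley(grid)) <= 1.0 + 1e-6

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            build_filterbank(1500.0, 10, 0.0, 700.0)
        with pytest.raises(ValueError):
            build_filterbank(1500.0, 10, 20.0, 800.0)
        with pytest.raises(ValueError):
            build_filterbank(1500.0, 0, 20.0, 700.0)


class TestScatteringTransformCore:
    def test_zero_signal_gives_zero_coefficients(self):
        out = scattering_transform(Waveform(np.zeros(3750), 1500.0),
                                   ScatteringConfig())
        assert np.all(out.values == 0)

    def test_path_count_matches_enumeration_oracle(self):
        """Brute-force enumeration of frequency-decreasing paths over the
        banks' centre frequencies predicts the coefficient count."""
        config = ScatteringConfig(M=20, N=10, P=5)
        b1, b2, b3 = config.banks()
        count = 1 + len(b1.center_freqs)
        for f1 in b1.center_freqs:
            for f2 in b2.center_freqs:
                if f2 < f1:
                    count += 1
                    for f3 in b3.center_freqs:
                        if f3 < f2:
                            count += 1
        out = scattering_transform(
            Waveform(np.random.default_rng(0).normal(size=2048), 1500.0),
            config)
        assert len(out) == count
        assert len(out.path_labels) == count

    def test_shift_stability(self, pcg_segment):
        """A 50-sample circular shift barely moves the features although it
        decorrelates the raw waveform."""
        config = ScatteringConfig()
        a = scattering_transform(pcg_segment, config).values
        shifted = Waveform(np.roll(pcg_segment.samples, 50), pcg_segment.fs)
        b = scattering_transform(shifted, config).values
        rel_feat = np.linalg.norm(b - a) / np.linalg.norm(a)
        rel_raw = (np.linalg.norm(shifted.samples - pcg_segment.samples)
                   / np.linalg.norm(pcg_segment.samples))
        assert rel_feat < 0.05
        assert rel_raw > 0.5

    def test_non_expansive_map(self, rng):
        """||S(x) - S(y)|| <= ||x - y|| over random signal pairs."""
        net = Scattering1D(SMALL, 768)
        for _ in range(100):
            x = rng.standard_normal(768)
            y = rng.standard_normal(768)
            ds = np.linalg.norm(net.transform(x).values
                                - net.transform(y).values)
            assert ds <= np.linalg.norm(x - y) * (1 + 1e-9)

    def test_energy_bounded_per_order(self, rng):
        """At every order the summed pre-averaging path energy stays below
        the input energy (Littlewood-Paley bound, exact single-rate mode)."""
        config = ScatteringConfig(M=12, N=6, P=3, subsample=False)
        net = Scattering1D(config, 1024)
        x = rng.standard_normal(1024)
        energies = {1: 0.0, 2: 0.0, 3: 0.0}
        for label, env in net.path_envelopes(x).items():
            energies[len(label)] += float(np.sum(env ** 2))
        ex = float(np.sum(x ** 2))
        for order in (1, 2, 3):
            assert energies[order] <= ex * (1 + 1e-6)

    def test_shift_distance_shrinks_with_invariance_scale(self, pcg_segment):
        """Frame-level feature distance under a fixed shift is non-
        increasing as T doubles (0.25 -> 0.5 -> 1.0 s)."""
        dists = []
        for T in (0.25, 0.5, 1.0):
            net = Scattering1D(ScatteringConfig(M=12, N=6, P=3, T=T),
                               len(pcg_segment))
            a = net.transform_frames(pcg_segment.samples)
            b = net.transform_frames(np.roll(pcg_segment.samples, 50))
            dists.append(np.linalg.norm(a - b) / np.linalg.norm(a))
        assert dists[0] >= dists[1] >= dists[2]

    def test_multirate_matches_exact_mode(self, pcg_segment):
        fast = scattering_transform(pcg_segment, SMALL).values
        exact = scattering_transform(
            pcg_segment, ScatteringConfig(M=12, N=6, P=3,
                                          subsample=False)).values
        np.testing.assert_allclose(fast, exact,
                                   atol=1e-5 * np.max(np.abs(exact)))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            scattering_transform(Waveform(np.zeros(100), 1500.0),
                                 ScatteringConfig(T=0.5))


class TestFeaturesForDataset:
    def _segments(self, rng, n=5, length=768):
        return [Waveform(rng.standard_normal(length), 1500.0)
                for _ in range(n)]

    def test_one_row_per_segment(self, rng):
        segs = self._segments(rng)
        matrix, labels = features_for_dataset(segs, SMALL)
        assert matrix.shape == (5, len(labels))

    def test_permutation_equivariance(self, rng):
        segs = self._segments(rng)
        m1, _ = features_for_dataset(segs, SMALL)
        m2, _ = features_for_dataset(segs[::-1], SMALL)
        np.testing.assert_allclose(m1, m2[::-1], atol=1e-6)

    def test_duplicate_segments_give_identical_rows(self, rng):
        seg = self._segments(rng, n=1)[0]
        matrix, _ = features_for_dataset([seg, seg], SMALL)
        np.testing.assert_array_equal(matrix[0], matrix[1])

    def test_heterogeneous_lengths_rejected(self, rng):
        segs = [Waveform(rng.standard_normal(768), 1500.0),
                Waveform(rng.standard_normal(800), 1500.0)]
        with pytest.raises(ValueError):
            features_for_dataset(segs, SMALL)


class TestSklearnEstimator:
    def test_fit_transform_shapes(self, rng):
        X = rng.standard_normal((4, 768))
        est = ScatteringTransform(M=12, N=6, P=3)
        out = est.fit_transform(X)
        assert out.shape == (4, est.n_paths_)

    def test_params_clone_roundtrip(self):
        est = ScatteringTransform(M=8, N=4, P=2, T=0.25, log=True)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_transform_before_fit_raises(self, rng):
        with pytest.raises(RuntimeError):
            ScatteringTransform().transform(rng.standard_normal((2, 768)))

    def test_log_option_applies_elementwise(self, rng):
        X = rng.standard_normal((2, 768))
        raw = ScatteringTransform(M=8, N=4, P=2, log=False).fit_transform(X)
        logged = ScatteringTransform(M=8, N=4, P=2, log=True,
                                     eps=1e-3).fit_transform(X)
        np.testing.assert_allclose(logged, np.log(1e-3 + np.abs(raw)),
                                   atol=1e-10)
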