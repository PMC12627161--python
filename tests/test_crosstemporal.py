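"""Downsampling, cross-temporal matrices and their regression decomposition."""

import numpy as np
import pytest

import rrsa
from rrsa.crosstemporal import iter_cts_batches
from rrsa.regression import CONDITIONS


def _make_epochs(data, trials=None, sfreq=1000.0, t0=-800.0, pid="sub-00"):
    data = np.asarray(data, float)
    times = t0 + np.arange(data.shape[2]) * 1000.0 / sfreq
    trials = trials or [f"s{k:03d}" for k in range(data.shape[0])]
    return rrsa.EpochsTensor(pid, trials, data, times, sfreq)


class TestDownsample:
    def test_geometry_1000_to_300(self, rng):
        epochs = _make_epochs(rng.normal(size=(2, 4, 800)))
        down = rrsa.downsample_epochs(epochs, 300.0)
        assert down.n_samples == 240
        assert down.sfreq == 300.0
        assert down.times[0] == -800.0
        assert down.times[1] - down.times[0] == pytest.approx(1000.0 / 300.0)

    def test_equal_rate_passthrough(self, rng):
        epochs = _make_epochs(rng.normal(size=(2, 4, 100)))
        down = rrsa.downsample_epochs(epochs, 1000.0)
        np.testing.assert_array_equal(down.data, epochs.data)

    def test_upsampling_rejected(self, rng):
        with pytest.raises(ValueError):
            rrsa.downsample_epochs(_make_epochs(rng.normal(size=(2, 4, 100))), 2000.0)

    def test_sinusoid_preserved(self):
        # a 10-Hz sinusoid is far below the 150-Hz Nyquist of the target rate
        t = np.arange(800) / 1000.0
        wave = np.sin(2 * np.pi * 10 * t)
        epochs = _make_epochs(np.tile(wave, (2, 4, 1)))
        down = rrsa.downsample_epochs(epochs, 300.0)
        t_down = np.arange(down.n_samples) / 300.0
        analytic = np.sin(2 * np.pi * 10 * t_down)
        r = np.corrcoef(down.data[0, 0], analytic)[0, 1]
        assert r > 0.999

    def test_decimate_mode_keeps_samples_untouched(self, rng):
        epochs = _make_epochs(rng.normal(size=(2, 4, 800)))
        down = rrsa.downsample_epochs(epochs, 250.0, method="decimate")
        np.testing.assert_array_equal(down.data, epochs.data[:, :, ::4])
        with pytest.raises(ValueError, match="integer"):
            rrsa.downsample_epochs(epochs, 300.0, method="decimate")


class TestCTSMatrix:
    def test_self_pair_unit_diagonal(self, rng):
        trial = rng.normal(size=(8, 12))
        m = rrsa.cts_matrix(trial, trial)
        np.testing.assert_allclose(np.diag(m.matrix), 1.0, atol=1e-12)

    def test_geometry_240(self, rng):
        m = rrsa.cts_matrix(rng.normal(size=(4, 240)), rng.normal(size=(4, 240)))
        assert m.matrix.shape == (240, 240)

    def test_matches_cell_by_cell_oracle(self, rng):
        a, b = rng.normal(size=(2, 4, 3))
        m = rrsa.cts_matrix(a, b)
        for k in range(3):
            for l in range(3):
                assert m.matrix[k, l] == pytest.approx(
                    rrsa.spatial_pattern_correlation(a[:, k], b[:, l]), abs=1e-12
                )

    def test_orientation_transpose_identity(self, rng):
        a, b = rng.normal(size=(2, 5, 6))
        np.testing.assert_allclose(
            rrsa.cts_matrix(a, b).matrix, rrsa.cts_matrix(b, a).matrix.T, atol=1e-12
        )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            rrsa.cts_matrix(rng.normal(size=(4, 5)), rng.normal(size=(4, 6)))


class TestFitRCTS:
    def _batches(self, table, value_fn, n_samples=5):
        X = table.design_matrix()
        pairs = table.pairs
        mats = np.empty((len(pairs), n_samples, n_samples))
        for p, x in enumerate(X):
            mats[p] = value_fn(x)
        yield pairs, mats

    def test_noise_free_planted_model_recovered_exactly(self, small_table):
        truth = np.array([0.02, 0.05, 0.03, 0.01])

        def cell_values(x):
            base = float(x @ truth)
            return np.full((5, 5), base) + np.eye(5) * 0.01 * x[1]

        rcts = rrsa.fit_rcts(self._batches(small_table, cell_values), small_table)
        np.testing.assert_allclose(rcts.beta[0], np.full((5, 5), 0.02), atol=1e-10)
        np.testing.assert_allclose(
            rcts.beta[1], np.full((5, 5), 0.05) + np.eye(5) * 0.01, atol=1e-10
        )

    def test_constant_stack_gives_intercept_only(self, small_table):
        rcts = rrsa.fit_rcts(
            self._batches(small_table, lambda x: np.full((4, 4), 0.3), n_samples=4),
            small_table,
        )
        np.testing.assert_allclose(rcts.beta[0], 0.3, atol=1e-12)
        np.testing.assert_allclose(rcts.beta[1:], 0.0, atol=1e-12)

    def test_condition_algebra_cellwise(self, small_table, rng):
        noise = rng.normal(scale=0.01, size=(len(small_table), 4, 4))

        def cell_values(x):
            return np.full((4, 4), float(x @ [0.02, 0.05, 0.03, 0.01]))

        pairs, mats = next(self._batches(small_table, cell_values, n_samples=4))
        rcts = rrsa.fit_rcts(iter([(pairs, mats + noise)]), small_table)
        np.testing.assert_allclose(
            rcts["word_specific"] - rcts["unrelated"],
            rcts.beta[1] + rcts.beta[2] + rcts.beta[3],
            atol=1e-12,
        )

    def test_missing_cells_refit_over_valid_pairs(self, small_table):
        truth = np.array([0.02, 0.05, 0.03, 0.01])

        def cell_values(x):
            return np.full((3, 3), float(x @ truth))

        pairs, mats = next(self._batches(small_table, cell_values, n_samples=3))
        mats[2, 1, 1] = np.nan  # one pair missing at one cell
        rcts = rrsa.fit_rcts(iter([(pairs, mats)]), small_table)
        np.testing.assert_allclose(rcts.beta[:, 1, 1], truth, atol=1e-10)
        np.testing.assert_allclose(rcts.beta[:, 0, 0], truth, atol=1e-10)

    def test_streaming_batches_match_single_batch(self, small_table, rng):
        pairs = small_table.pairs
        mats = rng.normal(scale=0.1, size=(len(pairs), 4, 4))
        one = rrsa.fit_rcts(iter([(pairs, mats)]), small_table)
        chunked = rrsa.fit_rcts(
            iter([(pairs[:7], mats[:7]), (pairs[7:], mats[7:])]), small_table
        )
        np.testing.assert_allclose(one.beta, chunked.beta, atol=1e-12)


class TestDiagonalConsistency:
    def test_rcts_diagonal_equals_rrsa_on_downsampled_epochs(self, rng):
        lex, tax = rrsa.make_lexicon(8, 2, 2, seed=4)
        table = rrsa.build_predictor_table(lex, tax)
        truth = rrsa.make_ground_truth(
            lex, tax,
            rrsa.EffectSchedule(
                semantic=rrsa.EffectWindow(-700.0, -550.0, 0.5),
                word_specific=rrsa.EffectWindow(-500.0, -350.0, 1.0),
            ),
            noise_sd=0.5, seed=4,
        )
        epochs = rrsa.simulate_epochs(lex, truth, n_participants=1, n_channels=20, seed=4)[0]
        down = rrsa.downsample_epochs(epochs, 100.0)
        rcts = rrsa.fit_rcts(down, table)
        series = rrsa.pairwise_rsa_series(down)
        signals = rrsa.predicted_condition_signals(rrsa.fit_rrsa(series, table))
        for name in CONDITIONS:
            np.testing.assert_allclose(
                np.diag(rcts[name]), signals[name], atol=1e-8
            )

    def test_transience_patterns_in_disjoint_windows(self, rng):
        # effect planted only early; late-late cells and early-late cells
        # should look like noise
        lex, tax = rrsa.make_lexicon(8, 2, 2, seed=6)
        table = rrsa.build_predictor_table(lex, tax)
        truth = rrsa.make_ground_truth(
            lex, tax,
            rrsa.EffectSchedule(word_specific=rrsa.EffectWindow(-780.0, -600.0, 1.0)),
            noise_sd=1.0, signal_gain=4.0, seed=6,
        )
        tensors = rrsa.simulate_epochs(lex, truth, n_participants=4, n_channels=20, seed=6)
        mats = []
        for epochs in tensors:
            down = rrsa.downsample_epochs(epochs, 50.0)  # 40 samples
            rcts = rrsa.fit_rcts(down, table)
            mats.append(rcts["word_specific"] - rcts["unrelated"])
        ws = np.mean(mats, axis=0)
        early = down.times < -600
        late = down.times > -400
        on_effect = ws[np.ix_(early, early)].mean()
        off_effect = np.abs(ws[np.ix_(late, late)]).mean()
        cross = np.abs(ws[np.ix_(early, late)]).mean()
        assert on_effect > 0.3
        # off-window generalization is estimation noise, far below the effect
        assert off_effect < on_effect / 4
        assert cross < on_effect / 4


def test_iter_cts_batches_covers_all_pairs(rng):
    data = rng.normal(size=(5, 6, 4))
    epochs = rrsa.EpochsTensor(
        "p", [f"s{k}" for k in range(5)], data, np.arange(4.0), 1000.0
    )
    seen = []
    for pairs, mats in iter_cts_batches(epochs, batch_size=3):
        assert mats.shape[0] == len(pairs)
        seen.extend(pairs)
    assert len(seen) == 10
    assert seen == sorted(seen)
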