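"""Pseudo-population assembly, cross-temporal decoding, cluster significance."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import attnpev as ap
from attnpev.binning import BinGrid, RateTensor
from attnpev.decoding import (
    InsufficientTrialsError, InvalidConfigError, InvalidInputError,
)


def _tensor(values):
    values = np.asarray(values, dtype=float)
    u, t, b = values.shape
    grid = BinGrid(window=(0.0, 0.2 + 0.02 * (b - 1)), bin_width_s=0.2, step_s=0.02)
    return RateTensor(values, np.arange(u), np.arange(t), grid)


def _separable_rates(n_units=8, n_per_loc=30, n_bins=4, noise=0.05, seed=0):
    """Disjoint rate ranges per location: trivially decodable."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(ap.LOCATIONS, n_per_loc)
    offsets = {"top": 0.0, "middle": 5.0, "bottom": 10.0}
    values = np.empty((n_units, len(labels), n_bins))
    for t, lab in enumerate(labels):
        values[:, t, :] = offsets[lab] + rng.uniform(0, noise, size=(n_units, n_bins))
    return _tensor(values), np.asarray(labels)


class TestBuildPseudoTrials:
    def test_default_counts(self):
        rates, labels = _separable_rates(n_per_loc=45)
        pseudo = ap.build_pseudo_trials(rates, labels, n_per_condition=40, seed=0)
        assert pseudo.X.shape == (120, 8, 4)
        assert all(np.sum(pseudo.labels == loc) == 40 for loc in ap.LOCATIONS)

    def test_single_pseudo_trial_per_condition(self):
        rates, labels = _separable_rates()
        pseudo = ap.build_pseudo_trials(rates, labels, n_per_condition=1, seed=0)
        assert pseudo.n_pseudo == 3

    def test_without_replacement_needs_enough_trials(self):
        rates, labels = _separable_rates(n_per_loc=10)
        with pytest.raises(InsufficientTrialsError):
            ap.build_pseudo_trials(rates, labels, n_per_condition=40, seed=0,
                                   replace_draws=False)
        # with replacement (auto) it succeeds
        pseudo = ap.build_pseudo_trials(rates, labels, n_per_condition=40, seed=0)
        assert pseudo.n_pseudo == 120

    def test_deterministic_given_seed(self):
        rates, labels = _separable_rates()
        a = ap.build_pseudo_trials(rates, labels, seed=5)
        b = ap.build_pseudo_trials(rates, labels, seed=5)
        np.testing.assert_array_equal(a.X, b.X)

    def test_marginals_match_source(self):
        """Pseudo-trial rates per unit are draws from the source trials."""
        rng = np.random.default_rng(1)
        labels = np.repeat(ap.LOCATIONS, 40)
        values = rng.gamma(2.0, 2.0, size=(2, 120, 1))
        rates = _tensor(values)
        pseudo = ap.build_pseudo_trials(rates, labels, n_per_condition=40, seed=2)
        src = values[0, labels == "top", 0]
        draws = pseudo.X[np.asarray(pseudo.labels) == "top", 0, 0]
        assert set(np.round(draws, 12)) <= set(np.round(src, 12))
        p = stats.ks_2samp(src, draws).pvalue
        assert p > 0.01

    def test_unlabeled_pool(self):
        rates, labels = _separable_rates()
        pseudo = ap.build_pseudo_trials(rates, None, n_per_condition=40, seed=0)
        assert pseudo.labels is None and pseudo.n_pseudo == 40


class TestZscorePerBin:
    def test_pooled_normalization_identity(self):
        rates, labels = _separable_rates(noise=2.0)
        pseudo = ap.build_pseudo_trials(rates, labels, seed=0)
        z = ap.zscore_per_bin(pseudo)
        for b in range(z.n_bins):
            assert z.X[:, :, b].mean() == pytest.approx(0.0, abs=1e-10)
            assert z.X[:, :, b].std() == pytest.approx(1.0, abs=1e-10)

    def test_constant_bin_flagged(self):
        pseudo = ap.PseudoTrialSet(
            X=np.ones((6, 2, 2)), labels=np.repeat(["a", "b"], 3),
            unit_ids=np.arange(2), bin_centers=np.arange(2.0), n_per_condition=3,
        )
        z = ap.zscore_per_bin(pseudo)
        assert np.all(z.X == 0.0)
        assert z.degenerate_bins.all()

    def test_idempotent(self):
        rates, labels = _separable_rates(noise=2.0)
        z1 = ap.zscore_per_bin(ap.build_pseudo_trials(rates, labels, seed=0))
        z2 = ap.zscore_per_bin(z1)
        np.testing.assert_allclose(z1.X, z2.X, atol=1e-10)


class TestDecodeCrossTemporal:
    def test_separable_fixture_decodes_perfectly(self):
        rates, labels = _separable_rates()
        pseudo = ap.zscore_per_bin(ap.build_pseudo_trials(rates, labels, seed=0))
        mat = ap.decode_cross_temporal(pseudo, n_resamples=20, seed=1)
        assert np.all(np.diag(mat.performance) > 0.99)
        assert mat.chance == pytest.approx(1 / 3)
        assert np.all((mat.performance >= 0) & (mat.performance <= 1))

    def test_shuffled_labels_give_chance(self):
        rates, labels = _separable_rates()
        pseudo = ap.zscore_per_bin(ap.build_pseudo_trials(rates, labels, seed=0))
        null = ap.shuffled_baseline(pseudo, n_resamples=100, seed=2)
        assert null["mean"].mean() == pytest.approx(1 / 3, abs=0.04)
        assert np.all(null["lo"] <= null["hi"])

    def test_untuned_population_within_null_band(self):
        rng = np.random.default_rng(3)
        values = rng.normal(5, 1, size=(8, 90, 3))
        rates = _tensor(values)
        labels = np.repeat(ap.LOCATIONS, 30)
        pseudo = ap.zscore_per_bin(ap.build_pseudo_trials(rates, labels, seed=0))
        mat = ap.decode_cross_temporal(pseudo, n_resamples=60, seed=4)
        null = ap.shuffled_baseline(pseudo, n_resamples=60, seed=5)
        mat = ap.significance_map(ap.attach_null(mat, null))
        assert mat.clusters == []
        assert not mat.significant.any()

    def test_deterministic_given_seed(self):
        rates, labels = _separable_rates(noise=3.0)
        pseudo = ap.zscore_per_bin(ap.build_pseudo_trials(rates, labels, seed=0))
        a = ap.decode_cross_temporal(pseudo, n_resamples=10, seed=7)
        b = ap.decode_cross_temporal(pseudo, n_resamples=10, seed=7)
        np.testing.assert_array_equal(a.performance, b.performance)

    def test_monotone_in_tuning_strength(self):
        """Stronger location tuning never hurts decoding (3 levels)."""
        accs = []
        for gain in (1.2, 1.6, 2.4):
            pop = ap.make_population(
                12, {"location_only": 1.0, "color_only": 0, "both": 0, "untuned": 0},
                seed=20, loc_gain=gain,
            )
            trials, spikes = ap.simulate_session(
                pop, ap.ProtocolConfig(n_trials=240), ap.AgentConfig(), seed=21)
            ku, kept = ap.apply_inclusion_filters(spikes, trials)
            pre = ap.subsample_first_k(kept[kept["trial_type"] == "pre_cue"],
                                       by="cue_location", k=20)
            grid = ap.BinGrid(window=(0.1, 0.5))  # one sample-phase bin span
            rates = ap.bin_firing_rates(spikes, pre, grid).select_units(ku)
            rates = rates.select_bins(ap.select_nonoverlapping(grid))
            pseudo = ap.zscore_per_bin(
                ap.build_pseudo_trials(rates, pre["cue_location"].to_numpy(), seed=22))
            mat = ap.decode_cross_temporal(pseudo, n_resamples=30, seed=23)
            accs.append(np.diag(mat.performance).mean())
        assert accs[0] <= accs[1] + 0.03 and accs[1] <= accs[2] + 0.03
        assert accs[2] > accs[0]

    def test_train_frac_leaving_no_test_trials_rejected(self):
        rates, labels = _separable_rates()
        pseudo = ap.build_pseudo_trials(rates, labels, n_per_condition=4, seed=0)
        with pytest.raises(InvalidConfigError):
            ap.decode_cross_temporal(pseudo, train_frac=0.95, n_resamples=2, seed=0)


class TestSignificanceMap:
    def _matrix_from_flags(self, flagged):
        """DecodingMatrix whose 5%-criterion flags equal ``flagged``."""
        b = flagged.shape[0]
        perf = np.where(flagged, 0.9, 0.2)
        null_q95 = np.full((b, b), 0.5)
        return ap.DecodingMatrix(
            performance=perf, spread=np.zeros((b, b)),
            obs_lo=perf - 0.01, obs_hi=perf + 0.01,
            bin_centers=np.arange(b, dtype=float), chance=1 / 3, n_resamples=10,
            null_lo=np.full((b, b), 0.25), null_hi=np.full((b, b), 0.45),
            null_q95=null_q95, null_mean=np.full((b, b), 1 / 3),
        )

    def test_small_cluster_removed_large_retained(self):
        flagged = np.zeros((10, 10), dtype=bool)
        flagged[0, 0:4] = True              # 4 cells: removed at threshold 5
        flagged[5:8, 5:7] = True            # 6 cells: retained
        mat = ap.significance_map(self._matrix_from_flags(flagged), min_cluster_bins=5)
        assert not mat.significant[0, 0:4].any()
        assert mat.significant[5:8, 5:7].all()
        assert [c["size"] for c in mat.clusters] == [6]

    def test_exactly_five_cells_not_retained(self):
        flagged = np.zeros((8, 8), dtype=bool)
        flagged[2, 1:6] = True
        mat = ap.significance_map(self._matrix_from_flags(flagged), min_cluster_bins=5)
        assert not mat.significant.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floodfill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        flagged = rng.random((12, 12)) < 0.35
        mat = ap.significance_map(self._matrix_from_flags(flagged), min_cluster_bins=5)

        # brute-force 4-connected flood fill
        seen = np.zeros_like(flagged)
        keep = np.zeros_like(flagged)
        for i in range(12):
            for j in range(12):
                if flagged[i, j] and not seen[i, j]:
                    stack, comp = [(i, j)], []
                    seen[i, j] = True
                    while stack:
                        a, b = stack.pop()
                        comp.append((a, b))
                        for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                            x, y = a + da, b + db
                            if 0 <= x < 12 and 0 <= y < 12 and flagged[x, y] and not seen[x, y]:
                                seen[x, y] = True
                                stack.append((x, y))
                    if len(comp) > 5:
                        for a, b in comp:
                            keep[a, b] = True
        np.testing.assert_array_equal(mat.significant, keep)

    def test_diagonal_criterion(self):
        flagged = np.zeros((4, 4), dtype=bool)
        mat = self._matrix_from_flags(flagged)
        # obs_lo (0.19) < null_hi (0.45) -> diagonal not significant
        out = ap.significance_map(mat)
        assert not out.significant_diagonal.any()
        mat2 = dataclasses.replace(mat, obs_lo=np.full((4, 4), 0.5))
        assert ap.significance_map(mat2).significant_diagonal.all()

    def test_requires_null(self):
        mat = self._matrix_from_flags(np.zeros((3, 3), dtype=bool))
        mat = dataclasses.replace(mat, null_hi=None, null_q95=None)
        with pytest.raises(InvalidInputError):
            ap.significance_map(mat)


class TestTransferDecode:
    def test_fractions_sum_to_one(self):
        rates, labels = _separable_rates(noise=3.0)
        train = ap.build_pseudo_trials(rates, labels, n_per_condition=20, seed=0)
        test = ap.build_pseudo_trials(rates, None, n_per_condition=40, seed=1)
        res = ap.transfer_decode(train, test, n_resamples=10, seed=2)
        np.testing.assert_allclose(res.fractions.sum(axis=1), 1.0, atol=1e-9)
        assert res.overall_fractions.sum() == pytest.approx(1.0)
        assert res.n_test == 40

    def test_unit_mismatch_rejected(self):
        rates, labels = _separable_rates()
        train = ap.build_pseudo_trials(rates, labels, n_per_condition=10, seed=0)
        other = ap.build_pseudo_trials(rates.select_units([0, 1, 2]), None,
                                       n_per_condition=10, seed=1)
        with pytest.raises(InvalidInputError):
            ap.transfer_decode(train, other, n_resamples=2, seed=0)

    def test_biased_test_set_detected(self):
        """Test pseudo-trials built only from 'top' trials classify as top."""
        rates, labels = _separable_rates(noise=1.0)
        train = ap.build_pseudo_trials(rates, labels, n_per_condition=20, seed=0)
        top_only = rates.select_trials(np.flatnonzero(labels == "top"))
        test = ap.build_pseudo_trials(top_only, None, n_per_condition=40, seed=1)
        res = ap.transfer_decode(train, test, n_resamples=10, seed=2)
        k = list(res.classes).index("top")
        assert np.all(res.fractions[:, k] > 0.9)
        assert res.significant.all()
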