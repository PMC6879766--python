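import numpy as np
import pytest

import cardioahi as ca
from cardioahi.feature_optimisation import (AMSDUndefinedError, CATALOGUE,
                                            GROUP_OF, INPUT_GROUPS,
                                            TransformationChain,
                                            amsd_score, apply_transformation,
                                            optimise_feature)


class TestAMSD:
    def test_hand_computed_example(self):
        # classes {1,3} vs {0,2}: |2-1| / population SD of {0,1,2,3}
        values = np.array([1.0, 3.0, 0.0, 2.0])
        labels = np.array([True, True, False, False])
        expected = 1.0 / np.sqrt(1.25)  # = 0.894427...
        assert ca.amsd(values, labels) == pytest.approx(expected, abs=1e-12)

    def test_identical_distributions_zero(self):
        values = np.array([1.0, 2.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        assert ca.amsd(values, labels) == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, 500)
        labels = rng.random(500) < 0.3
        base = ca.amsd(values, labels)
        for a, b in [(2.0, 5.0), (0.1, -3.0), (137.2, 0.4)]:
            assert ca.amsd(a * values + b, labels) == \
                pytest.approx(base, abs=1e-10)

    def test_missing_values_ignored(self):
        values = np.array([1.0, 3.0, np.nan, 0.0, 2.0, np.nan])
        labels = np.array([True, True, True, False, False, False])
        assert ca.amsd(values, labels) == \
            pytest.approx(1.0 / np.sqrt(1.25), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(AMSDUndefinedError):
            ca.amsd(np.array([1.0, 2.0]), np.array([True, True]))
        assert amsd_score(np.array([1.0, 2.0]), np.array([True, True])) == 0.0

    def test_zero_sd_undefined(self):
        with pytest.raises(AMSDUndefinedError):
            ca.amsd(np.array([1.0, 1.0]), np.array([True, False]))


def spec(name, **params):
    return ca.TransformationSpec(name, GROUP_OF[name],
                                 tuple(sorted(params.items())))


class TestTransformations:
    def test_median_removal(self):
        out = apply_transformation([1.0, 2.0, 4.0], spec("Median"))
        assert np.allclose(out, [-1.0, 0.0, 2.0])

    def test_zscore_population_sd(self):
        out = apply_transformation([1.0, 2.0, 3.0], spec("Z-score"))
        assert np.allclose(out, [-1.22474487, 0.0, 1.22474487], atol=1e-8)

    def test_time_shift_plus_one(self):
        out = apply_transformation([1.0, 2.0, 3.0], spec("Time-shift", shift=1))
        assert np.isnan(out[0]) and np.allclose(out[1:], [1.0, 2.0])

    def test_time_shift_minus_one(self):
        out = apply_transformation([1.0, 2.0, 3.0],
                                   spec("Time-shift", shift=-1))
        assert np.isnan(out[-1]) and np.allclose(out[:-1], [2.0, 3.0])

    def test_winsor_clipping(self):
        x = np.concatenate([np.zeros(1), np.ones(98), [100.0]])
        out = apply_transformation(x, spec("Winsor", bounds=(5, 95)))
        assert out.max() <= np.percentile(x, 95) + 1e-12
        assert out.min() >= np.percentile(x, 5) - 1e-12

    def test_percentile_to_unit_range(self):
        out = apply_transformation([5.0, 1.0, 3.0], spec("Percentile"))
        assert np.allclose(out, [1.0, 0.0, 0.5])

    def test_log_shifts_nonpositive(self):
        out = apply_transformation([-1.0, 0.0, 1.0], spec("Log"))
        assert np.all(np.isfinite(out))
        assert np.all(np.diff(out) > 0)  # order preserved

    def test_boxcox_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        out = apply_transformation(rng.lognormal(0, 1, 200), spec("Box-Cox"))
        assert abs(np.nanmean(out)) < 1e-9
        assert abs(np.nanstd(out) - 1.0) < 1e-9

    def test_missing_propagates(self):
        x = np.array([1.0, np.nan, 3.0, 4.0])
        for name, params in [("Median", {}), ("Z-score", {}),
                             ("Abs", {}), ("Diff", {}), ("Int", {}),
                             ("Winsor", {"bounds": (1, 99)}),
                             ("Average", {"window": 7,
                                          "alignment": "centred"}),
                             ("Quantile", {"distribution": "normal"})]:
            out = apply_transformation(x, spec(name, **params))
            assert np.isnan(out[1]), name

    def test_windowed_sd_ignores_missing(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        out = apply_transformation(x, spec("SD", window=7,
                                           alignment="centred"))
        finite_in = np.isfinite(x)
        assert np.all(np.isfinite(out[finite_in]))

    def test_diff(self):
        out = apply_transformation([1.0, 4.0, 9.0], spec("Diff"))
        assert np.isnan(out[0]) and np.allclose(out[1:], [3.0, 5.0])

    def test_int_cumsum_mean_removed(self):
        out = apply_transformation([1.0, 2.0, 3.0], spec("Int"))
        assert np.allclose(out, [-1.0, -1.0, 0.0])

    def test_lowpass_smooths(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 200)
        out = apply_transformation(x, spec("LPF", cutoff=0.25))
        assert np.std(np.diff(out)) < np.std(np.diff(x))


class TestSuccessorGraph:
    def test_empty_chain_group0(self):
        succ = ca.valid_successor_specs(TransformationChain("f"))
        names = {s.name for s in succ}
        # every transformation lists group 0 among its inputs
        assert names == set(INPUT_GROUPS)

    def test_after_winsor(self):
        chain = TransformationChain("f", [spec("Winsor", bounds=(1, 99))])
        succ = {s.name for s in ca.valid_successor_specs(chain)}
        assert succ == {"Median", "Z-score", "Percentile", "Amplitude",
                        "Box-Cox", "Histogram", "Quantile", "Tukey-Ladder"}

    def test_after_log(self):
        chain = TransformationChain("f", [spec("Log")])
        succ = {s.name for s in ca.valid_successor_specs(chain)}
        assert succ == {"Winsor", "Box-Cox", "Histogram", "Quantile",
                        "Tukey-Ladder"}

    def test_depth_cap(self):
        chain = TransformationChain("f", [spec("Winsor", bounds=(1, 99))] * 5)
        assert ca.valid_successor_specs(chain) == []


class TestGreedySearch:
    def make_data(self, seed=0, n_rec=3, n_epochs=200):
        rng = np.random.default_rng(seed)
        series, labels = [], []
        for _ in range(n_rec):
            lab = rng.random(n_epochs) < 0.3
            x = rng.normal(0, 1, n_epochs) + 0.1 * lab
            series.append(x)
            labels.append(lab)
        return series, labels

    def test_depth1_equals_exhaustive(self):
        series, labels = self.make_data(seed=3)
        flat_labels = np.concatenate(labels)
        best_score, best_spec = amsd_score(np.concatenate(series),
                                           flat_labels), None
        for s in CATALOGUE:
            if 0 not in INPUT_GROUPS[s.name]:
                continue
            transformed = np.concatenate(
                [apply_transformation(x, s) for x in series])
            sc = amsd_score(transformed, flat_labels)
            if sc > best_score:
                best_score, best_spec = sc, s
        chain = optimise_feature(series, labels, max_depth=1)
        assert chain.achieved_amsd == pytest.approx(best_score, rel=1e-12)
        got = chain.specs[0] if chain.specs else None
        assert got == best_spec

    def test_dispersion_signal_found_by_group6(self):
        # class signal carried by local variance: a dispersion operator
        # (SD/MAD) must win the exhaustive depth-1 comparison
        rng = np.random.default_rng(7)
        series, labels = [], []
        for _ in range(3):
            lab = np.zeros(300, bool)
            lab[100:200] = True
            x = rng.normal(0, 1.0, 300)
            x[100:200] *= 3.0  # variance carries the class, mean does not
            series.append(x)
            labels.append(lab)
        chain = optimise_feature(series, labels, max_depth=1)
        assert chain.specs[0].name in ("MAD", "SD")

    def test_amsd_never_decreases(self):
        series, labels = self.make_data(seed=5)
        base = amsd_score(np.concatenate(series), np.concatenate(labels))
        chain = optimise_feature(series, labels)
        assert chain.achieved_amsd >= base
        assert len(chain) <= 5

    def test_replay_reproduces_amsd(self):
        series, labels = self.make_data(seed=11)
        chain = optimise_feature(series, labels, max_depth=3)
        replayed = np.concatenate([ca.apply_chain(x, chain) for x in series])
        assert amsd_score(replayed, np.concatenate(labels)) == \
            pytest.approx(chain.achieved_amsd, rel=1e-12)

    def test_degenerate_feature_empty_chain(self):
        series = [np.full(50, np.nan), np.full(50, np.nan)]
        labels = [np.zeros(50, bool), np.ones(50, bool)]
        chain = optimise_feature(series, labels)
        assert len(chain) == 0 and chain.achieved_amsd == 0.0

    def test_chain_is_graph_legal(self):
        series, labels = self.make_data(seed=13)
        chain = optimise_feature(series, labels)
        g = 0
        for s in chain.specs:
            assert g in INPUT_GROUPS[s.name]
            g = s.group

    def test_round_trip_json(self, tmp_path):
        from cardioahi.feature_optimisation import load_chains, save_chains
        series, labels = self.make_data(seed=17)
        chain = optimise_feature(series, labels, max_depth=2)
        save_chains(tmp_path / "c.json", [chain])
        back = load_chains(tmp_path / "c.json")[0]
        assert back.specs == chain.specs
        assert back.achieved_amsd == chain.achieved_amsd
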