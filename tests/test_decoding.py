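"""Pseudo-population construction and decoding: classifiers, leave-one-out
hygiene, cross-condition generalization, conjunctions, difficulty, and
sample-size curves."""

import numpy as np
import pytest

import viewchoice as vc
from viewchoice.decoding import _loo_nn


def gaussian_population(n_neurons=20, n_per_group=25, sep=10.0, seed=0):
    """Two groups of trials separated by ``sep`` SD along a random axis."""
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=n_neurons)
    axis /= np.linalg.norm(axis)
    a = rng.normal(size=(n_per_group, n_neurons))
    b = rng.normal(size=(n_per_group, n_neurons)) + sep * axis
    activity = np.vstack([a, b]).T             # (n_neurons, n_trials)
    labels = np.r_[np.zeros(n_per_group), np.ones(n_per_group)]
    return vc.build_pseudopopulation(activity, labels, min_trials=5, seed=seed)


class TestPseudoPopulation:
    def test_min_trial_filter_excludes_neuron(self):
        per_neuron = [
            {"a": np.ones(8), "b": np.ones(8)},
            {"a": np.ones(4), "b": np.ones(9)},   # 4 < 5 in group a
        ]
        pop = vc.build_pseudopopulation_pools(per_neuron, ["n0", "n1"],
                                              min_trials=5)
        assert pop.neuron_ids == ["n0"]
        assert pop.excluded == ["n1"]

    def test_no_survivor_raises(self):
        with pytest.raises(ValueError):
            vc.build_pseudopopulation_pools(
                [{"a": np.ones(2), "b": np.ones(2)}], min_trials=5)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            vc.build_pseudopopulation(np.ones((3, 10)), np.zeros(10))

    def test_matching_deterministic_and_sized(self):
        per_neuron = [{"a": np.arange(7.0), "b": np.arange(9.0)},
                      {"a": np.arange(5.0), "b": np.arange(12.0)}]
        pop = vc.build_pseudopopulation_pools(per_neuron, min_trials=5)
        m1, m2 = pop.sample(3), pop.sample(3)
        for g in ("a", "b"):
            assert np.array_equal(m1[g], m2[g])
        # group size equals the smallest per-neuron trial count in the group
        assert m1["a"].shape == (5, 2)
        assert m1["b"].shape == (9, 2)


class TestDecoders:
    def test_separable_groups_decode_perfectly(self):
        pop = gaussian_population(sep=10.0, seed=1)
        nn = vc.decode(pop, "nn", n_matchings=5, seed=0, n_shuffles=40)
        assert nn.mean_accuracy == 100.0
        assert nn.shuffle_p < 0.01
        svm = vc.decode(pop, "svm", n_matchings=5, seed=0, n_shuffles=40)
        assert svm.mean_accuracy >= 98.0  # regularized margin can concede a trial
        assert svm.shuffle_p < 0.01

    def test_null_groups_near_chance(self):
        ns = 0
        for s in range(10):
            pop = gaussian_population(sep=0.0, seed=100 + s)
            res = vc.decode(pop, "nn", n_matchings=20, seed=s, n_shuffles=60)
            ns += int(res.shuffle_p > 0.01)
        assert ns >= 8

    def test_accuracy_monotone_in_effect_size(self):
        accs = []
        for sep in (0.5, 1.0, 2.0):
            pop = gaussian_population(sep=sep, seed=7)
            accs.append(vc.decode(pop, "nn", n_matchings=30, seed=2,
                                  n_shuffles=0).mean_accuracy)
        assert accs[0] <= accs[1] <= accs[2]

    def test_nn_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(16, 6))
        y = rng.integers(0, 2, 16)
        got = _loo_nn(X, y)
        correct = 0
        for i in range(16):
            best, best_d = None, np.inf
            for j in range(16):
                if j == i:
                    continue
                d = float(np.sum((X[i] - X[j]) ** 2))
                if d < best_d:   # first index wins ties, as documented
                    best, best_d = j, d
            correct += int(y[best] == y[i])
        assert got == pytest.approx(100.0 * correct / 16)

    def test_leave_one_out_has_no_leakage(self):
        """A feature equal to the trial index carries no group information;
        a leaky split would let the classifier exploit it."""
        rng = np.random.default_rng(6)
        n = 40
        activity = np.vstack([np.arange(n, dtype=float),
                              rng.normal(size=n) * 0.01]).reshape(2, n)
        labels = rng.permutation(np.r_[np.zeros(n // 2), np.ones(n // 2)])
        pop = vc.build_pseudopopulation(activity, labels, min_trials=5, seed=0)
        res = vc.decode(pop, "svm", n_matchings=10, seed=1, n_shuffles=0)
        assert abs(res.mean_accuracy - 50.0) < 20.0

    def test_degenerate_group_raises(self):
        pop = vc.build_pseudopopulation(
            np.random.default_rng(0).normal(size=(3, 4)),
            np.array([0, 0, 0, 1]), min_trials=1)  # one trial in group 1
        with pytest.raises(ValueError):
            vc.decode(pop, "svm")

    def test_split8020_mode_runs(self):
        pop = gaussian_population(sep=6.0, seed=3)
        res = vc.decode(pop, "svm", n_matchings=8, seed=0, n_shuffles=0,
                        cv="split8020")
        assert res.mean_accuracy > 90.0


@pytest.fixture(scope="module")
def circuit_choice_setup(circuit_corpus, zscored_circuit, main_behavior):
    t = main_behavior.trials
    act = zscored_circuit.data["cue2"]
    seq_ab = (t["first_object"] == "A").to_numpy()
    view = t["view_choice"].to_numpy()
    obj = (t["chosen_object"] == "A").to_numpy().astype(int)
    return act, seq_ab, view, obj


class TestCrossConditionGeneralization:
    def test_view_choice_generalizes_across_sequences(self, circuit_choice_setup):
        act, seq_ab, view, _ = circuit_choice_setup
        tr = vc.build_pseudopopulation(act[:, seq_ab], view[seq_ab], min_trials=5)
        te = vc.build_pseudopopulation(act[:, ~seq_ab], view[~seq_ab], min_trials=5)
        within = vc.decode(tr, "svm", n_matchings=15, seed=0, n_shuffles=0)
        cross = vc.cross_condition_decode(tr, te, n_matchings=15, n_shuffles=40,
                                          seed=1)
        assert cross.mean_accuracy > 60.0
        assert cross.mean_accuracy > within.mean_accuracy - 25.0
        assert cross.shuffle_p < 0.01

    def test_object_choice_misclassified_without_recoding(self, circuit_choice_setup):
        act, seq_ab, _, obj = circuit_choice_setup
        tr = vc.build_pseudopopulation(act[:, seq_ab], obj[seq_ab], min_trials=5)
        te = vc.build_pseudopopulation(act[:, ~seq_ab], obj[~seq_ab], min_trials=5)
        plain = vc.cross_condition_decode(tr, te, n_matchings=15, n_shuffles=0,
                                          seed=2)
        recoded = vc.cross_condition_decode(tr, te, n_matchings=15, n_shuffles=0,
                                            seed=3, recode_rule="invert_by_sequence")
        assert plain.mean_accuracy < 40.0        # systematically inverted
        assert recoded.mean_accuracy > 60.0      # sequence knowledge recovers it

    def test_neuron_mismatch_raises(self, circuit_choice_setup):
        act, seq_ab, view, _ = circuit_choice_setup
        tr = vc.build_pseudopopulation(act[:, seq_ab], view[seq_ab], min_trials=5)
        te = vc.build_pseudopopulation(act[:2, ~seq_ab], view[~seq_ab], min_trials=5)
        with pytest.raises(ValueError):
            vc.cross_condition_decode(tr, te)


class TestConjunction:
    def _conjunction_pop(self, act, seq_ab, view):
        labels = np.array([f"{'AB' if s else 'BA'}-{'first' if v else 'second'}"
                           for s, v in zip(seq_ab, view)])
        return vc.build_pseudopopulation(act, labels, min_trials=5)

    def test_conjunction_classes_above_chance(self, circuit_choice_setup):
        act, seq_ab, view, _ = circuit_choice_setup
        pop = self._conjunction_pop(act, seq_ab, view)
        res = vc.conjunction_decode(pop, n_matchings=6, seed=0, n_shuffles=30)
        assert all(acc > 25.0 for acc in res.per_class.values())
        assert res.mean_accuracy > 40.0
        assert np.mean(res.shuffle_accuracies) == pytest.approx(25.0, abs=6.0)

    def test_pure_view_choice_population_confuses_sequence(self, main_behavior,
                                                           values):
        """Cells carrying only view choice cannot separate classes that differ
        in sequence but match in view choice."""
        pop_spec = {"view_choice_current": 0.5, "view_choice_last": 0.5}
        pop = vc.generate_population(pop_spec, 30, seed=41)
        rec = vc.generate_spike_counts(pop, main_behavior, "parametric",
                                       seed=42, values=values)
        zs = vc.zscore_epochs(rec)
        t = main_behavior.trials
        seq_ab = (t["first_object"] == "A").to_numpy()
        view = t["view_choice"].to_numpy()
        ppop = self._conjunction_pop(zs.data["cue2"], seq_ab, view)
        res = vc.conjunction_decode(ppop, n_matchings=6, seed=1, n_shuffles=0)
        conf = res.confusion
        groups = res.scheme["groups"]
        # off-diagonal mass concentrates on the view-matching, sequence-
        # differing partner class
        for g, partner in [(0, 2), (1, 3)]:
            assert groups[g].split("-")[1] == groups[partner].split("-")[1]
            off = [conf[g, h] for h in range(4) if h != g]
            assert conf[g, partner] == pytest.approx(max(off))

    def test_requires_four_groups(self, circuit_choice_setup):
        act, seq_ab, view, _ = circuit_choice_setup
        pop = vc.build_pseudopopulation(act, view, min_trials=5)
        with pytest.raises(ValueError):
            vc.conjunction_decode(pop)


class TestDifficultyAndSampleSize:
    def test_difficulty_terciles_ordered_on_circuit_corpus(
            self, circuit_choice_setup, values):
        act, _, view, _ = circuit_choice_setup
        dv = (values["v_first"] - values["v_second"]).to_numpy()
        table = vc.decode_by_difficulty(act, view, dv, method="svm",
                                        n_matchings=10, seed=0, n_shuffles=30)
        easy = table.loc[table.tercile == "easy", "accuracy"].iloc[0]
        hard = table.loc[table.tercile == "hard", "accuracy"].iloc[0]
        assert easy > hard
        assert (np.abs(table["n_trials"] - len(dv) / 3) <= 1).all()

    def test_difficulty_flat_for_difficulty_blind_signal(self, main_behavior,
                                                         values):
        pop = vc.generate_population({"view_choice_current": 1.0}, 25, seed=51)
        rec = vc.generate_spike_counts(pop, main_behavior, "parametric",
                                       seed=52, values=values)
        zs = vc.zscore_epochs(rec)
        view = main_behavior.trials["view_choice"].to_numpy()
        dv = (values["v_first"] - values["v_second"]).to_numpy()
        table = vc.decode_by_difficulty(zs.data["cue2"], view, dv, method="nn",
                                        n_matchings=25, seed=1, n_shuffles=0)
        spread = table["accuracy"].max() - table["accuracy"].min()
        assert spread < 12.0

    def test_sample_size_curve(self, circuit_choice_setup):
        act, _, view, _ = circuit_choice_setup
        pop = vc.build_pseudopopulation(act, view, min_trials=5)
        table = vc.accuracy_vs_samplesize(pop, sizes=[5, 20, pop.n_neurons],
                                          reps=12, method="nn", seed=0)
        accs = table["accuracy"].to_numpy()
        assert accs[0] <= accs[2] + 1.0
        full = vc.decode(pop, "nn", n_matchings=12, seed=5,
                         n_shuffles=0).mean_accuracy
        assert table["accuracy"].iloc[-1] == pytest.approx(full, abs=6.0)

    def test_sample_size_validation(self, circuit_choice_setup):
        act, _, view, _ = circuit_choice_setup
        pop = vc.build_pseudopopulation(act, view, min_trials=5)
        with pytest.raises(ValueError):
            vc.accuracy_vs_samplesize(pop, sizes=[0], reps=2)

    def test_null_corpus_flat_at_chance(self):
        rng = np.random.default_rng(9)
        activity = rng.normal(size=(30, 60))
        labels = np.r_[np.zeros(30), np.ones(30)]
        pop = vc.build_pseudopopulation(activity, labels, min_trials=5, seed=0)
        table = vc.accuracy_vs_samplesize(pop, sizes=[5, 15, 30], reps=15,
                                          method="nn", seed=1)
        assert (np.abs(table["accuracy"] - 50.0) < 15.0).all()


class TestNucleusDecoding:
    def test_planted_best_nucleus_wins(self, main_behavior, values):
        """Group-mean NN decoding over each nucleus' 20 strongest value cells
        identifies the nucleus with the planted high-fidelity value code."""
        rng = np.random.default_rng(60)
        neurons = []
        for i in range(100):
            nucleus = ("dLA", "vLA", "BL", "BM", "CE")[i % 5]
            gain = 18.0 if nucleus == "dLA" else 3.0
            neurons.append(vc.SyntheticNeuron(
                f"n{i:04d}", "view_value_pos", baseline_hz=5.0, gain_hz=gain,
                latency_ms=80.0, nucleus=nucleus))
        rec = vc.generate_spike_counts(neurons, main_behavior, seed=61,
                                       values=values)
        zs = vc.zscore_epochs(rec)
        v1 = values["v_first"].to_numpy()
        labels = np.where(v1 > np.median(v1), "high", "low")
        import pandas as pd

        coefs = np.array([
            vc.fit_glm(pd.DataFrame({"v": v1}),
                       zs.data["cue1"][k])["v"]["coef"]
            for k in range(len(zs.neuron_ids))
        ])
        kept = [neurons[i] for i in zs.kept_index]
        accs = {}
        for nucleus in ("dLA", "BL"):
            idx = [k for k, nr in enumerate(kept) if nr.nucleus == nucleus]
            top = sorted(idx, key=lambda k: -abs(coefs[k]))[:20]
            pop = vc.build_pseudopopulation(zs.data["cue1"][top], labels,
                                            min_trials=5, seed=0)
            accs[nucleus] = vc.decode(pop, "nn_mean", n_matchings=20, seed=1,
                                      n_shuffles=0).mean_accuracy
        assert accs["dLA"] > accs["BL"]
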