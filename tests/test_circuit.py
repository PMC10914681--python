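"""Decision-circuit dynamics: correctness of choices, integral-feedback
signatures, attractor structure, ablations, and the many-objects extension."""

import numpy as np
import pytest

import viewchoice as vc
from viewchoice.circuit import _standard_battery


def proto(va, vb, seq=("A", "B")):
    return vc.StimulusProtocol({"A": va, "B": vb}, seq)


@pytest.fixture(scope="module")
def battery_outcomes(quiet_params):
    out, traces = vc.simulate_trials(quiet_params, _standard_battery(), seed=0,
                                     record=True, record_every=8)
    return out, traces


class TestNoiseFreeDecisions:
    def test_higher_value_wins_both_orders(self, battery_outcomes):
        out, _ = battery_outcomes
        better = np.where(out["v_first"] > out["v_second"],
                          out["first_object"], out["second_object"])
        assert (out["object_choice"].to_numpy() == better).all()

    def test_view_choice_consistent_with_object_choice(self, battery_outcomes):
        out, _ = battery_outcomes
        # chosen-is-first  <=>  view choice 'first' (XOR-consistent routing)
        chose_first = out["object_choice"] == out["first_object"]
        assert (np.where(chose_first, "first", "second")
                == out["view_choice"].to_numpy()).all()

    def test_equal_values_undecided_at_zero_noise(self, quiet_params):
        tr = vc.simulate_trial(quiet_params, proto(0.5, 0.5), seed=0)
        assert tr.view_choice == "undecided"
        assert tr.object_choice == "undecided"
        c1 = tr.series["C1"]
        assert np.allclose(c1, tr.series["C2"], atol=1e-9)

    def test_switch_engages_during_second_cue(self, battery_outcomes):
        _, traces = battery_outcomes
        for tr in traces:
            assert tr.switch_engaged
            t_flip = tr.time_ms[np.argmax(tr.series["rE"] > 0.5)]
            c_on, c_off = tr.protocol.epoch("cue2")
            assert c_on < t_flip < c_off

    def test_deterministic_under_seed(self, quiet_params):
        a = vc.simulate_trial(quiet_params, proto(0.3, 0.7), seed=1)
        b = vc.simulate_trial(quiet_params, proto(0.3, 0.7), seed=1)
        assert np.array_equal(a.series["C1"], b.series["C1"])

    def test_value_inputs_validated(self):
        with pytest.raises(ValueError):
            vc.StimulusProtocol({"A": 1.2, "B": 0.5}, ("A", "B"))
        with pytest.raises(ValueError):
            vc.StimulusProtocol({"A": 0.5, "B": 0.5}, ("A", "A"))

    def test_blowup_raises_integration_error(self, quiet_params):
        from dataclasses import replace

        bad = replace(quiet_params, w_mm=80.0)  # runaway memory loop
        with pytest.raises(vc.IntegrationError):
            vc.simulate_trial(bad, proto(0.2, 0.8), seed=0)


class TestIntegralFeedback:
    def test_v2_value_tuning_reverses_between_cue_and_delay(self, quiet_params):
        """V2's rate rises with the first value during cue1 and falls with it
        during the delay - the integral-feedback signature."""
        vals = [0.2, 0.5, 0.8]
        cue1_means, delay_means = [], []
        for v in vals:
            tr = vc.simulate_trial(quiet_params, proto(v, 0.5), seed=0)
            cue1_means.append(tr.epoch_mean("V2", "cue1"))
            delay_means.append(tr.epoch_mean("V2", "delay1"))
        assert cue1_means[2] > cue1_means[1] > cue1_means[0]
        assert delay_means[2] < delay_means[1] < delay_means[0]

    def test_v2_cue2_encodes_value_difference(self, quiet_params):
        hi = vc.simulate_trial(quiet_params, proto(0.2, 0.8), seed=0)
        lo = vc.simulate_trial(quiet_params, proto(0.8, 0.2), seed=0)
        assert hi.epoch_mean("V2", "cue2") > lo.epoch_mean("V2", "cue2")

    def test_synaptic_efficacies_bounded(self, battery_outcomes):
        _, traces = battery_outcomes
        for tr in traces[:6]:
            for key in ("wA", "wB", "wA2", "wB2"):
                w = tr.series[key]
                assert w.min() > 0 and w.max() <= 1.0 + 1e-9
            wf = tr.series["wF"]
            assert wf.min() > 0 and wf.max() < 10.0

    def test_facilitation_rests_at_one(self, quiet_params):
        """Without stimuli the facilitation variable stays at its resting
        value of 1 (recovery equilibrium)."""
        pr = vc.StimulusProtocol({"A": 0.0, "B": 0.0}, ("A", "B"))
        tr = vc.simulate_trial(quiet_params, pr)
        settle = tr.series["wF"][tr.time_ms < 0]
        assert np.allclose(settle, 1.0, atol=1e-3)


class TestFineStepOracle:
    def test_choices_and_attractors_match_finer_dt(self, quiet_params):
        from dataclasses import replace

        fine = replace(quiet_params, dt=0.05)
        for va, vb, seq in [(0.2, 0.8, ("A", "B")), (0.8, 0.2, ("A", "B")),
                            (0.65, 0.35, ("B", "A"))]:
            a = vc.simulate_trial(quiet_params, proto(va, vb, seq), seed=0)
            b = vc.simulate_trial(fine, proto(va, vb, seq), seed=0)
            assert a.view_choice == b.view_choice
            assert a.object_choice == b.object_choice
            # latched end states agree to ~1e-3 despite the step-size change
            for key in ("C1", "C2", "CA", "CB", "M1", "M2"):
                assert a.series[key][-1] == pytest.approx(
                    b.series[key][-1], abs=2e-3)


class TestNoisyDecisions:
    def test_accuracy_monotone_in_value_difference(self):
        params = vc.NetworkParams()  # eta = 0.025
        accs = []
        for dv in (0.1, 0.2, 0.4):
            protos = [proto(0.5 - dv / 2, 0.5 + dv / 2,
                            ("A", "B") if i % 2 else ("B", "A"))
                      for i in range(48)]
            out, _ = vc.simulate_trials(params, protos, seed=7)
            accs.append((out["object_choice"] == "B").mean())
        assert accs[0] <= accs[1] <= accs[2]
        assert accs[0] > 0.6 and accs[2] > 0.95

    def test_decision_margin_when_switch_engaged(self):
        params = vc.NetworkParams()
        protos = [proto(0.45, 0.55, ("A", "B") if i % 2 else ("B", "A"))
                  for i in range(100)]
        out, _ = vc.simulate_trials(params, protos, seed=8)
        engaged = out["switch_engaged"]
        assert engaged.all()
        assert (out.loc[engaged, "margin_view"] > 0.2).mean() > 0.95

    def test_equal_values_split_at_chance(self):
        params = vc.NetworkParams()
        protos = [proto(0.5, 0.5) for _ in range(120)]
        out, _ = vc.simulate_trials(params, protos, seed=9)
        frac_a = (out["object_choice"] == "A").mean()
        assert abs(frac_a - 0.5) < 4 * np.sqrt(0.25 / 120)


class TestFixedPointStructure:
    def test_switch_saddle_node_counts(self, quiet_params):
        d = vc.switch_bifurcation(quiet_params, np.array([0.5, 1.5, 3.0]))
        assert d.counts(0) == (2, 1)   # bistable: low/high + saddle
        assert d.counts(1) == (2, 1)
        assert d.counts(2)[0] == 1     # beyond the knee: high state only

    def test_fixed_point_residuals(self, quiet_params):
        d = vc.switch_bifurcation(quiet_params, np.array([1.0]))
        sig = quiet_params.sigma
        for (rE, rI), _ in d.fixed_points[0]:
            fE = -rE + sig(quiet_params.w_ee * rE - quiet_params.w_ei * rI
                           + quiet_params.i_e + 1.0, quiet_params.alpha_e)
            fI = -rI + sig(quiet_params.w_ie * rE - quiet_params.w_ii * rI
                           + quiet_params.i_i, quiet_params.alpha_i)
            assert abs(fE) < 1e-8 and abs(fI) < 1e-8

    def test_decision_regime_map(self, quiet_params):
        table = vc.decision_regime(quiet_params, np.array([-2.0, -0.6, 0.0]))
        assert table.loc[0, "regime"] == "non_competing"
        assert table.loc[1, "regime"] == "winner_take_all"
        assert table.loc[2, "regime"] == "winner_take_all"
        assert table.loc[1, "n_fixed"] == 3 and table.loc[1, "n_stable"] == 2

    def test_regime_symmetric_under_label_swap(self, quiet_params):
        """The symmetric pair's attractors come in mirrored (a,b)/(b,a) pairs."""
        from viewchoice.circuit import _fixed_points_2d

        sig = quiet_params.sigma
        i0 = -0.6

        def F(x):
            c1, c2 = x
            return np.array([
                -c1 + sig(quiet_params.w_plus * c1 - quiet_params.w_minus * c2 + i0),
                -c2 + sig(quiet_params.w_plus * c2 - quiet_params.w_minus * c1 + i0),
            ])

        def J(x):
            c1, c2 = x
            s1 = sig(quiet_params.w_plus * c1 - quiet_params.w_minus * c2 + i0)
            s2 = sig(quiet_params.w_plus * c2 - quiet_params.w_minus * c1 + i0)
            d1, d2 = s1 * (1 - s1), s2 * (1 - s2)
            return np.array([[-1 + quiet_params.w_plus * d1, -quiet_params.w_minus * d1],
                             [-quiet_params.w_minus * d2, -1 + quiet_params.w_plus * d2]])

        grid = np.linspace(0, 1, 13)
        pts = _fixed_points_2d(F, J, [np.array([a, b]) for a in grid for b in grid])
        stable = [p for p, s in pts if s]
        for p in stable:
            assert any(np.allclose(p[::-1], q, atol=1e-6) for q in stable)


class TestAblations:
    def test_no_switch_never_decides(self):
        rep = vc.run_ablation("no_switch", seed=0)
        assert rep.verdict["ever_decides"] is False

    def test_object_specific_view_always_second(self):
        rep = vc.run_ablation("object_specific_view", seed=0)
        assert rep.verdict["always_second"] is True

    def test_positive_tuned_selects_higher_value_but_not_many_objects(self):
        rep = vc.run_ablation("positive_tuned_wMC08", seed=0)
        assert rep.verdict["fraction_correct"] >= 0.9
        assert rep.verdict["many_objects_capable"] is False

    def test_classical_simultaneous_selects_higher_value(self):
        rep = vc.run_ablation("classical_simultaneous", seed=0)
        assert rep.verdict["selects_higher_value"] is True
        assert rep.verdict["many_objects_capable"] is False

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            vc.run_ablation("lesion_everything")


class TestManyObjects:
    def test_max_value_member_wins_every_ordered_pair(self, quiet_params):
        vals = [0.2, 0.4, 0.6, 0.8]
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                res = vc.simulate_many_objects(quiet_params, vals, (i, j), (i, j),
                                               seed=0)
                want = i if vals[i] > vals[j] else j
                assert res["chosen_id"] == want, (i, j, res)

    def test_view_choice_unit_generalizes_across_objects(self, quiet_params):
        """C2 wins whenever the second-viewed option has the higher value,
        for pairs drawn from different parts of the object set."""
        vals = [0.2, 0.4, 0.6, 0.8]
        for pair in [(0, 3), (1, 2), (0, 2), (1, 3)]:
            res = vc.simulate_many_objects(quiet_params, vals, pair, pair, seed=0)
            assert res["view_choice"] == "second"  # ascending value order

    def test_equal_value_pair_splits_at_chance(self):
        params = vc.NetworkParams()
        names = ["O0", "O1", "O2"]
        protos = [vc.StimulusProtocol({"O0": 0.5, "O1": 0.5, "O2": 0.2},
                                      ("O0", "O1")) for _ in range(120)]
        out, _ = vc.simulate_trials(params, protos, seed=5)
        frac = (out["object_choice"] == "O0").mean()
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / 120)

    def test_pair_validation(self, quiet_params):
        with pytest.raises(ValueError):
            vc.simulate_many_objects(quiet_params, [0.5, 0.6], (0, 5), (0, 5))
        with pytest.raises(ValueError):
            vc.simulate_many_objects(quiet_params, [0.5, 0.6], (0, 1), (0, 2))
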