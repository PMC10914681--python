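import numpy as np
import pytest

import viewchoice as vc


@pytest.fixture(scope="session")
def main_behavior():
    """One main-task session: 150 trials, reversal agent with magnitude use."""
    sched = vc.generate_schedule("main", 150, seed=11)
    return vc.simulate_agent(
        sched, vc.RLParams(variant="reversal", alpha=0.3, beta=3.0, mag_weight=1.0),
        seed=12)


@pytest.fixture(scope="session")
def values(main_behavior):
    return vc.session_values(main_behavior)


@pytest.fixture(scope="session")
def parametric_recording(main_behavior, values):
    """Default-mixture population with parametric tuning, 60 neurons."""
    pop = vc.generate_population(n_neurons=60, seed=13)
    rec = vc.generate_spike_counts(pop, main_behavior, "parametric", seed=14,
                                   values=values)
    return pop, rec


#: functional mixture for circuit-driven corpora (view-based machinery heavy)
CIRCUIT_SPEC = {
    "object_value_A": 0.08, "object_value_B": 0.08,
    "view_value_pos": 0.14, "view_value_neg": 0.12,
    "view_choice_current": 0.16, "view_choice_last": 0.12,
    "object_choice": 0.10, "object_sequence": 0.08,
    "combination": 0.08, "untuned": 0.04,
}


@pytest.fixture(scope="session")
def circuit_corpus(main_behavior, values):
    """45 neurons whose rates follow the decision-circuit populations."""
    pop = vc.generate_population(CIRCUIT_SPEC, n_neurons=45, seed=21)
    rec = vc.generate_spike_counts(pop, main_behavior, "circuit", seed=22,
                                   values=values)
    return pop, rec


@pytest.fixture(scope="session")
def zscored_circuit(circuit_corpus):
    _, rec = circuit_corpus
    return vc.zscore_epochs(rec)


@pytest.fixture(scope="session")
def quiet_params():
    return vc.NetworkParams(eta=0.0)


def type_to_category(ftype: str) -> str:
    """Planted functional type -> expected angle-classification category."""
    return {
        "object_value_A": "object_value_A",
        "object_value_B": "object_value_B",
        "view_value_pos": "view_value_positive",
        "view_value_neg": "view_value_positive",
    }[ftype]
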