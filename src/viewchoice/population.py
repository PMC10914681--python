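"""Synthetic neuron populations with the functional cell types observed in
amygdala during sequential-viewing choice: object-value cells (graded value
signal for one specific object), view-based value cells (graded signal for
whichever object is currently viewed, positive or negative tuning),
view-based choice cells (categorical signal for choosing the currently- vs
last-viewed object), object-choice cells, object-sequence cells, combination
(conjunction) cells, and untuned cells, tagged with amygdala nucleus labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import ConfigurationError

FUNCTIONAL_TYPES = (
    "object_value_A",
    "object_value_B",
    "view_value_pos",
    "view_value_neg",
    "view_choice_current",
    "view_choice_last",
    "object_choice",
    "object_sequence",
    "combination",
    "untuned",
)

NUCLEI = ("dLA", "vLA", "BL", "BM", "CE")

#: base nucleus probabilities, proportional to recorded sample sizes
_NUCLEUS_P = {"dLA": 0.223, "vLA": 0.176, "BL": 0.403, "BM": 0.073, "CE": 0.125}

#: default functional-type mixture for a main-task population
DEFAULT_POP_SPEC = {
    "object_value_A": 0.10,
    "object_value_B": 0.11,
    "view_value_pos": 0.15,
    "view_value_neg": 0.15,
    "view_choice_current": 0.13,
    "view_choice_last": 0.13,
    "object_choice": 0.08,
    "object_sequence": 0.05,
    "combination": 0.05,
    "untuned": 0.05,
}


@dataclass
class SyntheticNeuron:
    """One synthetic unit: functional type plus rate parametrization.

    ``baseline_hz`` is the resting rate, ``gain_hz`` the modulation per value
    unit (value scaled to [0, 1]) or per choice contrast, ``latency_ms`` the
    response lag after the driving event.  ``pref`` disambiguates within-type
    preferences (object id, view-choice target, preferred sequence, or the
    (sequence, view-choice) conjunction for combination cells).
    """

    neuron_id: str
    functional_type: str
    baseline_hz: float
    gain_hz: float
    latency_ms: float
    nucleus: str
    pref: tuple = ()
    #: phasic response duration; None means the modulation spans its whole epoch
    duration_ms: float | None = None

    def __post_init__(self) -> None:
        if self.functional_type not in FUNCTIONAL_TYPES:
            raise ConfigurationError(f"unknown functional type {self.functional_type!r}")
        if self.baseline_hz < 0:
            raise ConfigurationError("baseline rate must be >= 0")
        if self.nucleus not in NUCLEI:
            raise ConfigurationError(f"unknown nucleus {self.nucleus!r}")


def _nucleus_probs(ftype: str) -> np.ndarray:
    """Mild anatomical topography: object-value cells concentrate dorsally in
    the lateral nucleus, view-based cells in the basolateral nucleus."""
    p = dict(_NUCLEUS_P)
    if ftype.startswith("object_value"):
        p["dLA"] *= 2.5
    elif ftype.startswith(("view_value", "view_choice", "combination")):
        p["BL"] *= 2.0
    arr = np.array([p[n] for n in NUCLEI])
    return arr / arr.sum()


def generate_population(pop_spec: dict[str, float] | None = None,
                        n_neurons: int = 233, seed: int = 0,
                        baseline_median_hz: float = 5.0,
                        baseline_sigma: float = 0.6,
                        gain_median_hz: float = 8.0,
                        gain_sigma: float = 0.4) -> list[SyntheticNeuron]:
    """Draw a population; type counts are multinomial with the spec proportions.

    Baselines and gains are log-normal across neurons (the field's usual
    heavy-tailed rate distribution); latencies uniform in 50-150 ms and
    phasic response durations uniform in 250-500 ms (cue-evoked responses
    are transient rather than epoch-filling).  Deterministic under ``seed``.
    """
    spec = dict(DEFAULT_POP_SPEC if pop_spec is None else pop_spec)
    for t, frac in spec.items():
        if t not in FUNCTIONAL_TYPES:
            raise ConfigurationError(f"unknown functional type {t!r}")
        if frac < 0:
            raise ConfigurationError("proportions must be >= 0")
    total = sum(spec.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ConfigurationError(f"proportions must sum to 1 (got {total})")
    rng = np.random.default_rng(seed)
    types = list(spec)
    counts = rng.multinomial(n_neurons, [spec[t] for t in types])

    neurons: list[SyntheticNeuron] = []
    i = 0
    for ftype, cnt in zip(types, counts):
        for _ in range(cnt):
            if ftype == "object_value_A":
                pref = ("A",)
            elif ftype == "object_value_B":
                pref = ("B",)
            elif ftype == "object_choice":
                pref = (str(rng.choice(["A", "B"])),)
            elif ftype == "object_sequence":
                pref = (str(rng.choice(["A", "B"])),)  # preferred first object
            elif ftype == "combination":
                pref = (str(rng.choice(["A", "B"])), str(rng.choice(["first", "second"])))
            else:
                pref = ()
            neurons.append(
                SyntheticNeuron(
                    neuron_id=f"n{i:04d}",
                    functional_type=ftype,
                    baseline_hz=float(rng.lognormal(np.log(baseline_median_hz),
                                                    baseline_sigma)),
                    gain_hz=float(rng.lognormal(np.log(gain_median_hz), gain_sigma)),
                    latency_ms=float(rng.uniform(50.0, 150.0)),
                    nucleus=str(rng.choice(NUCLEI, p=_nucleus_probs(ftype))),
                    pref=pref,
                    duration_ms=float(rng.uniform(250.0, 500.0)),
                )
            )
            i += 1
    return neurons
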