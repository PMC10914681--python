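"""Binned spike-count generation for synthetic sessions.

Rates can come from a parametric tuning model (each neuron's functional type
defines an epoch-locked, latency-shifted modulation of its baseline) or from
the decision-circuit populations (each neuron's rate tracks a model
population's trial trace).  Emission is Poisson per 20-ms bin; fixed task
epochs are exact sums of the bins they cover, so fixed-window and
sliding-window analyses see consistent counts.

Trial timeline (ms relative to first-cue onset): pre-fixation control
[-1000, -500), fixation [-500, 0), cue1 [0, 500), delay1 [500, 1000),
cue2 [1000, 1500), delay2 [1500, 2000), targets [2000, 2500).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import NetworkParams, StimulusProtocol, simulate_trials
from .population import SyntheticNeuron
from .rl import ObjectValueModel, fit_session_logistic
from .task import SessionBehavior

BIN_MS = 20.0
GRID_START_MS = -1000.0
GRID_END_MS = 2500.0

EPOCHS = {
    "control": (-1000.0, -500.0),
    "fixation": (-500.0, 0.0),
    "cue1": (0.0, 500.0),
    "delay1": (500.0, 1000.0),
    "cue2": (1000.0, 1500.0),
    "delay2": (1500.0, 2000.0),
    "targets": (2000.0, 2500.0),
}


@dataclass
class RecordingSet:
    """Per-neuron, per-trial binned spike counts with epoch sums.

    ``bins`` has shape (n_neurons, n_trials, n_bins) on a shared 20-ms grid;
    ``epochs`` maps epoch name to an (n_neurons, n_trials) integer array that
    equals the sum of the bins inside the epoch window (half-open).
    """

    neurons: list[SyntheticNeuron]
    behavior: SessionBehavior
    bin_edges_ms: np.ndarray
    bins: np.ndarray
    epochs: dict[str, np.ndarray]
    clipped_rate_bins: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_trials(self) -> int:
        return self.bins.shape[1]

    def epoch_rate_hz(self, epoch: str) -> np.ndarray:
        t0, t1 = EPOCHS[epoch]
        return self.epochs[epoch] / ((t1 - t0) / 1000.0)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("bins", data=self.bins, compression="gzip")
            f.create_dataset("bin_edges_ms", data=self.bin_edges_ms)
            for name, arr in self.epochs.items():
                f.create_dataset(f"epochs/{name}", data=arr)
            ntab = f.create_group("neurons")
            for attr in ("neuron_id", "functional_type", "nucleus"):
                ntab.create_dataset(
                    attr, data=np.array([getattr(nr, attr) for nr in self.neurons],
                                        dtype="S32"))
            for attr in ("baseline_hz", "gain_hz", "latency_ms"):
                ntab.create_dataset(
                    attr, data=np.array([getattr(nr, attr) for nr in self.neurons]))

    def epochs_to_csv(self, path) -> None:
        frames = []
        for name, arr in self.epochs.items():
            df = pd.DataFrame(arr,
                              index=[nr.neuron_id for nr in self.neurons]).reset_index(
                names="neuron_id")
            df = df.melt(id_vars="neuron_id", var_name="trial", value_name="count")
            df["epoch"] = name
            frames.append(df)
        pd.concat(frames).to_csv(path, index=False)


def session_values(behavior: SessionBehavior,
                   value_model: ObjectValueModel | None = None) -> pd.DataFrame:
    """Per-trial object values on a [0, 1] scale.

    Values combine cued magnitude and block probability with the session's
    fitted logistic weights, then are affinely mapped to [0, 1] using the
    session min/max (the circuit's admissible input range).  Also returns the
    magnitude-only value component (``*_mag``) on the same kind of scale,
    used by analyses that must avoid the built-in anti-correlation of
    learned values.
    """
    t = behavior.trials
    variant = behavior.schedule.task_variant
    if variant == "four_objects":
        # probability-only values; the active pair's probabilities are in the
        # first/second columns, independent of which object set is on
        raw = np.stack([t["first_prob"].to_numpy(float),
                        t["second_prob"].to_numpy(float)])
        lo, span = raw.min(), max(raw.max() - raw.min(), 1e-12)
        vf, vs = (raw - lo) / span
        first_is_a = t["first_object"].isin(["A", "C"]).to_numpy()
        return pd.DataFrame(
            {"value_A": np.where(first_is_a, vf, vs),
             "value_B": np.where(first_is_a, vs, vf),
             "v_first": vf, "v_second": vs,
             "value_A_mag": np.where(first_is_a, vf, vs),
             "value_B_mag": np.where(first_is_a, vs, vf),
             "v_first_mag": vf, "v_second_mag": vs},
            index=t.index,
        )
    if value_model is None:
        value_model = fit_session_logistic(behavior)
    raw_a = value_model.value(t["mag_A"], t["prob_A"])
    raw_b = value_model.value(t["mag_B"], t["prob_B"])
    allv = np.concatenate([raw_a, raw_b])
    lo, hi = allv.min(), allv.max()
    span = hi - lo if hi > lo else 1.0
    va = (raw_a - lo) / span
    vb = (raw_b - lo) / span
    mags = np.concatenate([t["mag_A"], t["mag_B"]])
    mlo, mspan = mags.min(), max(mags.max() - mags.min(), 1e-12)
    ma = (t["mag_A"] - mlo) / mspan
    mb = (t["mag_B"] - mlo) / mspan
    first_is_a = (t["first_object"] == "A").to_numpy()
    out = pd.DataFrame(
        {
            "value_A": va,
            "value_B": vb,
            "v_first": np.where(first_is_a, va, vb),
            "v_second": np.where(first_is_a, vb, va),
            "value_A_mag": ma,
            "value_B_mag": mb,
            "v_first_mag": np.where(first_is_a, ma, mb),
            "v_second_mag": np.where(first_is_a, mb, ma),
        },
        index=t.index,
    )
    return out


def _bin_centers(edges: np.ndarray) -> np.ndarray:
    return (edges[:-1] + edges[1:]) / 2.0


def _parametric_rates(neuron: SyntheticNeuron, behavior: SessionBehavior,
                      values: pd.DataFrame, centers: np.ndarray) -> np.ndarray:
    """(n_trials, n_bins) firing rate in Hz for one neuron."""
    t = behavior.trials
    n = len(t)
    rate = np.full((n, centers.size), neuron.baseline_hz)
    lat = neuron.latency_ms
    g = neuron.gain_hz
    ft = neuron.functional_type

    dur = neuron.duration_ms

    def window(t0, t1):
        # phasic response: starts at latency, lasts duration_ms (or fills the
        # driving span when no duration is set)
        end = t1 + lat if dur is None else min(t0 + lat + dur, t1 + lat)
        return (centers >= t0 + lat) & (centers < end)

    cue1 = window(0, 500)
    cue2 = window(1000, 1500)
    cue2_delay2 = window(1000, 2000)
    targets = window(2000, 2500)

    first_obj = t["first_object"].to_numpy()
    chosen = t["chosen_object"].to_numpy()
    view_choice_first = t["view_choice"].to_numpy().astype(bool)

    if ft in ("object_value_A", "object_value_B"):
        obj = ft[-1]
        v = values[f"value_{obj}"].to_numpy()
        shown_first = first_obj == obj
        rate[shown_first[:, None] & cue1[None, :]] += np.repeat(
            g * v[shown_first], cue1.sum())
        rate[~shown_first[:, None] & cue2[None, :]] += np.repeat(
            g * v[~shown_first], cue2.sum())
    elif ft == "view_value_pos":
        rate[:, cue1] += g * values["v_first"].to_numpy()[:, None]
        rate[:, cue2] += g * values["v_second"].to_numpy()[:, None]
    elif ft == "view_value_neg":
        rate[:, cue1] += g * (1.0 - values["v_first"].to_numpy()[:, None])
        rate[:, cue2] += g * (1.0 - values["v_second"].to_numpy()[:, None])
    elif ft == "view_choice_current":
        on = ~view_choice_first  # second-viewed (current at cue2) chosen
        rate[on[:, None] & cue2_delay2[None, :]] += g
    elif ft == "view_choice_last":
        on = view_choice_first
        rate[on[:, None] & cue2_delay2[None, :]] += g
    elif ft == "object_choice":
        on = chosen == neuron.pref[0]
        rate[on[:, None] & targets[None, :]] += g
    elif ft == "object_sequence":
        on = first_obj == neuron.pref[0]
        rate[on[:, None] & cue2[None, :]] += g
    elif ft == "combination":
        obj, vc = neuron.pref
        chose_second = ~view_choice_first
        seq_on = first_obj == obj
        vc_on = chose_second if vc == "second" else ~chose_second
        on = seq_on & vc_on
        rate[on[:, None] & cue2_delay2[None, :]] += g
    # untuned: baseline only
    return rate


# mapping from functional type to circuit population trace
_CIRCUIT_SOURCE = {
    "view_value_pos": "V2",
    "view_value_neg": "V1",
    "view_choice_current": "C2",
    "view_choice_last": "C1",
}


def _circuit_rates(neuron: SyntheticNeuron, traces, behavior: SessionBehavior,
                   values: pd.DataFrame, centers: np.ndarray) -> np.ndarray:
    """(n_trials, n_bins) rates driven by the model populations.

    Outside the simulated span the trace is clamped to its endpoint values,
    so the latched choice attractors extend into the targets epoch and the
    pre-trial grid sees resting activity.
    """
    n = len(traces)
    rate = np.full((n, centers.size), neuron.baseline_hz)
    g = neuron.gain_hz
    ft = neuron.functional_type
    first_obj = behavior.trials["first_object"].to_numpy()

    for j, tr in enumerate(traces):
        if ft in _CIRCUIT_SOURCE:
            key = _CIRCUIT_SOURCE[ft]
        elif ft in ("object_value_A", "object_value_B"):
            obj = ft[-1]
            # graded object drive: object-selective input scaled by its value
            key = f"r{obj}"
        elif ft == "object_choice":
            key = f"C{neuron.pref[0]}"
        elif ft == "object_sequence":
            key = f"{neuron.pref[0]}1"
        elif ft == "combination":
            obj, vc = neuron.pref
            key = f"C{obj}1" if vc == "first" else f"C{obj}2"
        else:  # untuned
            continue
        src = np.interp(centers - neuron.latency_ms, tr.time_ms, tr.series[key])
        if ft in ("object_value_A", "object_value_B"):
            src = src * values[f"value_{ft[-1]}"].iloc[j]
        rate[j] += g * src
    return rate


def generate_spike_counts(population: list[SyntheticNeuron],
                          behavior: SessionBehavior,
                          rate_source: str = "parametric",
                          seed: int = 0,
                          values: pd.DataFrame | None = None,
                          circuit_params: NetworkParams | None = None) -> RecordingSet:
    """Poisson spike counts on the 20-ms grid for every neuron and trial.

    ``rate_source`` is ``"parametric"`` (type/gain/latency tuning model) or
    ``"circuit"`` (per-trial rates follow decision-circuit population
    traces).  Negative rates after tuning are clipped at zero and counted in
    ``clipped_rate_bins``.
    """
    if not population or behavior.n_trials == 0:
        raise ValueError("population and behavior must be nonempty")
    if rate_source not in ("parametric", "circuit"):
        raise ValueError(f"unknown rate_source {rate_source!r}")
    edges = np.arange(GRID_START_MS, GRID_END_MS + BIN_MS / 2, BIN_MS)
    centers = _bin_centers(edges)
    if values is None:
        values = session_values(behavior)
    rng = np.random.default_rng(seed)

    traces = None
    if rate_source == "circuit":
        params = circuit_params or NetworkParams()
        protos = []
        for j in range(behavior.n_trials):
            row = behavior.trials.iloc[j]
            protos.append(
                StimulusProtocol(
                    {"A": float(values["value_A"].iloc[j]),
                     "B": float(values["value_B"].iloc[j])},
                    (row["first_object"], row["second_object"]),
                )
            )
        _, traces = simulate_trials(params, protos, seed=seed + 1, record=True,
                                    record_every=int(BIN_MS / params.dt))

    n_neurons, n_trials, n_bins = len(population), behavior.n_trials, centers.size
    bins = np.empty((n_neurons, n_trials, n_bins), dtype=np.int64)
    clipped = 0
    for i, neuron in enumerate(population):
        if rate_source == "parametric":
            rate = _parametric_rates(neuron, behavior, values, centers)
        else:
            rate = _circuit_rates(neuron, traces, behavior, values, centers)
        neg = rate < 0
        clipped += int(neg.sum())
        rate = np.maximum(rate, 0.0)
        bins[i] = rng.poisson(rate * (BIN_MS / 1000.0))

    epochs = {}
    for name, (t0, t1) in EPOCHS.items():
        m = (centers >= t0) & (centers < t1)
        epochs[name] = bins[:, :, m].sum(axis=2)
    return RecordingSet(
        neurons=population,
        behavior=behavior,
        bin_edges_ms=edges,
        bins=bins,
        epochs=epochs,
        clipped_rate_bins=clipped,
        meta={"rate_source": rate_source, "seed": seed},
    )
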