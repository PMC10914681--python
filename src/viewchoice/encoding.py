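"""Single-neuron encoding statistics.

Covers the angle-based classification of value responses (object value vs
view-based value from the polar angle of the two standardized object-value
coefficients), sliding-window regression with a permutation-calibrated
consecutive-window significance criterion, value-to-choice transition
detection, the tuning-reversal test between cues (the integral-feedback
signature), and the across-neuron anti-correlation of first- vs
second-option value coefficients (the value-comparison signature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .glm import fit_glm
from .spikes import BIN_MS, GRID_START_MS, RecordingSet

# ---------------------------------------------------------------------------
# angle classification

CATEGORY_BY_SEGMENT = (
    "object_value_A",      # 0 deg: loads on object-A value only
    "view_value_positive",  # 45 deg: same-sign loading on both values
    "object_value_B",      # 90 deg
    "view_value_negative",  # 135 deg: opposite-sign loading
    "object_value_A",      # 180 deg
    "view_value_positive",  # 225 deg
    "object_value_B",      # 270 deg
    "view_value_negative",  # 315 deg
)


@dataclass
class ValueCellClass:
    angle_deg: float | None
    category: str
    gate_p: float
    beta_A: float
    beta_B: float


def classify_value_neuron(cue_response: np.ndarray, value_A: np.ndarray,
                          value_B: np.ndarray, first_object=None,
                          alpha: float = 0.05) -> ValueCellClass:
    """Classify a first-cue response by the angle of its value coefficients.

    With ``first_object`` labels, each object's coefficient comes from the
    response to that object when viewed first (its own trials); otherwise a
    joint regression on both values is used.  Neurons failing the overall
    F gate (either object's fit when split, the joint fit otherwise) are
    unclassified.  The standardized-coefficient plane splits into eight
    half-open 45-degree segments: 0/180 degrees = object-A value, 90/270 =
    object-B value, 45/225 = view-based value with uniform sign, 135/315 =
    view-based with opposing sign.  Exact boundary angles go to the
    counter-clockwise segment.
    """
    import pandas as pd

    y = np.asarray(cue_response, float)
    if first_object is not None:
        first_object = np.asarray(first_object)
        sel_a = first_object == "A"
        res_a = fit_glm(pd.DataFrame({"value": np.asarray(value_A)[sel_a]}), y[sel_a])
        res_b = fit_glm(pd.DataFrame({"value": np.asarray(value_B)[~sel_a]}), y[~sel_a])
        ba, bb = res_a["value"]["beta_std"], res_b["value"]["beta_std"]
        gate_p = min(res_a.f_p, res_b.f_p)
    else:
        res = fit_glm(pd.DataFrame({"value_A": value_A, "value_B": value_B}),
                      cue_response)
        ba, bb = res["value_A"]["beta_std"], res["value_B"]["beta_std"]
        gate_p = res.f_p
    if gate_p >= alpha or (ba == 0.0 and bb == 0.0):
        return ValueCellClass(None, "unclassified", gate_p, ba, bb)
    angle = math.degrees(math.atan2(bb, ba)) % 360.0
    if angle >= 360.0 - 1e-9:  # floating-point wrap of ~0 degrees
        angle = 0.0
    segment = int(((angle + 22.5) % 360.0) // 45.0)
    return ValueCellClass(angle, CATEGORY_BY_SEGMENT[segment], gate_p, ba, bb)


# ---------------------------------------------------------------------------
# sliding-window regression

@dataclass
class SlidingSeries:
    """Per-window regression series for one neuron.

    ``coef``/``t``/``p``/``partial_r2`` are (n_regressors, n_windows) arrays
    (row order in ``names``; intercept excluded).  The significance verdict
    is a run of more than ``run_threshold`` consecutive windows with
    p < alpha for the target regressor.
    """

    window_centers_ms: np.ndarray
    names: list[str]
    coef: np.ndarray
    t: np.ndarray
    p: np.ndarray
    partial_r2: np.ndarray
    target: str
    alpha: float
    run_threshold: int
    max_run: int
    significant: bool
    shuffle_max_runs: np.ndarray | None = None
    calibrated_threshold: int | None = None
    skipped_windows: list[int] = field(default_factory=list)

    def series(self, name: str, which: str = "coef") -> np.ndarray:
        return getattr(self, which)[self.names.index(name)]

    def run_onset_ms(self, window: tuple[float, float] | None = None,
                     name: str | None = None) -> float | None:
        """Center time of the first window of the first qualifying run
        (optionally restricted to windows inside ``window``)."""
        name = name or self.target
        sig = self.p[self.names.index(name)] < self.alpha
        centers = self.window_centers_ms
        if window is not None:
            inside = (centers >= window[0]) & (centers <= window[1])
        else:
            inside = np.ones_like(sig, dtype=bool)
        run = 0
        start = None
        for i, s in enumerate(sig & inside):
            if s:
                run += 1
                if run == 1:
                    start = i
                if run > self.run_threshold:
                    return float(centers[start])
            else:
                run = 0
        return None


def _max_run(mask: np.ndarray) -> int:
    best = run = 0
    for s in mask:
        run = run + 1 if s else 0
        best = max(best, run)
    return best


def _window_matrix(bins: np.ndarray, window_ms: float, step_ms: float,
                   span: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """(n_trials, n_windows) summed counts and window centers."""
    n_per = int(round(window_ms / BIN_MS))
    starts = np.arange(span[0], span[1] - window_ms + step_ms / 2, step_ms)
    idx0 = np.round((starts - GRID_START_MS) / BIN_MS).astype(int)
    csum = np.concatenate(
        [np.zeros((bins.shape[0], 1)), np.cumsum(bins, axis=1)], axis=1)
    Y = np.stack([csum[:, i + n_per] - csum[:, i] for i in idx0], axis=1)
    centers = starts + window_ms / 2.0
    return Y, centers


def sliding_regression(recording: RecordingSet, design, target: str,
                       neuron: int = 0, window_ms: float = 200.0,
                       step_ms: float = 20.0,
                       span: tuple[float, float] = (-500.0, 2500.0),
                       alpha: float = 0.05, run_threshold: int = 9,
                       n_shuffles: int = 0, seed: int = 0) -> SlidingSeries:
    """Sliding 200-ms/20-ms regression of one neuron's counts on a design.

    Every window is fit by OLS (batched across windows); the neuron is
    called significant for ``target`` if more than ``run_threshold``
    consecutive windows reach p < alpha.  With ``n_shuffles`` > 0 the run
    criterion is re-calibrated from trial-shuffled data: the reported
    ``calibrated_threshold`` is the smallest run length that fewer than 5%
    of shuffles exceed.
    """
    import pandas as pd

    X0 = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    names = list(design.columns) if isinstance(design, pd.DataFrame) else [
        f"x{i}" for i in range(X0.shape[1])]
    bins = recording.bins[neuron].astype(float)
    Y, centers = _window_matrix(bins, window_ms, step_ms, span)

    X = np.column_stack([np.ones(len(X0)), X0])
    n, p = X.shape
    dof = n - p
    pinv = np.linalg.pinv(X)
    XtX_inv_diag = np.diag(np.linalg.inv(X.T @ X))

    def fit_all(Yw):
        B = pinv @ Yw                     # (p, n_windows)
        R = Yw - X @ B
        sse = np.sum(R * R, axis=0)       # (n_windows,)
        se = np.sqrt(np.maximum(XtX_inv_diag[:, None] * sse[None, :] / dof, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            T = np.where(se > 0, B / se, 0.0)
        P = 2 * stats.t.sf(np.abs(T), dof)
        return B, T, P, sse

    B, T, P, sse = fit_all(Y)

    # partial R^2 per regressor (excluding intercept)
    pr2 = np.zeros((p - 1, Y.shape[1]))
    for j in range(1, p):
        Xr = np.delete(X, j, axis=1)
        Br = np.linalg.pinv(Xr) @ Y
        sse_r = np.sum((Y - Xr @ Br) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            pr2[j - 1] = np.where(sse_r > 0, (sse_r - sse) / sse_r, 0.0)

    ti = names.index(target)
    sig = P[ti + 1] < alpha
    max_run = _max_run(sig)

    shuffle_runs = None
    calibrated = None
    if n_shuffles > 0:
        rng = np.random.default_rng(seed)
        runs = np.empty(n_shuffles, dtype=int)
        for s in range(n_shuffles):
            perm = rng.permutation(n)
            _, _, Ps, _ = fit_all(Y[perm])
            runs[s] = _max_run(Ps[ti + 1] < alpha)
        shuffle_runs = runs
        # smallest threshold L such that < 5% of shuffles have run > L
        for L in range(0, int(runs.max()) + 2):
            if (runs > L).mean() < 0.05:
                calibrated = L
                break

    return SlidingSeries(
        window_centers_ms=centers,
        names=names,
        coef=B[1:], t=T[1:], p=P[1:], partial_r2=pr2,
        target=target, alpha=alpha, run_threshold=run_threshold,
        max_run=max_run, significant=max_run > run_threshold,
        shuffle_max_runs=shuffle_runs, calibrated_threshold=calibrated,
    )


def shuffled_pass_rate(recording: RecordingSet, design, target: str,
                       neurons: list[int] | None = None,
                       run_threshold: int = 9, seed: int = 0,
                       **kwargs) -> float:
    """Fraction of trial-shuffled neurons passing the consecutive-window
    criterion - the empirical false-positive rate of the verdict."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    idx = neurons if neurons is not None else list(range(recording.n_neurons))
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    names = list(design.columns)
    passed = 0
    for i in idx:
        perm = rng.permutation(X.shape[0])
        shuffled = pd.DataFrame(X[perm], columns=names)
        res = sliding_regression(recording, shuffled, target, neuron=i,
                                 run_threshold=run_threshold, **kwargs)
        passed += int(res.significant)
    return passed / len(idx)


# ---------------------------------------------------------------------------
# transitions, reversal, anti-correlation

def value_choice_transition(value_series: SlidingSeries,
                            choice_series: SlidingSeries,
                            window: tuple[float, float] = (1000.0, 2500.0)) -> dict:
    """Is a graded value signal followed by the binary choice signal?

    True iff the value series has a qualifying significant run whose onset
    precedes the choice series' run onset inside ``window`` (default: from
    second-cue onset onward).
    """
    if value_series.window_centers_ms.shape != choice_series.window_centers_ms.shape:
        raise ValueError("series must share the window grid")
    v_on = value_series.run_onset_ms(window)
    c_on = choice_series.run_onset_ms(window)
    verdict = v_on is not None and c_on is not None and v_on < c_on
    reason = None
    if v_on is None and c_on is None:
        reason = "neither series has a significant run"
    elif v_on is None:
        reason = "no significant value run"
    elif c_on is None:
        reason = "no significant choice run"
    elif not verdict:
        reason = "choice onset does not follow value onset"
    return {"verdict": verdict, "value_onset_ms": v_on, "choice_onset_ms": c_on,
            "reason": reason}


def tuning_reversal_test(coef_cue1: np.ndarray, coef_cue2: np.ndarray) -> dict:
    """Sign-reversal of value tuning between the cues, with a one-proportion z.

    A neuron is consistent with integral feedback control if its value
    coefficient flips sign from the first to the second cue.  The population
    test is z = (p_hat - 0.5) / sqrt(0.25 / n), two-sided.
    """
    c1 = np.asarray(coef_cue1, float)
    c2 = np.asarray(coef_cue2, float)
    if c1.size == 0 or c1.shape != c2.shape:
        raise ValueError("need matching nonempty coefficient arrays")
    consistent = (c1 * c2) < 0
    n = c1.size
    p_hat = consistent.mean()
    z = (p_hat - 0.5) / math.sqrt(0.25 / n)
    p = 2 * stats.norm.sf(abs(z))
    return {"consistent": consistent, "n_consistent": int(consistent.sum()),
            "n": n, "proportion": float(p_hat), "z": float(z), "p": float(p)}


def value_anticorrelation(coef_first: np.ndarray, coef_second: np.ndarray) -> dict:
    """Across-neuron correlation of first- vs second-option value coefficients.

    Negative correlation indicates that the two options pull single-neuron
    activity in opposite directions - a value comparison.  Coefficients must
    come from magnitude-only value regressors (uncorrelated across options
    by design) to avoid built-in anti-correlation.
    """
    a = np.asarray(coef_first, float)
    b = np.asarray(coef_second, float)
    if a.size < 3 or a.shape != b.shape:
        raise ValueError("need >= 3 matching coefficient pairs")
    r, p = stats.pearsonr(a, b)
    return {"r": float(r), "p": float(p), "n": int(a.size)}
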