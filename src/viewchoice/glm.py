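"""Linear-model machinery for single-neuron encoding analyses.

``fit_glm`` is an ordinary least-squares fit with two-sided t tests,
standardized coefficients x_i * s_i / s_y, an overall F test, and per
regressor partial R^2 = (SSE_reduced - SSE_full) / SSE_reduced.

Design-matrix builders reproduce the task regressor codings: view-based
choice (1 = first-viewed chosen, 0 = second-viewed chosen), object choice
(1 = A), viewing order (1 = A-then-B), per-option values, probabilities and
magnitudes, side regressors, block-wise +1/-1/0 contrasts for the
four-objects task, and juice regressors for the two-juices task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spikes import RecordingSet


class CollinearityError(np.linalg.LinAlgError):
    def __init__(self, columns):
        super().__init__(f"design matrix is rank deficient; collinear set: {columns}")
        self.columns = columns


@dataclass
class RegressionResult:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    beta_std: np.ndarray
    partial_r2: np.ndarray
    r2: float
    f_stat: float
    f_p: float
    n: int
    sse: float

    def __getitem__(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "coef": float(self.coef[i]), "se": float(self.se[i]),
            "t": float(self.t[i]), "p": float(self.p[i]),
            "beta_std": float(self.beta_std[i]),
            "partial_r2": float(self.partial_r2[i]),
        }


def _as_matrix(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def fit_glm(design, response, add_intercept: bool = True) -> RegressionResult:
    """OLS fit of one response on named regressors.

    Requires n >= p + 2 rows and a full-rank design; a rank-deficient design
    raises :class:`CollinearityError` naming the offending columns.
    """
    X, names = _as_matrix(design)
    y = np.asarray(response, dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + names
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows for {p} columns, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        bad = []
        for j in range(1, p):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.sum(resid ** 2) < 1e-10 * max(np.sum(X[:, j] ** 2), 1e-30):
                bad.append(names[j])
        raise CollinearityError(bad or names)

    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sse = float(resid @ resid)
    dof = n - p
    sigma2 = sse / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(t), dof)

    sy = y.std(ddof=0)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    beta_std = np.array([
        coef[j] * X[:, j].std(ddof=0) / sy if sy > 0 else 0.0 for j in range(p)
    ])
    # overall F for the non-intercept regressors
    k = p - 1 if add_intercept else p
    if k > 0 and sst > sse and dof > 0:
        f_stat = ((sst - sse) / k) / (sse / dof) if add_intercept else np.nan
        f_p = float(stats.f.sf(f_stat, k, dof)) if np.isfinite(f_stat) else np.nan
    else:
        f_stat, f_p = 0.0, 1.0

    partial = np.zeros(p)
    for j in range(p):
        if names[j] == "intercept":
            partial[j] = np.nan
            continue
        reduced = np.delete(X, j, axis=1)
        c_r, _, _, _ = np.linalg.lstsq(reduced, y, rcond=None)
        sse_r = float(np.sum((y - reduced @ c_r) ** 2))
        partial[j] = (sse_r - sse) / sse_r if sse_r > 0 else 0.0

    return RegressionResult(
        names=names, coef=coef, se=se, t=t, p=pvals, beta_std=beta_std,
        partial_r2=partial, r2=r2, f_stat=float(f_stat), f_p=float(f_p),
        n=n, sse=sse,
    )


# ---------------------------------------------------------------------------
# z-normalization

@dataclass
class ZScoredEpochs:
    """Baseline-normalized epoch activity: (rate - control mean)/control SD."""

    data: dict[str, np.ndarray]           # epoch -> (n_neurons, n_trials)
    neuron_ids: list[str]
    excluded: list[str]                   # zero-baseline-SD neurons
    kept_index: np.ndarray                # indices into the original population


def zscore_epochs(recording: RecordingSet,
                  baseline_epoch: str = "control") -> ZScoredEpochs:
    """Z-score every epoch against the pre-fixation control period.

    Neurons whose control-period SD is zero cannot be normalized and are
    excluded (listed in ``excluded``).
    """
    base = recording.epochs[baseline_epoch].astype(float)
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 0
    data = {}
    for name, arr in recording.epochs.items():
        z = (arr.astype(float) - mu) / np.where(sd > 0, sd, 1.0)
        data[name] = z[keep]
    ids = [nr.neuron_id for nr in recording.neurons]
    return ZScoredEpochs(
        data=data,
        neuron_ids=[i for i, k in zip(ids, keep) if k],
        excluded=[i for i, k in zip(ids, keep) if not k],
        kept_index=np.flatnonzero(keep),
    )


def sign_correct(values: np.ndarray, coefficients: np.ndarray) -> np.ndarray:
    """Flip each neuron's activity by the sign of its coefficient for a
    designated variable, so positively and negatively tuned cells average
    constructively."""
    signs = np.where(np.asarray(coefficients) < 0, -1.0, 1.0)
    return values * signs[:, None]


# ---------------------------------------------------------------------------
# design matrices

def design_glm2(behavior, values: pd.DataFrame) -> pd.DataFrame:
    """Main-task choice model: view/object choice, order, values, sides."""
    t = behavior.trials
    first_is_a = (t["first_object"] == "A").astype(float)
    view_first = t["view_choice"].astype(float)          # 1 = first-viewed chosen
    chosen_a = (t["chosen_object"] == "A").astype(float)
    chosen_value = np.where(t["view_choice"].astype(bool),
                            values["v_first"], values["v_second"])
    return pd.DataFrame(
        {
            "ViewChoice": view_first,
            "ObjectChoice": chosen_a,
            "ObjectView": first_is_a,
            "FirstValue": values["v_first"],
            "SecondValue": values["v_second"],
            "ChosenValue": chosen_value,
            "ObjectALeft": t["a_left"].astype(float),
            "LeftChosen": (t["side_chosen"] == "left").astype(float),
        }
    )


def design_glm3(behavior, values: pd.DataFrame | None = None) -> pd.DataFrame:
    """Magnitude/probability control model (raw reward attributes)."""
    t = behavior.trials
    chosen_first = t["view_choice"].astype(bool)
    return pd.DataFrame(
        {
            "ViewChoice": t["view_choice"].astype(float),
            "ObjectChoice": (t["chosen_object"] == "A").astype(float),
            "ObjectView": (t["first_object"] == "A").astype(float),
            "FirstProb": t["first_prob"].astype(float),
            "SecondProb": t["second_prob"].astype(float),
            "FirstMag": t["first_mag"].astype(float),
            "SecondMag": t["second_mag"].astype(float),
            "ChosenProb": np.where(chosen_first, t["first_prob"], t["second_prob"]),
            "ChosenMag": np.where(chosen_first, t["first_mag"], t["second_mag"]),
            "ObjectALeft": t["a_left"].astype(float),
            "LeftChosen": (t["side_chosen"] == "left").astype(float),
        }
    )


def design_glm5(behavior, values: pd.DataFrame) -> pd.DataFrame:
    """Four-objects task: block-wise +1/-1/0 choice and view contrasts; side
    regressors omitted."""
    t = behavior.trials
    chosen = t["chosen_object"].to_numpy()
    first = t["first_object"].to_numpy()

    def contrast(pos, neg):
        return np.where(chosen == pos, 1.0, np.where(chosen == neg, -1.0, 0.0))

    def vcontrast(pos, neg):
        return np.where(first == pos, 1.0, np.where(first == neg, -1.0, 0.0))

    chosen_value = np.where(t["view_choice"].astype(bool),
                            values["v_first"], values["v_second"])
    return pd.DataFrame(
        {
            "ViewChoice": t["view_choice"].astype(float),
            "ObjAChoice_minus_ObjBChoice": contrast("A", "B"),
            "ObjCChoice_minus_ObjDChoice": contrast("C", "D"),
            "ObjAView_minus_ObjBView": vcontrast("A", "B"),
            "ObjCView_minus_ObjDView": vcontrast("C", "D"),
            "FirstValue": values["v_first"],
            "SecondValue": values["v_second"],
            "ChosenValue": chosen_value,
        }
    )


def design_glm6(behavior, values: pd.DataFrame) -> pd.DataFrame:
    """Two-juices task: adds juice choice and juice order regressors."""
    t = behavior.trials
    juice_of_a = t["juice_of_A"].to_numpy()
    juice_of_b = np.where(juice_of_a == "juice1", "juice2", "juice1")
    chosen_a = (t["chosen_object"] == "A").to_numpy()
    juice_chosen = np.where(chosen_a, juice_of_a, juice_of_b)
    first_is_a = (t["first_object"] == "A").to_numpy()
    juice_first = np.where(first_is_a, juice_of_a, juice_of_b)
    chosen_value = np.where(t["view_choice"].astype(bool),
                            values["v_first_mag"], values["v_second_mag"])
    return pd.DataFrame(
        {
            "ViewChoice": t["view_choice"].astype(float),
            "ObjectAChoice": chosen_a.astype(float),
            "JuiceAChoice": (juice_chosen == "juice1").astype(float),
            "ObjectAView": first_is_a.astype(float),
            "JuiceAFirst": (juice_first == "juice1").astype(float),
            "FirstValue": values["v_first_mag"],
            "SecondValue": values["v_second_mag"],
            "ChosenValue": chosen_value,
            "ObjectALeft": t["a_left"].astype(float),
            "LeftChosen": (t["side_chosen"] == "left").astype(float),
        }
    )


def task_related_gate(recording: RecordingSet, alpha: float = 0.005) -> np.ndarray:
    """Wilcoxon test of cue-period counts against the pre-fixation control
    period (Bonferroni-style strict alpha); boolean mask per neuron."""
    base = recording.epochs["control"]
    keep = np.zeros(recording.n_neurons, dtype=bool)
    for i in range(recording.n_neurons):
        for epoch in ("cue1", "cue2"):
            diff = recording.epochs[epoch][i] - base[i]
            if np.all(diff == 0):
                continue
            try:
                p = stats.wilcoxon(diff, zero_method="wilcox").pvalue
            except ValueError:
                continue
            if p < alpha:
                keep[i] = True
                break
    return keep
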