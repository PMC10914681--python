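"""Pseudo-population decoding.

Separately "recorded" neurons are aggregated into pseudo-populations by
randomly matching trials within each group of a grouping variable; decoding
repeats over many random matchings.  Classifiers: a linear maximum-margin
SVM (C = 1) and a biologically plausible nearest-neighbor decoder that
assigns each trial to the group of its nearest single-trial (or group-mean)
neighbor by Euclidean distance.  Accuracy is leave-one-out cross-validated
and compared against label-shuffled data with a two-sided rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC, LinearSVC

MIN_TRIAL_CHOICES = (5, 10, 15)


def _linear_svm() -> LinearSVC:
    # liblinear solves the same linear maximum-margin problem orders of
    # magnitude faster than the kernel QP on non-separable (e.g. shuffled) data
    return LinearSVC(C=1.0, dual="auto", max_iter=20000)


@dataclass
class PseudoPopulation:
    """Per-group, per-neuron trial pools plus the matching machinery.

    ``pools[group][k]`` holds neuron k's activity values on its trials of
    that group.  ``sample(seed)`` draws one random within-group trial
    matching: for each group a (m_g, n_neurons) matrix, where m_g is the
    smallest per-neuron trial count in that group.
    """

    pools: dict[str, list[np.ndarray]]
    neuron_ids: list[str]
    excluded: list[str]
    min_trials: int
    seed: int

    @property
    def groups(self) -> list[str]:
        return list(self.pools)

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    def group_sizes(self) -> dict[str, int]:
        return {g: min(len(v) for v in pools) if (pools := self.pools[g]) else 0
                for g in self.pools}

    def sample(self, seed: int) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(seed)
        out = {}
        for g, pools in self.pools.items():
            m = min(len(v) for v in pools)
            cols = [v[rng.permutation(len(v))[:m]] for v in pools]
            out[g] = np.column_stack(cols)
        return out

    def subset(self, neuron_idx: np.ndarray) -> "PseudoPopulation":
        return PseudoPopulation(
            pools={g: [v[k] for k in neuron_idx] for g, v in self.pools.items()},
            neuron_ids=[self.neuron_ids[k] for k in neuron_idx],
            excluded=self.excluded,
            min_trials=self.min_trials,
            seed=self.seed,
        )


def build_pseudopopulation(activity: np.ndarray, labels: np.ndarray,
                           neuron_ids: list[str] | None = None,
                           min_trials: int = 5, seed: int = 0) -> PseudoPopulation:
    """Build group pools from an (n_neurons, n_trials) activity matrix.

    Neurons with fewer than ``min_trials`` trials in any group are excluded
    (and listed).  The grouping must yield at least two groups.
    """
    activity = np.asarray(activity, float)
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) < 2:
        raise ValueError("grouping must yield at least two groups")
    n_neurons = activity.shape[0]
    ids = neuron_ids or [f"n{i:04d}" for i in range(n_neurons)]
    group_masks = {g: labels == g for g in groups}
    keep, excluded = [], []
    for i in range(n_neurons):
        ok = all(group_masks[g].sum() >= min_trials for g in groups)
        # per-neuron trial availability: with a shared trial grid every neuron
        # sees the same trials; per-neuron masks would filter here instead
        (keep if ok else excluded).append(i)
    if not keep:
        raise ValueError("no neuron passes the minimum-trial filter")
    pools = {g: [activity[i, group_masks[g]] for i in keep] for g in groups}
    return PseudoPopulation(
        pools=pools,
        neuron_ids=[ids[i] for i in keep],
        excluded=[ids[i] for i in excluded],
        min_trials=min_trials,
        seed=seed,
    )


def build_pseudopopulation_pools(per_neuron: list[dict[str, np.ndarray]],
                                 neuron_ids: list[str] | None = None,
                                 min_trials: int = 5, seed: int = 0) -> PseudoPopulation:
    """Build from per-neuron {group: values} dicts (neurons recorded in
    different sessions, so per-neuron trial counts may differ)."""
    if not per_neuron:
        raise ValueError("empty neuron list")
    groups = sorted({g for d in per_neuron for g in d})
    if len(groups) < 2:
        raise ValueError("grouping must yield at least two groups")
    ids = neuron_ids or [f"n{i:04d}" for i in range(len(per_neuron))]
    keep, excluded = [], []
    for i, d in enumerate(per_neuron):
        ok = all(g in d and len(d[g]) >= min_trials for g in groups)
        (keep if ok else excluded).append(i)
    if not keep:
        raise ValueError("no neuron passes the minimum-trial filter")
    pools = {g: [np.asarray(per_neuron[i][g], float) for i in keep] for g in groups}
    return PseudoPopulation(pools, [ids[i] for i in keep],
                            [ids[i] for i in excluded], min_trials, seed)


@dataclass
class DecodeResult:
    accuracies: np.ndarray          # % correct per matching repetition
    shuffle_accuracies: np.ndarray  # % correct per label-shuffled repetition
    scheme: dict = field(default_factory=dict)
    per_class: dict | None = None
    confusion: np.ndarray | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=0))

    @property
    def shuffle_p(self) -> float:
        if self.shuffle_accuracies.size == 0:
            return float("nan")
        return float(stats.ranksums(self.accuracies, self.shuffle_accuracies).pvalue)


def _stack(matrices: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack(list(matrices.values()))
    y = np.concatenate([np.full(len(m), i) for i, m in enumerate(matrices.values())])
    return X, y


def _loo_svm(X: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    correct = 0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        clf = _linear_svm()
        clf.fit(X[mask], y[mask])
        correct += int(clf.predict(X[i:i + 1])[0] == y[i])
    return 100.0 * correct / n


def _loo_nn(X: np.ndarray, y: np.ndarray) -> float:
    """Nearest single-trial neighbor, leave-one-out; distance ties broken by
    the lowest trial index (deterministic)."""
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    nearest = np.argmin(d2, axis=1)   # argmin takes the first index on ties
    return 100.0 * float((y[nearest] == y).mean())


def _loo_nn_mean(X: np.ndarray, y: np.ndarray) -> float:
    """Nearest group-mean decoder: each test trial is assigned to the group
    whose mean vector (computed without the test trial) is closest."""
    labels = np.unique(y)
    correct = 0
    sums = {g: X[y == g].sum(axis=0) for g in labels}
    counts = {g: int((y == g).sum()) for g in labels}
    for i in range(len(y)):
        best, best_d = None, np.inf
        for g in labels:
            if g == y[i]:
                if counts[g] < 2:
                    return np.nan
                mu = (sums[g] - X[i]) / (counts[g] - 1)
            else:
                mu = sums[g] / counts[g]
            d = float(np.sum((X[i] - mu) ** 2))
            if d < best_d:
                best, best_d = g, d
        correct += int(best == y[i])
    return 100.0 * correct / len(y)


_METHODS = {"svm": _loo_svm, "nn": _loo_nn, "nn_mean": _loo_nn_mean}
#: repetition defaults per classifier (matching repetitions)
DEFAULT_MATCHINGS = {"svm": 150, "nn": 500, "nn_mean": 500}


def _split8020(X, y, rng) -> float:
    idx = rng.permutation(len(y))
    cut = max(int(0.8 * len(y)), 1)
    tr, te = idx[:cut], idx[cut:]
    if len(te) == 0 or len(np.unique(y[tr])) < 2:
        return np.nan
    clf = _linear_svm()
    clf.fit(X[tr], y[tr])
    return 100.0 * float((clf.predict(X[te]) == y[te]).mean())


def decode(pseudo: PseudoPopulation, method: str = "svm",
           n_matchings: int | None = None, seed: int = 0,
           n_shuffles: int = 1000, cv: str = "loo") -> DecodeResult:
    """Leave-one-out decoding accuracy over random trial matchings.

    For each matching repetition the pseudo-population is re-assembled with
    fresh random within-group trial matching and decoded; the shuffle null
    repeats the procedure with permuted group labels.  Significance is a
    two-sided rank-sum between the two accuracy vectors.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    sizes = pseudo.group_sizes()
    if min(sizes.values()) < 2:
        raise ValueError("degenerate group (fewer than 2 trials)")
    n_matchings = n_matchings or DEFAULT_MATCHINGS[method]
    rng = np.random.default_rng(seed)
    fn = _METHODS[method]

    accs = np.empty(n_matchings)
    for m in range(n_matchings):
        X, y = _stack(pseudo.sample(int(rng.integers(2 ** 31))))
        accs[m] = fn(X, y) if cv == "loo" else _split8020(X, y, rng)

    shuffles = np.empty(n_shuffles)
    for s in range(n_shuffles):
        X, y = _stack(pseudo.sample(int(rng.integers(2 ** 31))))
        y = rng.permutation(y)
        shuffles[s] = fn(X, y) if cv == "loo" else _split8020(X, y, rng)

    return DecodeResult(accs, shuffles,
                        scheme={"method": method, "cv": cv,
                                "groups": pseudo.groups,
                                "min_trials": pseudo.min_trials})


def cross_condition_decode(pseudo_train: PseudoPopulation,
                           pseudo_test: PseudoPopulation,
                           method: str = "svm", n_matchings: int = 50,
                           seed: int = 0, n_shuffles: int = 1000,
                           recode_rule: str = "none") -> DecodeResult:
    """Train in one condition, test in another (generalization test).

    ``recode_rule="invert_by_sequence"`` swaps the test population's group
    labels before evaluation - the recoding that recovers object choice from
    a view-based code once the viewing sequence is known.
    """
    if pseudo_train.neuron_ids != pseudo_test.neuron_ids:
        raise ValueError("train/test populations must share the neuron list")
    if recode_rule not in ("none", "invert_by_sequence"):
        raise ValueError(f"unknown recode rule {recode_rule!r}")
    rng = np.random.default_rng(seed)
    groups = pseudo_train.groups

    def one(shuffle: bool) -> float:
        Xtr, ytr = _stack(pseudo_train.sample(int(rng.integers(2 ** 31))))
        test_mats = pseudo_test.sample(int(rng.integers(2 ** 31)))
        if recode_rule == "invert_by_sequence":
            test_mats = {groups[0]: test_mats[groups[1]],
                         groups[1]: test_mats[groups[0]]}
        Xte, yte = _stack(test_mats)
        if shuffle:
            ytr = rng.permutation(ytr)
        if method == "svm":
            clf = _linear_svm()
            clf.fit(Xtr, ytr)
            pred = clf.predict(Xte)
        else:
            d2 = np.sum((Xte[:, None, :] - Xtr[None, :, :]) ** 2, axis=2)
            pred = ytr[np.argmin(d2, axis=1)]
        return 100.0 * float((pred == yte).mean())

    accs = np.array([one(False) for _ in range(n_matchings)])
    shuffles = np.array([one(True) for _ in range(n_shuffles)])
    return DecodeResult(accs, shuffles,
                        scheme={"method": method, "recode_rule": recode_rule,
                                "cross_condition": True})


def conjunction_decode(pseudo: PseudoPopulation, n_matchings: int = 50,
                       seed: int = 0, n_shuffles: int = 1000) -> DecodeResult:
    """Multi-class (one-vs-one linear SVM) decoding of 4 conjunction groups
    (viewing sequence x view-based choice); chance is 25%."""
    if len(pseudo.groups) != 4:
        raise ValueError("conjunction decoding needs exactly 4 groups")
    rng = np.random.default_rng(seed)
    groups = pseudo.groups
    k = len(groups)

    def one(shuffle: bool):
        X, y = _stack(pseudo.sample(int(rng.integers(2 ** 31))))
        if shuffle:
            y = rng.permutation(y)
        n = len(y)
        pred = np.empty(n, dtype=int)
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            clf = SVC(kernel="linear", C=1.0, decision_function_shape="ovo",
                      max_iter=100_000)
            clf.fit(X[mask], y[mask])
            pred[i] = clf.predict(X[i:i + 1])[0]
        return y, pred

    accs = np.empty(n_matchings)
    confusion = np.zeros((k, k))
    per_class = {g: [] for g in groups}
    for m in range(n_matchings):
        y, pred = one(False)
        accs[m] = 100.0 * float((pred == y).mean())
        for g in range(k):
            sel = y == g
            per_class[groups[g]].append(100.0 * float((pred[sel] == g).mean()))
            for h in range(k):
                confusion[g, h] += float((pred[sel] == h).mean())
    confusion /= n_matchings
    shuffles = np.array([
        100.0 * float((p == yy).mean()) for yy, p in (one(True) for _ in range(n_shuffles))
    ])
    return DecodeResult(accs, shuffles,
                        scheme={"method": "svm_ovo", "groups": groups},
                        per_class={g: float(np.mean(v)) for g, v in per_class.items()},
                        confusion=confusion)


def decode_by_difficulty(activity: np.ndarray, labels: np.ndarray,
                         value_differences: np.ndarray, min_trials: int = 5,
                         method: str = "svm", n_matchings: int = 30,
                         seed: int = 0, n_shuffles: int = 200) -> pd.DataFrame:
    """Decoding accuracy per decision-difficulty tercile.

    Trials are split by terciles of the unsigned value difference between
    the first- and second-viewed options; the grouping variable (typically
    view-based choice) is decoded within each tercile.  Terciles whose
    groups fall under 2 trials are skipped.
    """
    dv = np.abs(np.asarray(value_differences, float))
    # rank-based terciles: equal counts even with tied |dV| (ties broken by
    # trial order under the stable sort)
    order = np.argsort(dv, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(dv.size)
    tercile = (3 * ranks) // dv.size  # 0 = hardest (smallest |dV|)
    rows = []
    for tc, name in zip(range(3), ("hard", "middle", "easy")):
        sel = tercile == tc
        try:
            pop = build_pseudopopulation(activity[:, sel], labels[sel],
                                         min_trials=min_trials, seed=seed)
            res = decode(pop, method=method, n_matchings=n_matchings,
                         seed=seed + tc, n_shuffles=n_shuffles)
            rows.append({"tercile": name, "n_trials": int(sel.sum()),
                         "accuracy": res.mean_accuracy, "sd": res.sd_accuracy,
                         "shuffle_p": res.shuffle_p, "skipped": False})
        except ValueError:
            rows.append({"tercile": name, "n_trials": int(sel.sum()),
                         "accuracy": np.nan, "sd": np.nan, "shuffle_p": np.nan,
                         "skipped": True})
    return pd.DataFrame(rows)


def accuracy_vs_samplesize(pseudo: PseudoPopulation, sizes: list[int],
                           reps: int = 100, method: str = "svm",
                           seed: int = 0, n_matchings_per_rep: int = 1) -> pd.DataFrame:
    """Mean +/- SD accuracy for random neuron subsamples of each size."""
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size < 1 or size > pseudo.n_neurons:
            raise ValueError(f"sample size {size} outside [1, {pseudo.n_neurons}]")
        accs = []
        for _ in range(reps):
            idx = rng.choice(pseudo.n_neurons, size=size, replace=False)
            sub = pseudo.subset(idx)
            res = decode(sub, method=method, n_matchings=n_matchings_per_rep,
                         seed=int(rng.integers(2 ** 31)), n_shuffles=0)
            accs.append(res.mean_accuracy)
        rows.append({"size": size, "accuracy": float(np.mean(accs)),
                     "sd": float(np.std(accs, ddof=0)), "reps": reps})
    return pd.DataFrame(rows)
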