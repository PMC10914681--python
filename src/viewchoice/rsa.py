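"""Representational similarity analysis with template regression.

A condition-by-neuron matrix of normalized mean activity is correlated
across neurons to give a condition-by-condition similarity matrix.  Model
templates (object identity, view-based value with levels coded -2.25,
-0.75, 0.75, 2.25 and pairwise-product similarity, object value as the
product of identity and value templates, choice templates) are regressed
jointly onto the vectorized matrix; significance comes from permutation
tests that shuffle the condition rows and recompute the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALUE_LEVEL_CODES = {1: -2.25, 2: -0.75, 3: 0.75, 4: 2.25}


class ConditionError(ValueError):
    pass


@dataclass
class ConditionMatrix:
    """Condition x neuron matrix of normalized mean activity.

    ``conditions`` is a DataFrame (one row per condition, preserving order
    across calls) whose columns name condition attributes (``object``,
    ``value_level``, ``choice_object``, ``view_choice``, ``sequence``,
    ``side``); ``data`` is normalized per neuron (column mean removed,
    divided by column SD).
    """

    conditions: pd.DataFrame
    data: np.ndarray
    window: str = "fixed"

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)


@dataclass
class RSAMatrix:
    conditions: pd.DataFrame
    values: np.ndarray

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-10):
            raise AssertionError("RSA matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise AssertionError("RSA matrix diagonal must be 1")
        if v.max() > 1 + 1e-8 or v.min() < -1 - 1e-8:
            raise AssertionError("correlations must lie in [-1, 1]")


def condition_rsa(activity: np.ndarray, labels: pd.DataFrame,
                  window: str = "fixed",
                  conditions: pd.DataFrame | None = None,
                  ) -> tuple[ConditionMatrix, RSAMatrix]:
    """Condition means, per-neuron normalization, and pairwise correlations.

    ``activity`` is (n_neurons, n_trials); ``labels`` one row per trial with
    the condition attributes.  Conditions default to the sorted unique
    attribute combinations; passing an explicit ``conditions`` grid (e.g. a
    full factorial) raises on any unrealized condition, naming it.
    """
    activity = np.asarray(activity, float)
    cols = list(labels.columns)
    if conditions is not None:
        conds = conditions.reset_index(drop=True)
    else:
        conds = labels.drop_duplicates().sort_values(cols).reset_index(drop=True)
    means = np.empty((len(conds), activity.shape[0]))
    for ci, (_, cond) in enumerate(conds.iterrows()):
        m = np.ones(len(labels), dtype=bool)
        for c in cols:
            m &= (labels[c] == cond[c]).to_numpy()
        if not m.any():
            raise ConditionError(f"unrealized condition: {dict(cond)}")
        means[ci] = activity[:, m].mean(axis=1)
    mu = means.mean(axis=0, keepdims=True)
    sd = means.std(axis=0, ddof=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    normalized = (means - mu) / sd
    cm = ConditionMatrix(conditions=conds, data=normalized, window=window)
    rsa = RSAMatrix(conditions=conds, values=_corr(normalized))
    rsa.validate()
    return cm, rsa


def _corr(cond_by_neuron: np.ndarray) -> np.ndarray:
    r = np.corrcoef(cond_by_neuron)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


# ---------------------------------------------------------------------------
# templates

@dataclass
class TemplateSet:
    conditions: pd.DataFrame
    templates: dict[str, np.ndarray] = field(default_factory=dict)

    def names(self) -> list[str]:
        return list(self.templates)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.templates[name]


def build_templates(conditions: pd.DataFrame,
                    which: list[str] | None = None) -> TemplateSet:
    """Model similarity templates over a condition set.

    Available: ``identity``; ``object`` (1 for same object); ``view_value``
    (pairwise products of mean-centered level codes); ``ordinal_value``
    (negative level distance: adjacent levels equally similar anywhere on
    the scale); ``object_value`` (elementwise product of object and
    view_value); ``object_choice``; ``view_choice`` (1 for pairs that both
    refer to a first-viewed choice); ``left_choice``.  A template whose
    required attribute is missing raises.
    """
    k = len(conditions)
    available: dict[str, callable] = {}

    available["identity"] = lambda: np.eye(k)

    def need(col: str, template: str):
        if col not in conditions.columns:
            raise ConditionError(f"template {template!r} needs attribute {col!r}")
        return conditions[col].to_numpy()

    def same(col: str, template: str) -> np.ndarray:
        v = need(col, template)
        return (v[:, None] == v[None, :]).astype(float)

    def both(col: str, value, template: str) -> np.ndarray:
        v = need(col, template)
        on = (v == value).astype(float)
        return np.outer(on, on)

    available["object"] = lambda: same("object", "object")
    available["object_choice"] = lambda: same("choice_object", "object_choice")
    available["view_choice"] = lambda: both("view_choice", "first", "view_choice")
    # partition variant: 1 for any pair sharing the view-based choice (both
    # first-viewed or both second-viewed); higher power when both choice
    # categories carry signal
    available["view_choice_same"] = lambda: same("view_choice", "view_choice_same")
    available["left_choice"] = lambda: both("side", "left", "left_choice")

    def view_value() -> np.ndarray:
        lv = need("value_level", "view_value")
        codes = np.array([VALUE_LEVEL_CODES[int(x)] for x in lv])
        return np.outer(codes, codes)

    available["view_value"] = view_value

    def ordinal_value() -> np.ndarray:
        lv = need("value_level", "ordinal_value").astype(float)
        return -np.abs(lv[:, None] - lv[None, :])

    available["ordinal_value"] = ordinal_value
    available["object_value"] = lambda: available["object"]() * view_value()

    which = which or ["identity", "object", "view_value", "object_value"]
    ts = TemplateSet(conditions=conditions)
    for name in which:
        if name not in available:
            raise ConditionError(f"unknown template {name!r}")
        ts.templates[name] = available[name]()
    return ts


# ---------------------------------------------------------------------------
# template regression with permutation inference

@dataclass
class RSARegression:
    names: list[str]
    coef: np.ndarray
    t: np.ndarray
    partial_r2: np.ndarray
    r2: float
    critical_t: dict[str, float]    # per-template |t| threshold at permutation p < alpha
    significant: dict[str, bool]
    perm_p: dict[str, float]
    difference_tests: pd.DataFrame | None
    n_perm: int
    unique_cells: bool


def _vec(mat: np.ndarray, unique_cells: bool) -> np.ndarray:
    if unique_cells:
        iu = np.triu_indices(mat.shape[0], k=0)
        return mat[iu]
    return mat.ravel()


def _regress(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """coefs, t stats, R^2, partial R^2 (columns beyond the intercept)."""
    n, p = X.shape
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sse = float(resid @ resid)
    dof = max(n - p, 1)
    sigma2 = sse / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 1e-300))
    t = coef / se
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    pr2 = np.zeros(p)
    for j in range(1, p):
        Xr = np.delete(X, j, axis=1)
        cr, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
        sse_r = float(np.sum((y - Xr @ cr) ** 2))
        pr2[j] = (sse_r - sse) / sse_r if sse_r > 0 else 0.0
    return coef, t, r2, pr2


def rsa_regression(cond: ConditionMatrix, templates: TemplateSet,
                   n_perm: int = 10_000, seed: int = 0,
                   unique_cells: bool = False, alpha: float = 0.001,
                   difference_pairs: list[tuple[str, str]] | None = None) -> RSARegression:
    """Multiple regression of the neuronal RSA matrix on model templates.

    All matrix cells are vectorized (full matrix by default; upper triangle
    with diagonal in ``unique_cells`` mode) and regressed jointly on the
    templates, which therefore compete for variance.  The null distribution
    permutes the condition rows of the condition-by-neuron matrix and
    recomputes correlations and regression; the critical |t| is the
    (1 - alpha) quantile of the permuted |t| values.  Coefficient-difference
    tests use the permuted t-difference distribution the same way.
    """
    names = templates.names()
    R = _corr(cond.data)
    k = R.shape[0]
    y = _vec(R, unique_cells)
    X = np.column_stack([np.ones(y.size)]
                        + [_vec(templates[nm], unique_cells) for nm in names])
    if X.shape[1] >= y.size:
        raise ConditionError("more templates than informative matrix cells")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConditionError("templates are collinear over this condition set")

    coef, t, r2, pr2 = _regress(y, X)

    rng = np.random.default_rng(seed)
    t_null = np.empty((n_perm, len(names)))
    for s in range(n_perm):
        perm = rng.permutation(k)
        # row-permuting the condition matrix permutes the correlation matrix
        Rp = R[np.ix_(perm, perm)]
        _, tp, _, _ = _regress(_vec(Rp, unique_cells), X)
        t_null[s] = tp[1:]
    abs_null = np.abs(t_null)
    # per-template null: the identity template is permutation-invariant (the
    # diagonal survives any condition relabeling), so thresholds are not pooled
    critical_t = {
        nm: float(np.quantile(abs_null[:, j], 1 - alpha))
        for j, nm in enumerate(names)
    }
    perm_p = {
        nm: float((abs_null[:, j] >= abs(t[j + 1])).mean())
        for j, nm in enumerate(names)
    }
    significant = {nm: bool(abs(t[j + 1]) > critical_t[nm])
                   for j, nm in enumerate(names)}

    diff_table = None
    if difference_pairs:
        rows = []
        for a, b in difference_pairs:
            ia, ib = names.index(a), names.index(b)
            obs = t[ia + 1] - t[ib + 1]
            null = t_null[:, ia] - t_null[:, ib]
            crit = float(np.quantile(np.abs(null), 1 - alpha))
            rows.append({"a": a, "b": b, "t_diff": float(obs),
                         "critical": crit, "significant": abs(obs) > crit,
                         "p": float((np.abs(null) >= abs(obs)).mean())})
        diff_table = pd.DataFrame(rows)

    return RSARegression(
        names=names, coef=coef[1:], t=t[1:], partial_r2=pr2[1:], r2=r2,
        critical_t=critical_t, significant=significant, perm_p=perm_p,
        difference_tests=diff_table, n_perm=n_perm, unique_cells=unique_cells,
    )


def value_quartile_labels(values: np.ndarray) -> np.ndarray:
    """Four equally populated value groups (1..4); boundary ties broken by
    trial order after stable ranking."""
    v = np.asarray(values, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(v.size)
    return 1 + (4 * ranks) // v.size


def sliding_rsa_partial_r2(activity_bins: np.ndarray, labels: pd.DataFrame,
                           template_name: str, which: list[str],
                           window_idx: list[np.ndarray],
                           n_perm: int = 0, seed: int = 0) -> np.ndarray:
    """Partial R^2 of one template across sliding windows.

    ``activity_bins`` is (n_neurons, n_trials, n_bins); ``window_idx`` lists
    the bin indices of each window.  Returns the per-window partial R^2 of
    ``template_name`` from the joint regression on ``which`` templates.
    """
    out = np.empty(len(window_idx))
    for w, idx in enumerate(window_idx):
        act = activity_bins[:, :, idx].sum(axis=2)
        cm, _ = condition_rsa(act, labels, window="sliding")
        ts = build_templates(cm.conditions, which=which)
        reg = rsa_regression(cm, ts, n_perm=max(n_perm, 1), seed=seed)
        out[w] = reg.partial_r2[reg.names.index(template_name)]
    return out
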