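"""Reinforcement-learning models of choice behavior, fitting, and optimality.

The model family covers a basic delta-rule learner, a reversal learner that
additionally updates the unchosen object's value in the opposite direction
(suited to blocked probability reversals), two-learning-rate variants that
split the rate between rewarded and unrewarded trials, and Pearce-Hall
variants in which the effective learning rate tracks the recent unsigned
prediction error (associability).

Value update (reversal learner), with R_t in {0, 1} and A chosen::

    V_A(t+1) = V_A(t) + alpha * ( R_t - V_A(t))
    V_B(t+1) = V_B(t) + alpha * (-R_t - V_B(t))

Choices follow a softmax on the value difference with inverse temperature
beta.  Fitting maximizes the likelihood of realized choices by Nelder-Mead
search over smoothly transformed parameters (alpha via a logistic map, beta
via an exponential map), with multiple random restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .task import SMALL_REWARD_ML, SessionBehavior, SessionSchedule

VARIANTS = (
    "basic",
    "basic_2lr",
    "reversal",
    "reversal_2lr",
    "pearce_hall",
    "ph_reversal",
    "ph_reversal_2lr",
)

_PH_VARIANTS = {"pearce_hall", "ph_reversal", "ph_reversal_2lr"}
_REVERSAL_VARIANTS = {"reversal", "reversal_2lr", "ph_reversal", "ph_reversal_2lr"}
_2LR_VARIANTS = {"basic_2lr", "reversal_2lr", "ph_reversal_2lr"}

_LOGP_FLOOR = math.log(1e-12)


class ParameterError(ValueError):
    """Raised for RL parameters outside their admissible range."""


@dataclass
class RLParams:
    """Parameters of one RL variant.

    alpha/alpha_neg are learning rates in [0, 1] (alpha_neg applies on
    unrewarded trials for two-learning-rate variants).  beta >= 0 is the
    softmax inverse temperature.  For Pearce-Hall variants alpha scales the
    associability (kappa in the usual notation) and gamma in [0, 1] is the
    associability decay.  mag_weight adds cued magnitude (mL) to the choice
    utility; it defaults to 0 so that choices follow the pure value softmax.
    """

    variant: str = "reversal"
    alpha: float = 0.3
    beta: float = 3.0
    alpha_neg: float | None = None
    gamma: float | None = None
    mag_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown RL variant: {self.variant!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError("alpha must lie in [0, 1]")
        if self.beta < 0.0:
            raise ParameterError("beta must be >= 0")
        if self.variant in _2LR_VARIANTS:
            if self.alpha_neg is None:
                self.alpha_neg = self.alpha
            if not 0.0 <= self.alpha_neg <= 1.0:
                raise ParameterError("alpha_neg must lie in [0, 1]")
        if self.variant in _PH_VARIANTS:
            if self.gamma is None:
                self.gamma = 0.5
            if not 0.0 <= self.gamma <= 1.0:
                raise ParameterError("gamma must lie in [0, 1]")

    @property
    def n_free(self) -> int:
        k = 2  # alpha, beta
        if self.variant in _2LR_VARIANTS:
            k += 1
        if self.variant in _PH_VARIANTS:
            k += 1
        return k


@dataclass
class AgentState:
    """Per-trial latent series of one likelihood evaluation."""

    values: pd.DataFrame  # columns V_A, V_B (pre-choice values per trial)
    prediction_errors: np.ndarray
    choice_logp: np.ndarray


@dataclass
class FitResult:
    params: RLParams
    neg_loglik: float
    aic: float
    bic: float
    n_trials: int
    n_restarts: int
    converged: bool
    boundary_flags: list[str] = field(default_factory=list)
    clamped_trials: int = 0


def _update(params: RLParams, v_c: float, v_u: float, r: float,
            assoc: float) -> tuple[float, float, float, float]:
    """One value update; returns (new chosen, new unchosen, pe, new assoc)."""
    pe = r - v_c
    if params.variant in _PH_VARIANTS:
        rate = params.alpha * assoc
        assoc = params.gamma * abs(pe) + (1.0 - params.gamma) * assoc
    elif params.variant in _2LR_VARIANTS:
        rate = params.alpha if r > 0 else params.alpha_neg
    else:
        rate = params.alpha
    v_c = v_c + rate * pe
    if params.variant in _REVERSAL_VARIANTS:
        v_u = v_u + rate * (-r - v_u)
    return v_c, v_u, pe, assoc


def _utility_gap(params: RLParams, v_a: float, v_b: float,
                 mag_a: float, mag_b: float) -> float:
    return (v_a - v_b) + params.mag_weight * (mag_a - mag_b)


def rl_loglikelihood(behavior: SessionBehavior, params: RLParams) -> tuple[float, AgentState]:
    """Negative log-likelihood of the realized choices under ``params``.

    Values are replayed forward from V = 0 using the session's recorded
    choices and binary reward outcomes; the per-trial likelihood is the
    softmax probability of the realized choice.  Log-probabilities are
    floored at log(1e-12) (and the event counted) so that extreme beta
    cannot produce -inf.
    """
    trials = behavior.trials
    if len(trials) == 0:
        raise ValueError("behavior has no trials")
    chosen = trials["chosen_object"].to_numpy()
    rewarded = trials["rewarded"].to_numpy(dtype=float)
    mag_a = trials["mag_A"].to_numpy(dtype=float)
    mag_b = trials["mag_B"].to_numpy(dtype=float)
    n = len(trials)

    v_a = v_b = 0.0
    assoc = 1.0
    logp = np.empty(n)
    pes = np.empty(n)
    va_series = np.empty(n)
    vb_series = np.empty(n)
    clamped = 0
    beta = params.beta
    for t in range(n):
        va_series[t] = v_a
        vb_series[t] = v_b
        gap = _utility_gap(params, v_a, v_b, mag_a[t], mag_b[t])
        z = beta * gap
        # log sigmoid, numerically stable
        if z >= 0:
            lp_a = -math.log1p(math.exp(-z))
        else:
            lp_a = z - math.log1p(math.exp(z))
        lp = lp_a if chosen[t] == "A" else lp_a - z
        if lp < _LOGP_FLOOR:
            lp = _LOGP_FLOOR
            clamped += 1
        logp[t] = lp
        r = rewarded[t]
        if chosen[t] == "A":
            v_a, v_b, pes[t], assoc = _update(params, v_a, v_b, r, assoc)
        else:
            v_b, v_a, pes[t], assoc = _update(params, v_b, v_a, r, assoc)
    state = AgentState(
        values=pd.DataFrame({"V_A": va_series, "V_B": vb_series}),
        prediction_errors=pes,
        choice_logp=logp,
    )
    return float(-logp.sum()), state


def simulate_agent(schedule: SessionSchedule, rl_params: RLParams, seed: int,
                   session_id: str | None = None) -> SessionBehavior:
    """Simulate an RL agent on a schedule; returns the full trial record.

    Choices are sampled from the softmax of the value (plus optional
    magnitude-weighted) difference; rewards are sampled from the chosen
    object's true block probability.  Binary reward coding: R = 1 when the
    cued magnitude is delivered, 0 for the small consolation reward.
    """
    rng = np.random.default_rng(seed)
    sched = schedule.trials
    n = len(sched)
    objects = schedule.objects
    values = {o: 0.0 for o in objects}
    assoc = 1.0
    records = []
    for t in range(n):
        row = sched.iloc[t]
        first = row["first_object"]
        if schedule.task_variant == "four_objects":
            pair = ("A", "B") if row["object_set"] == 0 else ("C", "D")
        else:
            pair = ("A", "B")
        a, b = pair  # canonical pair order; 'A'-slot is the first of the pair
        second = b if first == a else a
        gap = _utility_gap(rl_params, values[a], values[b], row["mag_A"], row["mag_B"])
        p_a = 1.0 / (1.0 + math.exp(-np.clip(rl_params.beta * gap, -700, 700)))
        chosen = a if rng.random() < p_a else b
        unchosen = b if chosen == a else a
        mag_chosen = float(row["mag_A"] if chosen == a else row["mag_B"])
        if schedule.task_variant == "two_juices":
            # reward is always delivered; the binary learning signal is the
            # identity of the juice (preferred juice1 = 1, juice2 = 0)
            juice_a = row["juice_of_A"]
            juice_chosen = juice_a if chosen == "A" else (
                "juice2" if juice_a == "juice1" else "juice1")
            rewarded = int(juice_chosen == "juice1")
            reward_ml = mag_chosen
        else:
            p_rew = float(row[f"prob_{chosen}"])
            rewarded = int(rng.random() < p_rew)
            reward_ml = mag_chosen if rewarded else SMALL_REWARD_ML
        v_a_pre, v_b_pre = values[a], values[b]
        vc, vu, pe, assoc = _update(rl_params, values[chosen], values[unchosen],
                                    float(rewarded), assoc)
        values[chosen], values[unchosen] = vc, vu
        side = ("left" if row["a_left"] else "right") if chosen == a else \
               ("right" if row["a_left"] else "left")
        records.append(
            {
                "trial": t,
                "first_object": first,
                "second_object": second,
                "first_mag": float(row["mag_A"] if first == a else row["mag_B"]),
                "second_mag": float(row["mag_A"] if second == a else row["mag_B"]),
                "first_prob": float(row[f"prob_{first}"]),
                "second_prob": float(row[f"prob_{second}"]),
                "V_A": v_a_pre,
                "V_B": v_b_pre,
                "chosen_object": chosen,
                "view_choice": int(chosen == first),
                "side_chosen": side,
                "rewarded": rewarded,
                "reward_ml": reward_ml,
                "pe": pe,
            }
        )
    trials = pd.DataFrame.from_records(records) if records else pd.DataFrame()
    if n > 0:
        extra = sched.reset_index(drop=True)[
            [c for c in sched.columns if c not in trials.columns]
        ]
        trials = pd.concat([trials, extra], axis=1)
    return SessionBehavior(
        schedule=schedule,
        trials=trials,
        session_id=session_id or f"sim-{seed}",
        seed=seed,
        agent_params={"variant": rl_params.variant, "alpha": rl_params.alpha,
                      "beta": rl_params.beta, "mag_weight": rl_params.mag_weight},
    )


# ---------------------------------------------------------------------------
# fitting

def _pack(params: RLParams) -> np.ndarray:
    x = [math.log(params.alpha / (1 - params.alpha)) if 0 < params.alpha < 1 else 0.0,
         math.log(max(params.beta, 1e-6))]
    if params.variant in _2LR_VARIANTS:
        a = params.alpha_neg
        x.append(math.log(a / (1 - a)) if 0 < a < 1 else 0.0)
    if params.variant in _PH_VARIANTS:
        g = params.gamma
        x.append(math.log(g / (1 - g)) if 0 < g < 1 else 0.0)
    return np.asarray(x)


def _unpack(x: np.ndarray, variant: str, mag_weight: float) -> RLParams:
    sig = lambda u: 1.0 / (1.0 + math.exp(-np.clip(u, -500, 500)))
    alpha = sig(x[0])
    beta = math.exp(np.clip(x[1], -500, 50))
    i = 2
    alpha_neg = gamma = None
    if variant in _2LR_VARIANTS:
        alpha_neg = sig(x[i]); i += 1
    if variant in _PH_VARIANTS:
        gamma = sig(x[i]); i += 1
    return RLParams(variant=variant, alpha=alpha, beta=beta,
                    alpha_neg=alpha_neg, gamma=gamma, mag_weight=mag_weight)


def fit_rl(behavior: SessionBehavior, variant: str = "reversal",
           n_restarts: int = 20, seed: int = 0,
           mag_weight: float = 0.0) -> FitResult:
    """Maximum-likelihood fit of one RL variant by restarted Nelder-Mead.

    Parameters are searched on unconstrained scales (learning rates through a
    logistic transform, beta through an exponential) from ``n_restarts``
    random starting points; the best converged solution is returned.  AIC and
    BIC use the number of free parameters of the variant and the trial count.
    """
    if behavior.n_trials < 20:
        raise ValueError("need >= 20 trials to fit")
    if variant not in VARIANTS:
        raise ParameterError(f"unknown RL variant: {variant!r}")
    rng = np.random.default_rng(seed)
    template = RLParams(variant=variant, alpha=0.5, beta=1.0, mag_weight=mag_weight)
    k = template.n_free

    def objective(x: np.ndarray) -> float:
        p = _unpack(x, variant, mag_weight)
        nll, _ = rl_loglikelihood(behavior, p)
        return nll

    best = None
    any_converged = False
    for _ in range(max(n_restarts, 1)):
        start = RLParams(
            variant=variant,
            alpha=float(rng.uniform(0.05, 0.95)),
            beta=float(rng.uniform(0.2, 8.0)),
            alpha_neg=float(rng.uniform(0.05, 0.95)) if variant in _2LR_VARIANTS else None,
            gamma=float(rng.uniform(0.05, 0.95)) if variant in _PH_VARIANTS else None,
            mag_weight=mag_weight,
        )
        res = minimize(objective, _pack(start), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all Nelder-Mead restarts failed")
    params = _unpack(best.x, variant, mag_weight)
    nll = float(best.fun)
    n = behavior.n_trials
    _, state = rl_loglikelihood(behavior, params)
    clamped = int((state.choice_logp <= _LOGP_FLOOR + 1e-12).sum())
    flags = []
    if params.beta < 1e-3:
        flags.append("beta_lower_boundary")
    if params.beta > 1e3:
        flags.append("beta_upper_boundary")
    if params.alpha < 1e-4 or params.alpha > 1 - 1e-4:
        flags.append("alpha_boundary")
    return FitResult(
        params=params,
        neg_loglik=nll,
        aic=2 * k + 2 * nll,
        bic=k * math.log(n) + 2 * nll,
        n_trials=n,
        n_restarts=n_restarts,
        converged=any_converged,
        boundary_flags=flags,
        clamped_trials=clamped,
    )


def compare_models(behaviors: list[SessionBehavior],
                   variants: tuple[str, ...] = VARIANTS,
                   n_restarts: int = 10, seed: int = 0) -> pd.DataFrame:
    """Fit each variant to each session; summed AIC/BIC and winner counts.

    Returns one row per variant with columns ``sum_aic``, ``sum_bic``,
    ``aic_wins``, ``bic_wins`` (per-session winner counts) and ``k``.
    """
    aic = np.zeros((len(variants), len(behaviors)))
    bic = np.zeros_like(aic)
    ks = []
    for i, variant in enumerate(variants):
        for j, beh in enumerate(behaviors):
            fit = fit_rl(beh, variant, n_restarts=n_restarts, seed=seed + 97 * j + i)
            aic[i, j] = fit.aic
            bic[i, j] = fit.bic
        ks.append(RLParams(variant=variant).n_free)
    table = pd.DataFrame(
        {
            "variant": list(variants),
            "k": ks,
            "sum_aic": aic.sum(axis=1),
            "sum_bic": bic.sum(axis=1),
            "aic_wins": (aic == aic.min(axis=0)).sum(axis=1),
            "bic_wins": (bic == bic.min(axis=0)).sum(axis=1),
        }
    ).set_index("variant")
    return table


# ---------------------------------------------------------------------------
# session-level logistic value model

@dataclass
class ObjectValueModel:
    """Session logistic model of object choice and the derived value weights.

    The logistic models ObjectAChosen on ObjectAFirst, the magnitude
    difference (mag_A - mag_B, mL) and the probability difference
    (prob_A - prob_B).  Object value is then the linear combination
    ``value(RM, Prob) = beta_mag * RM + beta_prob * Prob``.
    """

    intercept: float
    beta_first: float
    beta_mag: float
    beta_prob: float
    ridge_flagged: bool = False

    def value(self, magnitude: np.ndarray | float, probability: np.ndarray | float):
        return self.beta_mag * np.asarray(magnitude) + self.beta_prob * np.asarray(probability)


def fit_session_logistic(behavior: SessionBehavior) -> ObjectValueModel:
    """Fit the session choice logistic and derive magnitude/probability weights."""
    import statsmodels.api as sm

    t = behavior.trials
    y = (t["chosen_object"] == "A").to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    cols = [
        np.ones(len(t)),
        (t["first_object"] == "A").to_numpy(dtype=float),
        (t["mag_A"] - t["mag_B"]).to_numpy(dtype=float),
        (t["prob_A"] - t["prob_B"]).to_numpy(dtype=float),
    ]
    # a reward attribute that never varies (e.g. constant probabilities in a
    # magnitude-only variant) carries no information; its weight is fixed at 0
    active = [True] + [np.std(c) > 0 for c in cols[1:]]
    X = np.column_stack([c for c, a in zip(cols, active) if a])
    flagged = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coefs = res.params
        if not np.all(np.isfinite(coefs)) or np.abs(coefs).max() > 50:
            raise np.linalg.LinAlgError("separation")
    except Exception:
        # complete/quasi separation: ridge-stabilized fit, flagged
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(penalty="l2", C=1.0, fit_intercept=False,
                                solver="lbfgs", max_iter=1000)
        lr.fit(X, y)
        coefs = lr.coef_[0]
        flagged = True
    full = np.zeros(4)
    full[np.flatnonzero(active)] = coefs
    return ObjectValueModel(
        intercept=float(full[0]),
        beta_first=float(full[1]),
        beta_mag=float(full[2]),
        beta_prob=float(full[3]),
        ridge_flagged=flagged,
    )


# ---------------------------------------------------------------------------
# optimality grid

@dataclass
class OptimalityMap:
    alphas: np.ndarray
    betas: np.ndarray
    mean_reward_ml: np.ndarray  # shape (n_alpha, n_beta)
    n_reps: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.mean_reward_ml.shape


def optimality_grid(schedules: list[SessionSchedule],
                    alphas: np.ndarray | None = None,
                    betas: np.ndarray | None = None,
                    n_reps: int = 100, seed: int = 0,
                    mag_weight: float = 1.0,
                    probability_only: bool = False) -> OptimalityMap:
    """Mean obtained reward (mL) of the reversal learner over an (alpha, beta) grid.

    Every (alpha, beta) cell simulates the reversal learner ``n_reps`` times
    on each schedule; the map holds the mean delivered volume per trial.  The
    default grid spans alpha in [0, 1] step 0.01 and beta in [0, 5] step 0.05
    (101 x 101 cells).  ``probability_only`` removes cued magnitudes from the
    choice utility.  The simulation is vectorized across grid cells and
    repetitions.
    """
    if not schedules:
        raise ValueError("need at least one schedule")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if alphas is None:
        alphas = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)
    if betas is None:
        betas = np.round(np.arange(0.0, 5.0 + 1e-9, 0.05), 10)
    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    rng = np.random.default_rng(seed)

    a_grid = np.repeat(alphas, len(betas))  # (n_cells,)
    b_grid = np.tile(betas, len(alphas))
    n_cells = a_grid.size
    a = a_grid[:, None]  # broadcast over reps
    b = b_grid[:, None]
    w_mag = 0.0 if probability_only else mag_weight

    total = np.zeros((n_cells, n_reps))
    n_total_trials = 0
    for sched in schedules:
        t = sched.trials
        prob_a = t["prob_A"].to_numpy(dtype=float)
        prob_b = t["prob_B"].to_numpy(dtype=float)
        mag_a = t["mag_A"].to_numpy(dtype=float)
        mag_b = t["mag_B"].to_numpy(dtype=float)
        n = len(t)
        n_total_trials += n
        v_a = np.zeros((n_cells, n_reps))
        v_b = np.zeros((n_cells, n_reps))
        for i in range(n):
            gap = (v_a - v_b) + w_mag * (mag_a[i] - mag_b[i])
            p_choose_a = 1.0 / (1.0 + np.exp(-np.clip(b * gap, -700, 700)))
            chose_a = rng.random((n_cells, n_reps)) < p_choose_a
            p_rew = np.where(chose_a, prob_a[i], prob_b[i])
            rewarded = rng.random((n_cells, n_reps)) < p_rew
            mag_c = np.where(chose_a, mag_a[i], mag_b[i])
            total += np.where(rewarded, mag_c, SMALL_REWARD_ML)
            r = rewarded.astype(float)
            # reversal update, vectorized over cells/reps
            pe_c = r - np.where(chose_a, v_a, v_b)
            pe_u = -r - np.where(chose_a, v_b, v_a)
            v_a = v_a + a * np.where(chose_a, pe_c, pe_u)
            v_b = v_b + a * np.where(chose_a, pe_u, pe_c)
        del v_a, v_b
    mean_ml = (total / n_total_trials).mean(axis=1).reshape(len(alphas), len(betas))
    return OptimalityMap(alphas=alphas, betas=betas, mean_reward_ml=mean_ml, n_reps=n_reps)
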