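"""Three-stage firing-rate circuit for view-based decisions between
sequentially viewed objects.

Stage 1 (value memory): two view-based value populations V1 (negatively
tuned, input 1-V) and V2 (positively tuned, input V) are coupled to
self-exciting memory populations M1/M2 that integrate their drive and feed
back inhibition proportional to the integrated value (integral feedback
control).  After the first object, the sustained inhibition equals the first
value, so the response to the second object encodes the signed value
difference - the comparison signal.

Stage 2 (view-based decision): decision populations C1 ("last-viewed
chosen") and C2 ("currently-viewed chosen") compete through self-excitation
and mutual inhibition (winner-take-all attractor dynamics).  Competition is
gated by a bistable excitatory/inhibitory "switch" whose drive is the
facilitating synaptic input from object-selective neurons; the switch jumps
to its high state during the second cue, so no decision is taken before both
options have been seen.

Stage 3 (expansion recoding): object-sequence populations (X1: object X
seen first; X2: object X seen second), built from short-term synaptic
depression, combine with C1/C2 in threshold "combination" units whose sums
drive a final winner-take-all between object-choice populations, recovering
the chosen object's identity from the view-based choice.

All populations follow first-order rate equations integrated with
Euler-Maruyama; additive Gaussian noise of amplitude eta enters every rate
equation (not the synaptic efficacies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ABLATION_VARIANTS = (
    "classical_simultaneous",
    "no_switch",
    "object_specific_view",
    "positive_tuned_wMC08",
)


class IntegrationError(RuntimeError):
    """Numerical blow-up during integration; carries the trace prefix."""

    def __init__(self, message: str, trace_prefix=None):
        super().__init__(message)
        self.trace_prefix = trace_prefix


@dataclass
class NetworkParams:
    """Connection weights, inputs, transfer functions and integration step.

    Defaults follow the reference parameter set: wMM=1 in units of the
    memory transfer slope (the memory populations are perfect integrators,
    so the self-coupling times the transfer slope equals one; with
    fM(u) = 0.2 [u]+ this makes the raw self-weight 1/0.2 = 5).  Times are
    in ms, rates dimensionless (sigmoid outputs in (0, 1), linear-threshold
    outputs unbounded).
    """

    tau: float = 10.0
    tau_f: float = 500.0
    tau_s: float = 1000.0
    # stage 1: value memory
    w_mv: float = 0.6          # V -> M
    w_vm: float = 0.6          # M -> V (inhibitory in the full model)
    fm_slope: float = 0.2      # k of fM(u) = k [u]+
    w_mm: float = 5.0          # M self-coupling; w_mm * fm_slope = 1 -> perfect integrator
    # stage 2: view-based decision + switch
    w_plus: float = 2.5
    w_minus: float = 2.0
    w_v: float = 0.1           # V -> C input scale
    w_ee: float = 16.0
    w_ei: float = 9.0
    w_ie: float = 10.0
    w_ii: float = 7.0
    # object drive -> switch input b.  The E-I subsystem's saddle-node sits
    # at b* ~ 2.05; with facilitation compounding over the two cue periods
    # (factor e^{k2 t/tau_f}) this weight makes the drive cross the knee
    # ~150 ms into the second cue and never during the first.
    w_b: float = 0.5
    i_e: float = -3.0
    i_i: float = -1.0
    i_0: float = -1.6          # view WTA background; switch output rE adds to it
    alpha_e: float = 1.0       # sigmoid gain, E and C populations
    alpha_i: float = 3.0       # sigmoid gain, I population
    k1: float = 0.015          # synaptic recovery
    k2: float = 1.1            # facilitation
    k3: float = 0.22           # depression
    # stage 3: expansion recoding + object choice
    w_c: float = 0.5           # combination sums -> object WTA
    i_1: float = -1.6          # object WTA background
    f_threshold: float = 1.35  # combination linear-threshold offset
    # simulation
    eta: float = 0.025
    dt: float = 0.5

    def __post_init__(self) -> None:
        if min(self.tau, self.tau_f, self.tau_s) <= 0:
            raise ValueError("time constants must be > 0")
        if self.dt > self.tau / 10:
            raise ValueError("dt must be <= tau/10")

    def sigma(self, u, gain: float = 1.0):
        return 1.0 / (1.0 + np.exp(-np.clip(u / gain, -500, 500)))


@dataclass
class StimulusProtocol:
    """Stimulus schedule for one trial: which objects appear when, and with
    what value input.  Values must lie in [0, 1] (affinely rescale session
    values first).  Timing defaults to the main task (500 ms cues/delays);
    the control tasks use 350 ms."""

    object_values: dict[str, float]
    sequence: tuple[str, str]
    cue_ms: float = 500.0
    delay_ms: float = 500.0
    settle_ms: float = 300.0

    def __post_init__(self) -> None:
        for o, v in self.object_values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"value of {o!r} outside [0, 1]: {v}")
        if len(self.sequence) != 2 or self.sequence[0] == self.sequence[1]:
            raise ValueError("sequence must name two distinct objects")
        for o in self.sequence:
            if o not in self.object_values:
                raise ValueError(f"sequence object {o!r} has no value")

    @property
    def objects(self) -> tuple[str, ...]:
        return tuple(sorted(self.object_values))

    @property
    def total_ms(self) -> float:
        return 2 * (self.cue_ms + self.delay_ms)

    def epoch(self, name: str) -> tuple[float, float]:
        c, d = self.cue_ms, self.delay_ms
        table = {
            "cue1": (0.0, c),
            "delay1": (c, c + d),
            "cue2": (c + d, 2 * c + d),
            "delay2": (2 * c + d, 2 * c + 2 * d),
        }
        return table[name]


@dataclass
class NetworkTrace:
    """Recorded time series of all populations plus the decision readout."""

    time_ms: np.ndarray
    series: dict[str, np.ndarray]
    protocol: StimulusProtocol
    view_choice: str            # "first" | "second" | "undecided"
    object_choice: str          # object id | "undecided"
    margin_view: float
    margin_object: float
    switch_engaged: bool
    seed: int

    def epoch_mean(self, name: str, epoch: str) -> float:
        t0, t1 = self.protocol.epoch(epoch)
        m = (self.time_ms >= t0) & (self.time_ms < t1)
        return float(self.series[name][m].mean())


_VIEW_MODES = {
    # iv1/iv2 construction: "shared" = both pools see the current object's
    # value (full cross-connectivity); "split" = pool 1 is wired to the first
    # listed object only, pool 2 to the second (ablations).
    "full": "shared",
    "no_switch": "shared",
    "object_specific_view": "split_negpos",
    "positive_tuned_wMC08": "split_pospos",
}


def _simulate_batch(
    params: NetworkParams,
    protocols: list[StimulusProtocol],
    seed: int,
    variant: str = "full",
    record: bool = False,
    record_every: int = 4,
    i0_background: float = 0.0,
):
    """Integrate a batch of trials with shared timing/object set.

    Returns (outcomes DataFrame, traces list-or-None).
    """
    if not protocols:
        raise ValueError("no protocols given")
    p0 = protocols[0]
    objs = list(p0.objects)
    for pr in protocols:
        if pr.objects != p0.objects or (pr.cue_ms, pr.delay_ms, pr.settle_ms) != (
            p0.cue_ms, p0.delay_ms, p0.settle_ms,
        ):
            raise ValueError("batch requires shared timing and object set")
    n = len(protocols)
    n_obj = len(objs)
    idx = {o: i for i, o in enumerate(objs)}
    first_i = np.array([idx[pr.sequence[0]] for pr in protocols])
    second_i = np.array([idx[pr.sequence[1]] for pr in protocols])
    v_first = np.array([pr.object_values[pr.sequence[0]] for pr in protocols])
    v_second = np.array([pr.object_values[pr.sequence[1]] for pr in protocols])

    mode = _VIEW_MODES[variant]
    use_expansion = mode == "shared"
    m_sign = 1.0 if mode == "split_pospos" else -1.0
    w_vm = 0.8 if mode == "split_pospos" else params.w_vm
    # positive-feedback memory loop is tuned to neutrality so held activity
    # neither decays nor grows once input is removed
    if mode == "split_pospos":
        w_mm = (1.0 - params.w_mv * params.fm_slope * w_vm) / params.fm_slope
    else:
        w_mm = params.w_mm

    dt, tau = params.dt, params.tau
    eta = params.eta
    # noise enters the rate equations as an additive term, tau dx = (f + eta xi) dt,
    # so the per-step increment is (eta/tau) sqrt(dt) xi  (dt-invariant variance)
    noise_amp = eta * math.sqrt(dt) / tau
    rng = np.random.default_rng(seed)
    relu = lambda u: np.maximum(u, 0.0)
    sig = params.sigma

    c_ms, d_ms, settle = p0.cue_ms, p0.delay_ms, p0.settle_ms
    t_grid = np.arange(-settle, p0.total_ms + dt / 2, dt)
    n_steps = len(t_grid)

    # state
    z = lambda: np.zeros(n)
    V1, V2, M1, M2 = z(), z(), z(), z()
    rE, rI = z(), z()
    wF = np.ones(n)
    C1, C2 = z(), z()
    r = np.zeros((n_obj, n))
    X1, X2 = np.zeros((n_obj, n)), np.zeros((n_obj, n))
    wX1, wX2 = np.ones((n_obj, n)), np.ones((n_obj, n))
    CX1, CX2 = np.zeros((n_obj, n)), np.zeros((n_obj, n))
    CXo = np.zeros((n_obj, n))

    # the final object WTA competes among the trial's presented options; the
    # remaining combination pathways exist but receive no competition gate
    presented = np.zeros((n_obj, n), dtype=bool)
    presented[first_i, trial_ar := np.arange(n)] = True
    presented[second_i, trial_ar] = True

    switch_engaged = np.zeros(n, dtype=bool)
    rec_t: list[float] = []
    rec: dict[str, list[np.ndarray]] = {}
    if record:
        keys = ["V1", "V2", "M1", "M2", "rE", "rI", "wF", "C1", "C2"]
        for o in objs:
            keys += [f"r{o}", f"{o}1", f"{o}2", f"w{o}", f"w{o}2",
                     f"C{o}1", f"C{o}2", f"C{o}"]
        rec = {k: [] for k in keys}

    for step in range(n_steps):
        t = t_grid[step]
        in_cue1 = 0.0 <= t < c_ms
        in_cue2 = c_ms + d_ms <= t < 2 * c_ms + d_ms
        if in_cue1:
            stim_idx, v_now = first_i, v_first
        elif in_cue2:
            stim_idx, v_now = second_i, v_second
        else:
            stim_idx, v_now = None, None

        # stimulus-dependent value inputs
        if stim_idx is None:
            iv1 = iv2 = 0.0
        elif mode == "shared":
            iv1, iv2 = 1.0 - v_now, v_now
        else:
            on0 = (stim_idx == 0).astype(float)
            on1 = (stim_idx == 1).astype(float)
            if mode == "split_negpos":
                iv1, iv2 = (1.0 - v_now) * on0, v_now * on1
            else:  # split_pospos
                iv1, iv2 = v_now * on0, v_now * on1

        # object-selective drive
        I_obj = np.zeros((n_obj, n))
        if stim_idx is not None:
            I_obj[stim_idx, trial_ar] = 1.0

        b = params.w_b * r.sum(axis=0)

        dV1 = (-V1 + m_sign * w_vm * relu(M1) + iv1) / tau
        dV2 = (-V2 + m_sign * w_vm * relu(M2) + iv2) / tau
        fm = lambda u: params.fm_slope * relu(u)
        dM1 = (-M1 + params.w_mv * fm(V1) + w_mm * fm(M1)) / tau
        dM2 = (-M2 + params.w_mv * fm(V2) + w_mm * fm(M2)) / tau

        if variant == "no_switch":
            gate = i0_background
            drE = drI = dwF = 0.0
        else:
            drE = (-rE + sig(params.w_ee * rE - params.w_ei * rI + params.i_e + wF * b,
                             params.alpha_e)) / tau
            drI = (-rI + sig(params.w_ie * rE - params.w_ii * rI + params.i_i,
                             params.alpha_i)) / tau
            # facilitation driven by the presynaptic object drive, so it
            # compounds across successive cue presentations
            dwF = (params.k1 * (1.0 - wF) + params.k2 * r.sum(axis=0) * wF) / params.tau_f
            gate = rE
        I0 = params.i_0 + gate

        dC1 = (-C1 + sig(params.w_plus * C1 - params.w_minus * C2
                         + params.w_v * V1 + I0)) / tau
        dC2 = (-C2 + sig(params.w_plus * C2 - params.w_minus * C1
                         + params.w_v * V2 + I0)) / tau

        dr = (-r + I_obj) / tau
        r_sum = r.sum(axis=0)
        others = r_sum[None, :] - r
        dX1 = (-X1 + wX1 * r + others) / tau
        dX2 = (-X2 + r + wX2 * others) / tau
        dwX1 = (params.k1 * (1.0 - wX1) - params.k3 * X1 * wX1) / params.tau_s
        dwX2 = (params.k1 * (1.0 - wX2) - params.k3 * X2 * wX2) / params.tau_s

        if use_expansion:
            fthr = lambda u: relu(u - params.f_threshold)
            dCX1 = (-CX1 + fthr(X1 + C1[None, :])) / tau
            dCX2 = (-CX2 + fthr(X2 + C2[None, :])) / tau
            sX = CX1 + CX2
            active = CXo * presented
            inh = active.sum(axis=0)[None, :] - active
            # the switch output gates the object WTA as well, so the choice
            # latches through the post-cue2 delay after sX decays
            gate_obj = np.where(presented, gate, 0.0)
            dCXo = (-CXo + sig(params.w_plus * CXo - params.w_minus * inh
                               + params.w_c * sX + params.i_1 + gate_obj)) / tau

        if eta > 0.0:
            noise = noise_amp * rng.standard_normal((8 + 6 * n_obj, n))
            V1 = V1 + dt * dV1 + noise[0]
            V2 = V2 + dt * dV2 + noise[1]
            M1 = M1 + dt * dM1 + noise[2]
            M2 = M2 + dt * dM2 + noise[3]
            if variant != "no_switch":
                rE = rE + dt * drE + noise[4]
                rI = rI + dt * drI + noise[5]
                wF = wF + dt * dwF
            C1 = C1 + dt * dC1 + noise[6]
            C2 = C2 + dt * dC2 + noise[7]
            r = r + dt * dr + noise[8:8 + n_obj]
            X1 = X1 + dt * dX1 + noise[8 + n_obj:8 + 2 * n_obj]
            X2 = X2 + dt * dX2 + noise[8 + 2 * n_obj:8 + 3 * n_obj]
            wX1 = wX1 + dt * dwX1
            wX2 = wX2 + dt * dwX2
            if use_expansion:
                CX1 = CX1 + dt * dCX1 + noise[8 + 3 * n_obj:8 + 4 * n_obj]
                CX2 = CX2 + dt * dCX2 + noise[8 + 4 * n_obj:8 + 5 * n_obj]
                CXo = CXo + dt * dCXo + noise[8 + 5 * n_obj:8 + 6 * n_obj]
        else:
            V1 = V1 + dt * dV1
            V2 = V2 + dt * dV2
            M1 = M1 + dt * dM1
            M2 = M2 + dt * dM2
            if variant != "no_switch":
                rE = rE + dt * drE
                rI = rI + dt * drI
                wF = wF + dt * dwF
            C1 = C1 + dt * dC1
            C2 = C2 + dt * dC2
            r = r + dt * dr
            X1 = X1 + dt * dX1
            X2 = X2 + dt * dX2
            wX1 = wX1 + dt * dwX1
            wX2 = wX2 + dt * dwX2
            if use_expansion:
                CX1 = CX1 + dt * dCX1
                CX2 = CX2 + dt * dCX2
                CXo = CXo + dt * dCXo

        switch_engaged |= rE > 0.5

        if step % 200 == 0:
            peak = max(np.abs(V1).max(), np.abs(M1).max(), np.abs(M2).max(),
                       np.abs(V2).max())
            if peak > 1e3:
                raise IntegrationError(
                    f"rate exceeded 1e3 at t={t:.1f} ms",
                    trace_prefix={"t_ms": t, "V1": V1.copy(), "M1": M1.copy()},
                )

        if record and step % record_every == 0:
            rec_t.append(t)
            for k, arr in (("V1", V1), ("V2", V2), ("M1", M1), ("M2", M2),
                           ("rE", rE), ("rI", rI), ("wF", wF),
                           ("C1", C1), ("C2", C2)):
                rec[k].append(arr.copy())
            for oi, o in enumerate(objs):
                rec[f"r{o}"].append(r[oi].copy())
                rec[f"{o}1"].append(X1[oi].copy())
                rec[f"{o}2"].append(X2[oi].copy())
                rec[f"w{o}"].append(wX1[oi].copy())
                rec[f"w{o}2"].append(wX2[oi].copy())
                rec[f"C{o}1"].append(CX1[oi].copy())
                rec[f"C{o}2"].append(CX2[oi].copy())
                rec[f"C{o}"].append(CXo[oi].copy())

    # readout at end of post-cue2 delay
    dv = C1 - C2
    view_choice = np.where(dv > 0, "first", "second")
    view_choice = np.where(np.abs(dv) < 1e-12, "undecided", view_choice)
    margin_view = np.abs(dv)
    if use_expansion:
        masked = np.where(presented, CXo, -np.inf)
        order = np.argsort(masked, axis=0)
        top, second_best = order[-1], order[-2]
        margin_obj = CXo[top, trial_ar] - CXo[second_best, trial_ar]
        obj_choice = np.array([objs[i] for i in top])
        obj_choice = np.where(margin_obj < 1e-12, "undecided", obj_choice)
    else:
        # object-specific ablations: pool 1 is wired to objs[0], pool 2 to objs[1]
        obj_choice = np.where(dv > 0, objs[0], objs[1])
        obj_choice = np.where(np.abs(dv) < 1e-12, "undecided", obj_choice)
        margin_obj = margin_view

    outcomes = pd.DataFrame(
        {
            "first_object": [pr.sequence[0] for pr in protocols],
            "second_object": [pr.sequence[1] for pr in protocols],
            "v_first": v_first,
            "v_second": v_second,
            "view_choice": view_choice,
            "object_choice": obj_choice,
            "margin_view": margin_view,
            "margin_object": margin_obj,
            "switch_engaged": switch_engaged,
        }
    )

    traces = None
    if record:
        time_ms = np.asarray(rec_t)
        traces = []
        for j in range(n):
            series = {k: np.asarray([frame[j] for frame in v]) for k, v in rec.items()}
            traces.append(
                NetworkTrace(
                    time_ms=time_ms,
                    series=series,
                    protocol=protocols[j],
                    view_choice=str(view_choice[j]),
                    object_choice=str(obj_choice[j]),
                    margin_view=float(margin_view[j]),
                    margin_object=float(margin_obj[j]),
                    switch_engaged=bool(switch_engaged[j]),
                    seed=seed,
                )
            )
    return outcomes, traces


def simulate_trial(params: NetworkParams, protocol: StimulusProtocol,
                   seed: int = 0, record_every: int = 4) -> NetworkTrace:
    """Simulate one trial of the full model and return its trace."""
    _, traces = _simulate_batch(params, [protocol], seed, record=True,
                                record_every=record_every)
    return traces[0]


def simulate_trials(params: NetworkParams, protocols: list[StimulusProtocol],
                    seed: int = 0, record: bool = False,
                    record_every: int = 4, variant: str = "full",
                    i0_background: float = 0.0):
    """Simulate a batch of trials; returns (outcomes DataFrame, traces|None)."""
    return _simulate_batch(params, protocols, seed, variant=variant,
                           record=record, record_every=record_every,
                           i0_background=i0_background)


# ---------------------------------------------------------------------------
# fixed points, bifurcations, regimes

@dataclass
class BifurcationDiagram:
    control: np.ndarray
    fixed_points: list[list[tuple[np.ndarray, bool]]]  # per value: [(state, stable)]
    failed: list[int] = field(default_factory=list)

    def counts(self, i: int) -> tuple[int, int]:
        pts = self.fixed_points[i]
        stable = sum(1 for _, s in pts if s)
        return stable, len(pts) - stable


def _newton_2d(F, J, x0, max_iter=200, tol=1e-12):
    x = np.asarray(x0, dtype=float)
    for _ in range(max_iter):
        f = F(x)
        if np.abs(f).max() < tol:
            return x
        try:
            step = np.linalg.solve(J(x), f)
        except np.linalg.LinAlgError:
            return None
        # damping for robustness
        lam = 1.0
        for _ in range(30):
            xn = x - lam * step
            if np.abs(F(xn)).max() < np.abs(f).max():
                break
            lam *= 0.5
        else:
            return None
        x = xn
    return x if np.abs(F(x)).max() < 1e-9 else None


def _unique(points: list[np.ndarray], tol=1e-5) -> list[np.ndarray]:
    uniq: list[np.ndarray] = []
    for p in points:
        if not any(np.abs(p - q).max() < tol for q in uniq):
            uniq.append(p)
    return uniq


def _fixed_points_2d(F, J, guesses) -> list[tuple[np.ndarray, bool]]:
    roots = []
    for g in guesses:
        x = _newton_2d(F, J, g)
        if x is not None:
            roots.append(x)
    out = []
    for x in _unique(roots):
        eig = np.linalg.eigvals(J(x))
        # J here is the Jacobian of the *dynamics*; stable iff all Re < 0
        stable = bool(np.all(eig.real < -1e-8))
        if np.any(np.abs(eig.real) <= 1e-8):
            continue  # marginal point at a bifurcation; skip rather than mislabel
        out.append((x, stable))
    return out


def switch_bifurcation(params: NetworkParams, b_range: np.ndarray,
                       wf: float = 1.0) -> BifurcationDiagram:
    """Fixed points of the E-I switch subsystem (wF frozen) versus drive b.

    Below the bistable window there is a single stable low-activity state;
    inside it two stable states (low/high) coexist with an unstable saddle;
    above it only the high state survives - the saddle-node structure that
    lets object drive flip the switch on.
    """
    b_range = np.asarray(b_range, dtype=float)
    ae, ai = params.alpha_e, params.alpha_i
    sig = params.sigma

    def make(b):
        def F(x):
            rE, rI = x
            return np.array([
                -rE + sig(params.w_ee * rE - params.w_ei * rI + params.i_e + wf * b, ae),
                -rI + sig(params.w_ie * rE - params.w_ii * rI + params.i_i, ai),
            ])

        def J(x):
            rE, rI = x
            sE = sig(params.w_ee * rE - params.w_ei * rI + params.i_e + wf * b, ae)
            sI = sig(params.w_ie * rE - params.w_ii * rI + params.i_i, ai)
            dE, dI = sE * (1 - sE) / ae, sI * (1 - sI) / ai
            return np.array([
                [-1 + params.w_ee * dE, -params.w_ei * dE],
                [params.w_ie * dI, -1 - params.w_ii * dI],
            ])

        return F, J

    grid = np.linspace(0.0, 1.0, 13)
    guesses = [np.array([a, c]) for a in grid for c in grid]
    fps, failed = [], []
    for i, b in enumerate(b_range):
        F, J = make(b)
        pts = _fixed_points_2d(F, J, guesses)
        if not pts:
            failed.append(i)
        fps.append(pts)
    return BifurcationDiagram(control=b_range, fixed_points=fps, failed=failed)


def decision_regime(params: NetworkParams, i0_range: np.ndarray) -> pd.DataFrame:
    """Classify background input I0 into non-competing vs winner-take-all.

    Fixed points of the symmetric C1/C2 subsystem (no value input): a single
    stable point means the populations co-activate without competing; two
    stable asymmetric attractors (plus a saddle) mean winner-take-all.
    """
    i0_range = np.asarray(i0_range, dtype=float)
    sig = params.sigma

    rows = []
    grid = np.linspace(0.0, 1.0, 13)
    guesses = [np.array([a, c]) for a in grid for c in grid]
    for i0 in i0_range:
        def F(x, i0=i0):
            c1, c2 = x
            return np.array([
                -c1 + sig(params.w_plus * c1 - params.w_minus * c2 + i0),
                -c2 + sig(params.w_plus * c2 - params.w_minus * c1 + i0),
            ])

        def J(x, i0=i0):
            c1, c2 = x
            s1 = sig(params.w_plus * c1 - params.w_minus * c2 + i0)
            s2 = sig(params.w_plus * c2 - params.w_minus * c1 + i0)
            d1, d2 = s1 * (1 - s1), s2 * (1 - s2)
            return np.array([
                [-1 + params.w_plus * d1, -params.w_minus * d1],
                [-params.w_minus * d2, -1 + params.w_plus * d2],
            ])

        pts = _fixed_points_2d(F, J, guesses)
        stable = sum(1 for _, s in pts if s)
        regime = "winner_take_all" if stable >= 2 else "non_competing"
        rows.append({"I0": i0, "n_fixed": len(pts), "n_stable": stable,
                     "regime": regime})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ablations and the many-objects extension

@dataclass
class AblationReport:
    variant: str
    outcomes: pd.DataFrame
    verdict: dict


def _standard_battery(values=(0.2, 0.35, 0.5, 0.65, 0.8), min_gap=0.1):
    """Ordered value pairs with |dV| >= min_gap, both viewing orders."""
    protos = []
    for va in values:
        for vb in values:
            if abs(va - vb) < min_gap or va == vb:
                continue
            protos.append(StimulusProtocol({"A": va, "B": vb}, ("A", "B")))
            protos.append(StimulusProtocol({"A": va, "B": vb}, ("B", "A")))
    return protos


def run_ablation(variant: str, trial_battery: list[StimulusProtocol] | None = None,
                 seed: int = 0, params: NetworkParams | None = None) -> AblationReport:
    """Run an architecture variant over a trial battery and summarize it.

    Variants: ``classical_simultaneous`` (simultaneous value inputs to an
    object-specific attractor pair), ``no_switch`` (background input never
    engages competition), ``object_specific_view`` (cross-connections from
    object values to view pools removed), ``positive_tuned_wMC08`` (both
    pools positively tuned with a weak positive memory weight).
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown ablation variant: {variant!r}")
    params = params or NetworkParams(eta=0.0)
    battery = trial_battery or _standard_battery()

    if variant == "classical_simultaneous":
        out = _classical_simultaneous(params, battery, seed)
        correct = _fraction_higher_value(out)
        verdict = {
            "selects_higher_value": bool(correct == 1.0),
            "fraction_correct": correct,
            "many_objects_capable": False,
            "reason": "one decision pool per object; new objects need new circuits",
        }
        return AblationReport(variant, out, verdict)

    out, _ = _simulate_batch(params, battery, seed, variant=variant)
    if variant == "no_switch":
        decided = (out["margin_view"] > 0.2).mean()
        verdict = {
            "ever_decides": bool(decided > 0),
            "fraction_decided": float(decided),
            "reason": "no excitatory drive: C populations never separate",
        }
    elif variant == "object_specific_view":
        second = (out["object_choice"] == out["second_object"]).mean()
        verdict = {
            "always_second": bool(second == 1.0),
            "fraction_second_chosen": float(second),
            "reason": "no integral feedback: second value faces no memory trace",
        }
    else:  # positive_tuned_wMC08
        correct = _fraction_higher_value(out)
        verdict = {
            "selects_higher_value": bool(correct == 1.0),
            "fraction_correct": correct,
            "many_objects_capable": False,
            "reason": "value pools are object-wired; a third object needs new wiring",
        }
    return AblationReport(variant, out, verdict)


def _fraction_higher_value(out: pd.DataFrame) -> float:
    better = np.where(out["v_first"] > out["v_second"],
                      out["first_object"], out["second_object"])
    return float((out["object_choice"].to_numpy() == better).mean())


def _classical_simultaneous(params: NetworkParams, battery, seed: int) -> pd.DataFrame:
    """Two object-specific attractor pools with simultaneous value input."""
    rng = np.random.default_rng(seed)
    sig = params.sigma
    dt, tau, eta = params.dt, params.tau, params.eta
    namp = eta * math.sqrt(dt) / tau
    rows = []
    i0_on = -0.6  # inside the winner-take-all window of the C subsystem
    for pr in battery:
        objs = list(pr.objects)
        va, vb = pr.object_values[objs[0]], pr.object_values[objs[1]]
        ca = cb = 0.0
        n_settle = int(pr.settle_ms / dt)
        n_stim = int(pr.cue_ms / dt)
        n_post = int(pr.delay_ms / dt)
        for phase, n_steps in (("settle", n_settle), ("stim", n_stim), ("post", n_post)):
            on = phase != "settle"
            ia = params.w_v * va if phase == "stim" else 0.0
            ib = params.w_v * vb if phase == "stim" else 0.0
            i0 = i0_on if on else 0.0
            for _ in range(n_steps):
                dca = (-ca + sig(params.w_plus * ca - params.w_minus * cb + ia + i0)) / tau
                dcb = (-cb + sig(params.w_plus * cb - params.w_minus * ca + ib + i0)) / tau
                if eta > 0:
                    ca += dt * dca + namp * rng.standard_normal()
                    cb += dt * dcb + namp * rng.standard_normal()
                else:
                    ca += dt * dca
                    cb += dt * dcb
        margin = abs(ca - cb)
        choice = objs[0] if ca > cb else objs[1]
        if margin < 1e-12:
            choice = "undecided"
        rows.append({
            "first_object": objs[0], "second_object": objs[1],
            "v_first": va, "v_second": vb,
            "view_choice": "simultaneous", "object_choice": choice,
            "margin_view": margin, "margin_object": margin,
            "switch_engaged": True,
        })
    return pd.DataFrame(rows)


def simulate_many_objects(params: NetworkParams, object_values: list[float],
                          pair: tuple[int, int], sequence: tuple[int, int],
                          seed: int = 0, record: bool = False):
    """Choice between one ordered pair drawn from a larger object set.

    The view-based stage is shared across all objects; the object-sequence
    and combination stages carry one unit pair per object.  ``pair`` and
    ``sequence`` index into ``object_values``; the chosen object's index is
    returned together with the outcome row (and trace if requested).
    """
    n_obj = len(object_values)
    if n_obj < 2:
        raise ValueError("need at least 2 objects")
    if sorted(sequence) != sorted(pair):
        raise ValueError("sequence must order the given pair")
    for i in pair:
        if not 0 <= i < n_obj:
            raise ValueError(f"pair id {i} not in object set")
    names = [f"O{i}" for i in range(n_obj)]
    values = {names[i]: float(object_values[i]) for i in range(n_obj)}
    proto = StimulusProtocol(values, (names[sequence[0]], names[sequence[1]]))
    out, traces = _simulate_batch(params, [proto], seed, record=record)
    row = out.iloc[0]
    chosen = row["object_choice"]
    chosen_id = names.index(chosen) if chosen in names else None
    result = {
        "chosen_id": chosen_id,
        "view_choice": row["view_choice"],
        "margin_object": float(row["margin_object"]),
        "switch_engaged": bool(row["switch_engaged"]),
    }
    if record:
        result["trace"] = traces[0]
    return result
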