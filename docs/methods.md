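# Methods

This note documents the models implemented in `viewchoice`, the parameter
choices that matter, the reasoning behind the genuinely open design
decisions, and the limits of what the synthetic pipeline can show.

## Task and behavioral models

**Task generator.** A main-task session presents two objects, A and B, one
after the other (500 ms cue, 500 ms inter-stimulus delay, 500 ms second cue,
500 ms delay, then a targets period). Each object carries an uncued reward
probability drawn from {0, .15, .35, .5, .65, .75, .85, 1}, constant within
blocks of 15–40 trials and redrawn independently per object at each block
boundary, and a trial-wise cued magnitude drawn iid from {0.25, 0.4, 0.65}
mL (the two objects may share a magnitude). Unrewarded trials deliver a
0.05 mL consolation volume; the binary reward code used by the learning
models is R = 1 for the cued magnitude and R = 0 for the consolation drop.
Viewing order and left/right target assignment are balanced in expectation.
Two control variants exist: a probability-only task with four objects in
two sets (0.85/0.15, reversing between the objects across blocks of 25–35
trials) and a two-juices task in which reward is always delivered and the
binary learning signal is the identity of the juice, with the object–juice
association reversing twice per session.

**RL family.** Seven delta-rule variants: basic (chosen option only),
reversal (the unchosen option is updated with −R, suited to anti-correlated
blocked reversals), two-learning-rate versions of both (separate α for
rewarded and unrewarded trials), and Pearce–Hall versions in which the
effective rate is α·a_t with associability a_{t+1} = γ|δ_t| + (1−γ)a_t,
a_0 = 1, γ fitted. Initial values are 0 with no free initial-value
parameter. Choices follow a softmax on the value difference; an optional
`mag_weight` adds the cued magnitude difference (mL) to the choice utility
so that simulated agents use both value sources, while the likelihood
defaults to the pure value softmax. Log-probabilities are floored at
ln(1e-12) (counted, flagged) so extreme β cannot produce −inf.

**Fitting.** Maximum likelihood by Nelder–Mead over transformed parameters
(rates through a logistic map, β through an exponential), 20 random restarts
by default, tolerance 1e-6 on the objective. Estimates pinned at a boundary
(β below 1e-3, α within 1e-4 of 0/1) are flagged rather than hidden. AIC =
2k + 2·negLL and BIC = k·ln n + 2·negLL hold as identities, with k the
variant's free-parameter count and n the trial count.

**Session values.** A per-session logistic of "object A chosen" on viewing
order, the magnitude difference and the probability difference yields the
weights β₂ (per mL) and β₃ (per unit probability); object value is
β₂·RM + β₃·Prob. Attributes with zero session variance are dropped with
weight 0; separated sessions fall back to a ridge-stabilized fit and are
flagged. For use as circuit input or tuning argument, values are affinely
mapped to [0, 1] by the session min/max — the circuit's admissible input
range. A magnitude-only value component on the same kind of scale is also
provided for analyses that must avoid learned-value anti-correlation.

**Optimality grid.** The reversal learner is simulated over α ∈ [0, 1] step
0.01 and β ∈ [0, 5] step 0.05 (101 × 101 cells), vectorized across cells and
repetitions; each cell reports mean delivered volume per trial. A
probability-only mode removes magnitudes from the utility.

## The decision circuit

All populations obey first-order rate equations with τ = 10 ms, integrated
by Euler–Maruyama at dt = 0.5 ms (validated against a 10× finer step at
zero noise).

**Stage 1 — value memory.** View pools receive stimulus-locked inputs
I_V1 = 1 − V_X, I_V2 = V_X for whichever object X is on screen and are
inhibited by memory pools (weight w_VM = 0.6) that integrate them (weight
w_MV = 0.6 through fM(u) = 0.2[u]+). The memory self-coupling is set to the
perfect-integrator condition w_MM · 0.2 = 1, i.e. a raw self-weight of 5:
with a leaky self-coupling the stored inhibition would decay with an
effective time constant of ~12 ms and could not bridge the 500 ms delay, so
the integral-feedback comparison — the mechanism the whole circuit depends
on — requires the integrator form. After the first cue the inhibition
converges to the first value (integral feedback); the pools' delay activity
is therefore *reversed* in value tuning, and their second-cue response
encodes the signed value difference.

**Stage 2 — gated view-based decision.** C1/C2 compete through
σ(w₊C_i − w₋C_j + w·V_i + I0) with w₊ = 2.5, w₋ = 2, w = 0.1 and
σ(u) = 1/(1+e^{−u}). Fixed-point analysis of this pair shows a
winner-take-all window I0 ∈ (≈−0.85, ≈0.4): below it a single low
"non-competing" state, inside it two attractors plus a saddle, above it a
single co-active state. The gating therefore works by *background offset*:
both winner-take-all stages receive a constant background of −1.6 plus the
switch output r_E, so rest sits below the window and the switch-on state
(−1.6 + r_E ≈ −0.6) sits inside it. The E–I switch (w_EE = 16, w_EI = 9,
w_IE = 10, w_II = 7, I_E = −3, I_I = −1, inhibitory gain 3) is bistable
with a saddle-node at drive b* ≈ 2.05 (located by continuation). Its drive
is the object signal b = w_b(r_A + r_B) through a facilitating efficacy
dw_F/dt = [k₁(1−w_F) + k₂(r_A+r_B)w_F]/τ_F (k₁ = 0.015, k₂ = 1.1, τ_F =
500 ms): facilitation is driven by the presynaptic object rate so it
*compounds across the two cue presentations*, and with w_b = 0.5 the drive
crosses the knee ~150–250 ms into the second cue and never during the
first. This is the package's own gating calibration: the three constants
involved (the perfect-integrator self-weight, the background offset, and
w_b with presynaptic facilitation) were set by the fixed-point analysis
above so that the circuit exhibits its defining behaviors — no premature
decision during the first cue, cue2-locked competition, and a latched
choice through the post-cue2 delay.

**Stage 3 — expansion recoding.** Object-sequence units X1 = w_X1·r_X +
Σ_{Y≠X} r_Y (and the mirrored X2) with postsynaptic short-term depression
dw/dt = [k₁(1−w) − k₃·X·w]/τ_s (k₃ = 0.22, τ_s = 1 s) respond during the
second cue preferentially when their object appeared first (X1) or second
(X2). Combination units f(X_i + C_j) with f(u) = [u − 1.35]+ conjoin
sequence and view choice; their sums s_X = C_X1 + C_X2 drive a final
winner-take-all over object pools (w_c = 0.5, background I₁ = −1.6 plus the
switch gate), which latches the chosen object's identity through the
post-cue2 delay. For the many-objects extension the view stage is shared,
sequence/combination units are instantiated per object, and the final
competition is gated only for the trial's presented pair: with a single
postsynaptic depression efficacy per unit, "seen first" is identified by
exclusion, which is unambiguous within the presented pair but degenerate
over never-shown objects.

**Noise.** Additive Gaussian noise of amplitude η = 0.025 enters every rate
equation (not the synaptic efficacies) as a term inside the equation,
τ dx = (f + ηξ)dt, giving per-step increments (η/τ)√dt·ξ. This
discretization is dt-invariant and leaves the switch barrier ~13 noise SDs
away, so decisions stay cue2-locked while equal-value trials are resolved
by noise at chance; adding η√dt directly to the state instead produces
premature stochastic switch flips and chance-level accuracy even for easy
value differences, contradicting the circuit's intended behavior.

**Readout and ties.** View choice is the larger of C1/C2 at the end of the
post-cue2 delay, object choice the larger of the gated object pools; exact
equality at zero noise is reported as "undecided" rather than resolved
arbitrarily. Rates above 1e3 abort integration with the trace prefix
attached. The facilitation variable rests at 1 and grows to at most ~9
within a trial (by construction of the compounding drive); the depression
efficacies stay in (0, 1].

**Ablations.** Four variants: a classical simultaneous-input attractor pair
(selects the higher value; no extension to new objects), a no-switch
variant (the background never enters the winner-take-all window; no
decision is ever taken), object-specific view pools (cross-connections from
object values to both view pools removed; the second option always wins
because no memory trace opposes it), and a positively tuned object-specific
variant with a weak positive memory weight of 0.8 whose loop is tuned to
neutrality so held activity neither decays nor grows (selects the higher
value for two objects, but each object needs its own wired pathway).

## Synthetic recordings

**Populations.** Functional type counts are multinomial draws from a
configurable mixture (defaults roughly mirroring the recorded prevalences:
~21% object-value, ~30% view-value, ~26% view-choice cells). Baseline rates
are log-normal across neurons (median 5 Hz, σ = 0.6) — the field's usual
heavy-tailed choice; recorded baseline distributions were not available, so
these are module parameters, not claims. Gains are log-normal (median 8 Hz
per value unit or choice contrast), latencies uniform in 50–150 ms, and
nucleus labels follow the recorded sample proportions with a mild planted
topography (object-value cells weighted toward dLA, view-based cells toward
BL).

**Spike counts.** Rates come either from a parametric tuning model (each
type modulates its epoch with its gain, latency-shifted) or from the
circuit's population traces (view-value cells follow V1/V2, view-choice
cells C1/C2, sequence cells X1, combination cells their combination unit,
object-choice cells the object pools; object-value cells follow the
object-selective drive scaled by the object's value). Emission is Poisson
per 20-ms bin on a fixed grid from −1000 to +2500 ms around the first cue;
fixed epochs (500 ms each: pre-fixation control, fixation, cue1, delay1,
cue2, delay2, targets) are exact sums of their bins, so fixed-window and
sliding-window analyses see consistent counts. Negative post-tuning rates
are clipped at zero and counted. Outside the simulated span, circuit traces
are clamped to their endpoint values — so the latched choice attractors
extend into the targets epoch and the pre-trial grid sees resting rates.

**Eye traces.** Gaze is sampled uniformly (250 Hz default), dwell positions
jittered and quantized to a tracker resolution so within-fixation samples
are flat. Fixations are maximal runs with speed (central differences) below
25% of the trace's speed SD lasting over 60 ms; a motionless trace (zero
speed SD) counts entirely as one fixation. Fixations starting within 100 ms
of a stimulus onset are flagged excluded as anticipatory.

## Analysis statistics

**GLMs.** Ordinary least squares with two-sided t tests, standardized
coefficients x_i·s_i/s_y, overall F, and per-regressor partial R² =
(SSE_reduced − SSE_full)/SSE_reduced. Rank-deficient designs raise an error
naming the collinear columns. Design builders reproduce the task codings:
view-based choice (1 = first-viewed chosen), object choice (1 = A), viewing
order (1 = A-then-B), per-option values/probabilities/magnitudes, sides;
+1/−1/0 block contrasts for the four-objects task (side regressors
omitted); juice choice/order regressors for the two-juices task. Epoch
activity is z-scored against the pre-fixation control period; zero-SD
neurons are excluded and listed.

**Angle classification.** The first-cue response is regressed on the two
object values — from each object's own first-viewed trials when viewing
labels are supplied (avoiding dilution), jointly otherwise — gated by the
overall F at p < 0.05. The standardized-coefficient plane splits into eight
half-open 45° segments ([θc − 22.5°, θc + 22.5°), boundaries assigned
counter-clockwise): segments toward 0°/180° are object-A value, 90°/270°
object-B value, 45°/225° view-based value with uniform sign, 135°/315°
view-based with opposing sign. Classification needs both objects' value
ranges to be comparable; short sessions with few blocks can leave one
object's range compressed, tilting standardized coefficients toward the
wider-range object.

**Sliding windows.** 200-ms windows stepped by 20 ms from 500 ms before the
first cue to 500 ms after target onset, each fit by OLS (batched). A neuron
is significant for a regressor if more than nine consecutive windows reach
p < 0.05; the threshold can be re-derived per neuron from trial-shuffled
data (the smallest run length fewer than 5% of shuffles exceed). Because
adjacent windows overlap by 90%, null runs are longer than an
independent-Bernoulli bound would suggest; the calibrated threshold lands
near, sometimes one above, nine. A structural note on this calibration:
once a shuffled regressor chance-correlates with a neuron's trial-level
rate modulation, the significance persists across every window the
modulation spans plus the window width, so each modulation event
contributes roughly the per-window alpha to the neuron's pass probability,
and cells with responses at both cues contribute twice. On this generator's
corpora (strong, clean modulations) the empirical false-positive rate of
the more-than-nine rule therefore sits at ~5-6% rather than strictly below
5%; the per-window tests themselves are exactly calibrated. Weaker, more
heterogeneous effect sizes — as in recorded data — push the rate below the
nominal level. Value-to-choice transitions are scored by
run onsets (first window of the qualifying run) within the second-cue span:
the verdict is true iff a significant value run starts before the
significant choice run. The tuning-reversal statistic is a one-proportion
z = (p̂ − 0.5)/√(0.25/n) on sign flips between epochs, two-sided; the
value-comparison statistic is the across-neuron Pearson correlation of
first- vs second-option value coefficients, which must come from regressors
uncorrelated across options (magnitude-only components for learned values;
the generator's session values are themselves uncorrelated across objects
because block probabilities are drawn independently).

**Decoding.** Pseudo-populations pool each neuron's per-group trials and
rematch them randomly per repetition; each group's matrix size is the
smallest per-neuron trial count, and neurons under the minimum (5/10/15)
are excluded and listed. Classifiers: a linear maximum-margin SVM (C = 1,
solved by liblinear — orders of magnitude faster than the kernel QP on
shuffled data — with the one-vs-one kernel form retained for the 4-class
conjunction decoder) and a nearest-neighbor rule (nearest single trial, or
nearest leave-one-out group mean for the nucleus variant) with distance
ties broken by the lowest trial index. Accuracy is leave-one-out (an 80/20
split mode exists), aggregated as mean over matching repetitions with SD;
significance is a two-sided rank-sum against label-shuffled repetitions
(1,000 by default). Cross-condition decoding trains in one viewing sequence
and tests in the other; the `invert_by_sequence` rule swaps the test
labels, which recovers object choice from a view-based code. Difficulty
terciles split trials by ranked |ΔV| (ties by trial order, so counts are
exact). Sample-size curves subsample neurons without replacement.

**RSA.** Condition-mean population vectors are normalized per neuron and
correlated across neurons. Templates: identity; same-object; view-based
value (levels coded −2.25, −0.75, 0.75, 2.25, similarity = pairwise
products; an ordinal-distance variant treats adjacent levels as equally
similar); object value (elementwise product of the object and value
templates); same-object-choice; both-first view choice (plus a same-view
partition variant); both-left choice. The full matrix is vectorized
(diagonal included; unique-cells mode available) and regressed jointly on
the templates, which therefore compete for variance. Inference permutes the
condition rows — equivalently relabels the correlation matrix — 10,000
times; critical |t| thresholds are per template (the identity template is
permutation-invariant, so pooling nulls across templates would be wrong),
and coefficient differences use the permuted t-difference distribution.
Value quartiles use stable ranks with ties broken by trial order. Two
structural caveats of this inference at small condition counts: (i)
correlation-based similarity saturates at ±1, so product-form value
templates fit best while condition means still carry trial noise — nearly
noise-free corpora produce sign-like matrices the product templates only
approximate; (ii) joint row permutation limits each template's attainable p
to the fraction of relabelings reproducing its structure (e.g. ~0.029 for a
4/4 object partition over 8 conditions), so coarse partition templates
cannot reach very strict alpha levels no matter how strong the fit; finer
templates (graded value products) can.

## Problem sizes

Default study conditions: sessions of 150 trials (300 where both objects'
value ranges must equilibrate, e.g. classifier-recovery checks); corpora of
45–233 neurons; circuit batteries over value pairs {0.2, 0.35, 0.5, 0.65,
0.8} with both viewing orders; calibrations with 200 shuffled neurons,
1,000 null GLM fits, and 200 null RSA corpora at 1,000 permutations;
recovery over 100 sessions of 300 trials (5 Nelder–Mead restarts, which
recover α to a median error well under 0.1) and 20 logistic sessions. The
acceptance script runs all of this from one seed in a few minutes.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analyses assume —
block-wise probabilities, independent per-object attributes, Poisson
spiking around type-defined rates, circuit-locked dynamics — but not
several properties of real recordings: no cross-neuron noise correlations
(neurons are conditionally independent given the trial), no spike-history
or adaptation effects, no drift or non-stationarity across a session, no
eye-movement-linked rate modulation, and sessions share one trial grid
(real pseudo-populations pool neurons recorded in different sessions; the
pools-based builder covers that case structurally). Passing tests therefore
show that the implementations are correct and calibrated on data satisfying
their assumptions, not that real amygdala recordings satisfy them. Known
model limitations: the circuit has no targets-epoch dynamics (attractors
are clamped beyond the simulated span, so view-choice signals persist into
the targets period rather than handing off as transiently as in recordings),
the value-tuning strength during the memory period depends on the chosen
memory–view coupling, and the many-objects extension identifies "seen
first" only within the presented pair.
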