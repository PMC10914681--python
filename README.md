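# viewchoice

A tested, fully synthetic pipeline for studying **view-based value
decisions**: how a decision between two *sequentially viewed* reward options
can be computed in an abstract reference frame ("choose the currently viewed
vs. the last-viewed option") and only afterwards mapped back onto object
identity. The package is written for computational and systems
neuroscientists who want to simulate the behavior, the circuit, and the
population analyses of this paradigm end to end, with every number
reproducible from a seed.

It provides four tightly coupled layers:

1. **Task & behavior** (`task`, `rl`) — sessions of ~150 trials with two
   sequentially cued objects, block-wise reward probabilities drawn from
   {0, .15, .35, .5, .65, .75, .85, 1} in blocks of 15–40 trials, and
   trial-wise cued magnitudes {0.25, 0.4, 0.65} mL. A family of
   reinforcement-learning agents; the central *reversal* learner updates
   both options,

   V_A(t+1) = V_A(t) + α(R_t − V_A(t)),  V_B(t+1) = V_B(t) + α(−R_t − V_B(t)),

   with softmax choice P(A) = 1/(1 + e^{−β(V_A−V_B)}). Maximum-likelihood
   fitting (restarted Nelder–Mead with smooth parameter transforms),
   AIC/BIC model comparison, a session-level logistic value model
   (value = β₂·RM + β₃·Prob), and a vectorized (α, β) optimality grid
   (101 × 101 cells).

2. **Decision circuit** (`circuit`) — a three-stage firing-rate network:
   *integral-feedback value memory* (view pools V1/V2 coupled to
   self-exciting memory pools M1/M2, so the response to the second object
   encodes the signed value difference), a *winner-take-all view-based
   decision* (C1/C2 with self-excitation w₊ = 2.5 and mutual inhibition
   w₋ = 2, gated by a bistable E–I switch whose facilitated object drive
   crosses its saddle-node only during the second cue), and *expansion
   recoding* (object-sequence units built from short-term synaptic
   depression feed combination units f(X_i + C_j) whose sums drive a final
   object winner-take-all). Plus fixed-point/bifurcation analysis, four
   architecture ablations, and a many-objects extension.

3. **Synthetic recordings** (`population`, `spikes`, `eye`) — populations of
   the functional cell types (object-value, view-based value, view-based
   choice, object-choice, object-sequence, combination, untuned) across
   amygdala nuclei (dLA, vLA, BL, BM, CE); Poisson spike counts on a 20-ms
   grid from either a parametric tuning model or the circuit's population
   traces; gaze traces with velocity-threshold fixation detection.

4. **Analyses** (`glm`, `encoding`, `decoding`, `rsa`, `workbench`) — the
   statistics used to test the circuit's predictions: value/choice GLMs with
   standardized coefficients and partial R², angle-based value-cell
   classification, sliding-window regression with a permutation-calibrated
   consecutive-window criterion, tuning-reversal and value-anticorrelation
   tests, pseudo-population SVM/nearest-neighbor decoding with leave-one-out
   CV, cross-condition generalization and sequence recoding, conjunction and
   difficulty-tercile decoding, template-based RSA with 10,000-permutation
   inference, and a one-config experiment runner.

## Worked example

`python examples/circuit_single_trial.py` simulates one noise-free trial in
which the first object is worth 0.2 and the second 0.8:

```
view choice   : second (C1 vs C2 margin 0.42)
object choice : B (CA vs CB margin 0.47)
switch engaged 234 ms into the second cue

population epoch means (rate units):
  V2   +0.05  -0.19  +0.16  -0.77
  M2   +0.24  +0.33  +1.05  +1.31
  rE   +0.01  +0.01  +0.55  +1.00
  C2   +0.18  +0.19  +0.39  +0.63
  CB   +0.18  +0.18  +0.38  +0.67
```

Columns are the cue1 / delay1 / cue2 / delay2 epoch means. V2 (the
positively tuned view pool) responds to value at the first cue, is pushed
*below* baseline during the delay by the memory pool's inhibition — the
reverse tuning that stores the first value — and its second-cue response
then reflects the value difference. The switch (rE) jumps ~230 ms into the
second cue, the view-based pair resolves toward C2 ("currently viewed
chosen"), and the object stage latches CB: object B, the higher-value
option, is chosen.

`python examples/population_decoding.py` shows the population-level
signature on a circuit-driven corpus of 45 synthetic neurons: view-based
choice decodes across viewing sequences (88.6% within, 69.4% cross, far
above chance), while object choice decodes at 27.7% across sequences —
systematic inversion — and recovers to 68.0% once the decoder's labels are
recoded by sequence. The other examples cover model comparison, bifurcation structure
and ablations, value-cell classification, value RSA, and the one-call
experiment runner.

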