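# Methods

`adaptgait` implements an event-triggered locomotion-intent recognition
pipeline for a powered knee/ankle prosthesis, together with the online
self-training loop that adapts it to a new user or a new day, and a synthetic
gait simulator that supplies test data with the statistical structure the
method assumes.  This note records the model, the parameter choices, the
numerical decisions, and what the synthetic experiments do and do not show.

## The recognition problem

A prosthesis state machine samples 17 mechanical channels at 500 Hz and emits
gait events (heel contact, toe off) on 30 ms frame boundaries.  At each
trigger of interest (TOI; here, heel contacts) the system must decide which
of five locomotion modes the user is in: standing (ST), level-ground walking
(LW), stair ascent (SA), stair descent (SD), or ramp descent (RD); ramp
ascent shares impedance parameters with level walking and is folded into LW.

Two window kinds feed classifiers built on the same 102-element feature
vector — six statistics per channel (mean, sample standard deviation, min,
max, initial value, final value) times 17 channels:

* **Forward prediction**: the 300 ms (150-sample) half-open window ending at
  the TOI.  This is the real-time control decision; at a heel contact the
  window contains only late swing.
* **Backward estimation**: the full heel-contact-to-heel-contact stride,
  accepted when it spans 300–3000 ms.  It sees both stance and swing and is
  therefore the more accurate, retrospective judgement of what the user just
  did.

### Label convention

A heel-contact trigger carries the mode and step type of the stride that
*ends* at it.  Both the forward window thrown at that trigger (late swing of
that same stride) and the backward window closing there then share one
well-defined target, which is what the self-training update requires.  On
synthetic template data there are no anticipatory swing cues, so a
"predict-the-upcoming-step" reading would make transitional steps
unclassifiable by construction; the completed-stride convention is the one
under which both window kinds are informative.  Steps are steady-state (SS)
when the mode repeats the previous stride's mode and transitional (T)
otherwise.

## Classifiers

Both window kinds are classified by a single-hidden-layer feedforward
network: 102 inputs → 20 tanh hidden units → 5 softmax outputs.  The
monitored training error is the mean cross-entropy of the posteriors (the
output layer and loss are this package's choice; only the hidden activation
is fixed by the method).  Weights and biases are initialized uniformly in
(−1/√fv, +1/√fv) where fv = 102 is the input count, i.e. ±0.099.

**Offline training** uses Møller's scaled conjugate gradient (SCG), full
batch, at most 1000 epochs (one SCG iteration per epoch, accepted or not),
with a break clause when training-error improvement plateaus at a precision
of 0.001.  Numerical choices:

* σ₀ = 1e-4 and initial λ = 1e-6 (standard published defaults); λ grows on
  rejected steps and shrinks (×0.25) on well-modeled ones.  Following the
  original algorithm, the curvature estimate δ persists across rejected
  iterations and accumulates the λ increments, so repeated rejections shrink
  the step until it is accepted.  If λ exceeds 1e15 the trust region has
  collapsed to numerical noise and training stops.
* The plateau clause compares consecutive *accepted* losses and requires
  three consecutive sub-0.001 improvements (patience 3).  A rejected step
  leaves the loss unchanged by construction, and single sub-threshold
  improvements occur transiently mid-run for conjugate-gradient methods;
  patience 1 was observed to stop training at wildly variable quality
  (final losses 0.05–0.5 across inits on identical data).
* Inputs are standardized per feature (z-score fitted on the SCG training
  set, floored at 1e-8, stored with the weights).  Raw features of magnitude
  ~3 intermittently saturate the tanh layer and SCG then stalls at the class
  prior; standardization is the conventional conditioning fix and travels
  with the weights so online prediction and adaptation see identical inputs.
* Biases follow the same uniform initialization rule as weights.

**Online adaptation** uses plain full-batch gradient descent from the current
weights: learning rate 0.01, at most three epochs per update, stopping early
if the loss improvement falls below the same 0.001 precision.

## The self-training loop

Replaying a session in time order: at each TOI the forward window is
classified with the current forward weights and, in adaptation mode, its
features are buffered.  When a stride closes (heel contact to heel contact)
and passes the 300–3000 ms gate, the backward window is classified by the
backward network; that prediction becomes the pseudo-label against which the
buffered forward features of that stride are trained by gradient descent.
Updated weights take effect from the next TOI, never retroactively.  The
buffer is cleared at every stride close, including rejected strides, so stale
features never leak into a later update.  Control mode performs the forward
predictions only and never touches the weights.

Forward and backward classifiers are separate weight sets, both trained
offline; only the forward set is adapted.  The backward classifier is the
label source — adapting it on its own outputs would let the supervision
drift.  A `shared_weights` switch routes backward estimation through the
(adapting) forward weights for comparison with the single-classifier reading
of the loop.  No confidence gating is applied to pseudo-labels: an erroneous
backward estimate does train the forward classifier toward a wrong target,
which is a documented limitation of self-training generally.

## The synthetic study

No recording of the original protocol is public, so the simulator generates
the study shape instead: four subjects (one left-side, three right-side),
four sessions each, sessions 1–3 for training and the drifted session 4 for
pseudo-online testing.  All simulator parameters are synthetic inventions
aimed at controllability and separability, not biomechanical realism.

Mode signatures are smooth curves over normalized stride phase built from
frozen per-channel constants: a baseline, a strictly positive "posture
pattern" p, an oscillation with two harmonics, and two scalar mode
coordinates — a *level* s_m along p (ST −0.9, LW 0.0, SA 0.6, SD −0.6,
RD 0.3) and a stance-gated *amplitude* a_m (LW 1.0, SA 1.6, SD 0.5, RD 1.35;
ST is quasi-static at 0.05 everywhere).  The amplitude contrast is expressed
through a sin⁴(πt) envelope that is near zero over the last ~20 % of the
cycle.  Two consequences define the geometry:

* The forward window (late swing) sees almost none of the amplitude
  signature and must lean on the posture level — which is exactly what
  session drift (a constant added to every channel, hence largely along p)
  corrupts.
* The backward window measures the amplitude signature over the whole cycle
  almost noiselessly, so backward estimation stays accurate under drift and
  qualifies as a pseudo-label source.  This realizes, in a controlled way,
  the claim that full-stride windows containing stance information support
  more accurate retrospective classification than swing-only windows.

Randomness enters as: white sample noise (SD 0.3), a per-stride scalar level
jitter along p (SD 0.18 in mode-level units — stride-to-stride execution
variability that does not average away within a window and sets the class
margins), stride durations uniform on 810–1410 ms snapped to 30 ms frames
(swing fraction 0.4), a first-order Markov mode sequence (redraw probability
0.3 from the mix ST 38 / LW 46 / SA 5 / SD 7 / RD 5 %, renormalized from the
published rounded percentages that sum to 101), per-subject channel offsets
(SD 0.15), gains (lognormal SD 0.05) and a coherent subject level along p
(SD 0.1), and a session drift of 0.1 per session (session 4 sits at 0.3,
roughly one adjacent-mode gap).  Because the protocol being emulated
deliberately exercised every activity in every session, any mode absent from
a drawn chain has a two-stride bout spliced in (never when the transition
rate is zero, which denotes a deliberate single-activity session).

Default problem sizes — 200 strides per session, 4 subjects, 4 sessions —
were chosen so that rare modes receive enough training support for stable
fits while a full user-dependent (DC) and leave-one-subject-out
user-independent (IC) grid over three cumulative session blocks remains a
desk-scale computation.

### What the synthetic experiments show, and what they do not

On this study the package reproduces the qualitative orderings of the
original results: adaptation lowers the step-weighted error in every block
for both DC and IC grouping; cumulative blocks lower it within every arm;
ramp descent, the nearest neighbor of walking, is the hardest class;
transitional steps err more than steady-state ones.  Absolute error rates
are properties of the synthetic geometry (drift magnitude versus jitter) and
are *not* comparable to the error percentages reported for the real
four-subject data, which depend on private recordings.  The simulator also
omits: anticipatory swing kinematics before transitions, user reaction to
classifier behavior (the original study was open-loop too), EMG, and any
realistic channel correlation structure.

## Evaluation conventions

Classification error is per predicted step (per TOI).  Reports carry
steady-state and transitional error separately plus the step-count-weighted
average, and a 5×5 confusion matrix in row percentages derived from counts.
Cross-subject summaries are mean and SEM (sample n−1 standard deviation over
√n), computed per subject first — matching error-bar-style summaries rather
than pooling steps across subjects.  Mixed-effects inference is out of
scope; the result table keeps per-subject rows so external tools can be
applied.  Times written "7h35" parse as hours + minutes/60.

## Known limitations

* Self-training inherits backward-estimation mistakes; with a badly trained
  backward network adaptation can hurt, and no gating defends against it.
* The 85/15 stratified split uses largest-remainder rounding with ties
  broken in canonical mode order; any consistent convention works.
* The completed-stride label convention makes "forward prediction"
  retrospective by one step on synthetic data (see above); conclusions about
  anticipatory intent recognition on real sensors are outside what these
  simulations can support.
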