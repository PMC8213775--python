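# Methods

## Model

The network is a set of `N` current-based leaky integrate-and-fire
neurons with exponential synapses.  Between events the state obeys the
linear free dynamics

    tau_mem dV/dt = -V + I,      tau_syn dI/dt = -I,

with the leak potential at zero and membrane potentials measured in
units of the threshold (theta = 1).  When a firing neuron `n` reaches
threshold with nonzero slope, its potential resets to zero and every
neuron's synaptic current jumps by column `n` of the recurrent weight
matrix `W` (zero diagonal — no self-connections).  Fixed input spikes
add columns of the input weight matrix to `I` at prescribed times.
Neurons can be marked non-firing (`firing_mask`), turning them into
leaky integrators used as voltage readouts.  Feed-forward layers are
expressed as block-structured `W`; there is no separate layer engine.

Both experiments use tau_mem = 20 ms and tau_syn = 5 ms.  The
degenerate case tau_mem = tau_syn (alpha kernel) is rejected: the
closed-form solution used throughout is a two-exponential expression
whose coefficients diverge there.

## Event-driven forward pass

Integration between events is the exact closed form

    I(t0+d) = I0 exp(-d/tau_syn)
    V(t0+d) = (V0 - A) exp(-d/tau_mem) + A exp(-d/tau_syn),
    A = I0 tau_syn / (tau_syn - tau_mem),

so the only numerical error in the simulator is the localisation of
threshold crossings.  Crossings are found per inter-event window by
scanning the closed form on a grid of spacing tau_syn/20 and declaring a
bracket only on a sign change of V - theta; the bracket is refined by
Brent's method to an absolute time tolerance of about 1e-12 ms (plain
bisection as fallback).  Consequences of the sign-change rule: a
membrane potential that peaks tangentially *at* the threshold does not
spike — this is the measure-zero critical set where the transition
condition dV/dt != 0 fails, and treating it as a non-crossing gives a
deterministic rule.  A crossing narrower than one grid cell (potential
rising above threshold and back inside ~0.25 ms) would be missed; with
the time constants above this requires finely tuned cancellation and
was never observed.

Events at numerically equal times are processed input-spikes-first, then
threshold crossings in ascending neuron index.  Current jumps commute,
so this ordering affects only replay determinism, not the state.
Coincident threshold crossings are collected against the pre-transition
state (each firing neuron's cached pre-reset current and slope refer to
the state before any of the coincident resets).  A configurable spike
cap (default 1e6) aborts runaway activity.

Each recorded spike caches the firing neuron's pre-reset current
`I_minus` and slope `Vdot_minus = (-theta + I_minus)/tau_mem`.  Together
with the spike times, this is the entire forward state the backward pass
needs for spike-time losses: memory is O(S) in the number of spikes.

## Adjoint backward pass

The adjoint pair (lambda_V, lambda_I) is integrated from T to 0 with
terminal condition zero, using the closed form of the linear
reverse-time system between events.  At the k-th recorded spike of
neuron n, only that neuron's lambda_V jumps:

    lam_V-[n] = lam_V+[n] + ( theta lam_V+[n]
                + (W^T (lam_V+ - lam_I))[n] + dl_p/dt_k ) / (tau_mem Vdot-)

lambda_I and all other lambda_V components are continuous; both facts
are asserted by tests.  The W^T product uses rows of W — i.e. the error
arriving at the firing neuron sums the *outgoing* weights times the
postsynaptic error signals — an index convention cross-checked against
the finite-difference oracle.  With the zero-diagonal invariant,
excluding or including the m = n term is equivalent.

The gradient accumulates `-tau_syn * lambda_I[j]` into `dL/dw_ji`
whenever neuron `i` spikes, and into input-weight entries whenever the
corresponding channel spikes.  The backward sweep is a reverse traversal
of the merged event queue (recurrent spikes, input spikes, voltage-loss
jumps); within one numerically identical time stamp the order is
voltage jumps, then spike jumps (each coincident jump computed from the
shared pre-jump adjoint state), then input spikes — mirroring the
forward ordering.

When a spike's cached |Vdot_minus| falls below `eps_crit = 1e-8`, the
jump denominator is near zero: the weight vector sits next to a critical
point where a spike appears or disappears and the exact gradient
diverges.  The library emits a warning and continues (no clipping by
default, matching the training recipe); an optional norm clip is
available on the optimizer side for user experiments.

## Loss heads

**First-spike-time cross-entropy** (`ttfs`).  Per sample, with `t_k` the
first spike time of output neuron `k` and `l` the label:

    loss = -log softmax(-t/tau0)[l] + alpha (exp(t_l / tau1) - 1)

with defaults tau0 = 0.5 ms, tau1 = 6.4 ms, alpha = 3e-3.  The softmax
term depends only on relative spike times; the exponential term pushes
the label neuron's spike early.  The analytic derivative with respect to
each *first* spike (later spikes carry none) feeds the adjoint jump.
A neuron that never fires enters the softmax with probability zero
(t = +infinity).  If the *label* neuron is silent the sample has no
spike to differentiate through: it contributes a configurable constant
(`missing_penalty`, default 100) to the reported loss and zero
gradient.  The constant is a reporting convention, not part of the
method — with the non-quiescent initialisation below the case is rare
after the first epochs.

**Max-over-time voltage cross-entropy** (`max_over_time`).  Softmax over
each non-firing readout's voltage maximum.  The maximum of the
double-exponential closed form is computed analytically per inter-event
segment (interior extremum plus endpoints; earliest time on ties).
Writing max_t V_k as sampling V_k with a Dirac delta at the maximum
time turns each readout's contribution into a single lambda_V jump at
its own t*, of magnitude

    (1{k=l} - softmax_k) / (tau_mem * N_batch)

applied during the backward traversal (the forward-time adjoint jump is
+dl/dV/tau_mem; traversing backward subtracts it — the sign was pinned
down analytically on a one-neuron system and confirmed by the
finite-difference oracle).  The magnitudes sum to zero across readouts.
Terms involving the derivative of the delta vanish because dV/dt = 0 at
an interior maximum; a maximum attained exactly at an event-time corner
is a measure-zero case handled by a fixed processing order.

## Data

**Yin-Yang task.**  Two interlocking semicircular lobes split a disc of
radius 0.5 into "yin" and "yang" regions, and two small discs (radius
0.1) on the vertical midline form a third "dot" class.  Points are
rejection-sampled uniformly on the disc with the target class cycling
0, 1, 2 so counts are balanced; coordinates are rescaled to [0, 1]^2.
The class predicate is unit-tested against an independent restatement,
and a logistic regression on the encoded features is checked to stay
well under 90 % — the task requires a hidden layer.  Train, validation
and test sets use seeds derived independently from the run seed.

**Latency encoding.**  A sample (x, y) becomes four spikes at
(x, 1-x, y, 1-y) * t_max on channels 0-3 plus a fixed bias spike at
t_bias on channel 4 (defaults t_max = 30 ms, t_bias = 0).  MNIST pixels
with value 0 or 1 of 255 emit nothing; the rest spike at
t_max (1 - v/255) — brighter pixels earlier.  The direction of that
mapping is a convention, not forced by the task; `invert_mnist` flips
it.  During MNIST training each input spike is independently dropped
with probability p_drop = 0.2.

## Training

Two-layer networks are assembled as hidden LIF neurons (driven by the
input weights) plus output neurons driven by the hidden->output block of
the recurrent matrix; outputs fire for the spike-time loss and are
non-firing integrators for the voltage loss.  Weights are Gaussian per
block with the reference statistics (Yin-Yang: hidden 1.5 +/- 0.78,
output 0.93 +/- 0.1; MNIST: 0.078 +/- 0.045 and 0.2 +/- 0.37, read as
raw per-weight parameters without fan-in scaling).  This initialisation
is deliberately non-quiescent — the untrained network fires on
essentially every sample, so spike-time gradients exist from the start
and no rate regularisation is needed (a test asserts >= 95 % of encoded
samples drive at least one hidden spike at initialisation).

Optimisation is bias-corrected Adam (beta1 = 0.9, beta2 = 0.999,
eps = 1e-8, eta = 5e-3) with the learning rate decayed by 0.95 per
epoch; minibatches of 32 (Yin-Yang) or 5 (MNIST).  The 1/N_batch factor
lives in the loss heads, so summed per-sample gradients are exactly the
batch gradient (asserted).  The bias-spike column is trained like any
other input weight.  Classification: earliest output spike (ties to the
lowest class index) for the spike-time loss, largest voltage maximum
for the voltage loss.  Validation accuracy selects the best epoch; test
accuracy is reported both there and at the final epoch.  The simulation
horizon is T = 45 ms for Yin-Yang (t_max = 30 ms plus roughly one
membrane time constant of settling) and 30 ms for MNIST (t_max =
20 ms); epoch counts default to 300 (Yin-Yang) and 100 (MNIST).

The test suite exercises a scaled-down Yin-Yang configuration — 120
hidden neurons, 1000/300/1000 train/validation/test samples, 15 epochs,
one seed — chosen so a full run finishes in minutes on one core while
still clearing 90 % test accuracy with margin (a representative run
reaches ~95-96 %); the published-scale configuration (200 hidden, 5000
samples, 300 epochs, 10 seeds, ~98 %) is available through the same
entry points.

## Verification strategy

Three mutually independent routes are compared: (1) the event-driven
simulator plus adjoint sweep, (2) central finite differences through
full simulations, (3) a dense explicit-Euler discretisation.  The Euler
oracle checks forward spike times (first-order convergence is itself
asserted); the differencer checks gradients.  The differencer carries a
mandatory spike-count guard: if a perturbed run changes any neuron's
spike count, a spike was created or destroyed between the two
evaluations, the implicit-function-theorem premise fails, and the entry
is flagged critical and excluded rather than silently averaged.
Default step is eps = 1e-4 * max(|w|, 1); comparisons pass across
eps in {1e-5, 1e-4, 1e-3}.  For gradient entries of very small
magnitude a plain quotient is rounding-noise limited, so the oracle
also exposes a Richardson-extrapolated variant (quotients at eps and
eps/2 combined to cancel the O(eps^2) term) used where 1e-6 relative
agreement is asserted.  The bouncing-ball fixture (closed-form ballistic
flight, exact impact times, reflection v+ = -0.8 v-) checks the
sensitivity-jump conditions of hybrid systems independently of any
neural quantity: the height-sensitivity ratio across an impact is
exactly -restitution.

## Numerical choices and limitations

- Crossing tolerance 1e-9 (threshold units) for collecting coincident
  crossings; event times resolved to ~1e-12 ms; both far below any
  quantity compared in tests.
- Spike trains with nondecreasing times are required; equal-time events
  follow the fixed ordering above.
- The gradient is exact only away from critical points; training ignores
  them (no clipping), which matches the recipe used here but means loss
  spikes can occur when a spike appears or disappears mid-training.
- The simulator is plain NumPy on one core; per-sample cost is
  milliseconds at the scales above, and very large networks or very
  dense activity would need a compiled event loop.
- Refractory periods, adaptive thresholds, conductance synapses,
  transmission delays and stochastic neurons are out of scope.
- MNIST files are never downloaded; the reader accepts standard IDX
  (optionally gzipped) files on disk.
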