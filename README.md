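# eventprop

Exact, event-based backpropagation for spiking neural networks of leaky
integrate-and-fire (LIF) neurons.

## The problem

Training spiking networks by gradient descent is complicated by the hard
firing threshold: the membrane potential is reset discontinuously at
spike times, so naive automatic differentiation does not apply.  This
package implements the adjoint-method solution for the current-based LIF
network

```
tau_mem dV/dt = -V + I        tau_syn dI/dt = -I
(V)_n = theta, (dV/dt)_n != 0   =>   (V+)_n = 0,  I+ = I- + W e_n
```

Treating the network as a hybrid dynamical system and applying the
implicit function theorem at each threshold crossing yields an *adjoint
spiking network* — a pair of error signals (λ_V, λ_I) integrated in
reverse time with a jump of the firing neuron's λ_V at every recorded
spike:

```
(λ_V-)_n = (λ_V+)_n + [ theta (λ_V+)_n + (Wᵀ(λ_V+ − λ_I))_n + ∂l_p/∂t_post ]
                      / ( tau_mem · (dV/dt)- )
```

The exact loss gradient for a weight then samples the *post-synaptic*
neuron's λ_I at the times spikes were transmitted across that weight:

```
dL/dw_ji = − tau_syn · Σ_{spikes from i} (λ_I)_j
```

The backward pass is a reverse traversal of the forward event queue and
needs only the spike times and pre-reset synaptic currents from the
forward pass — memory O(number of spikes), no dense state history.  The
gradient is exact up to floating point everywhere except the measure-zero
critical set where spikes appear or vanish (there it diverges, which the
library detects and reports).

The package provides:

* an event-driven forward simulator (closed-form integration between
  events, root-bracketed threshold crossings),
* the reverse-time adjoint sweep with per-spike jumps and exact gradient
  accumulation,
* two loss heads — cross-entropy over first output spike times (with an
  early-spiking regulariser) and cross-entropy over max-over-time
  voltages of non-firing readouts,
* latency-encoded datasets: a procedurally generated Yin-Yang task and an
  MNIST IDX reader,
* Adam training with per-epoch learning-rate decay, a scikit-learn style
  `EventPropClassifier`, and independent verification oracles (central
  differences, dense Euler simulation, a bouncing-ball hybrid system).

## Worked example

Compute an exact gradient and verify it against central differences on a
two-neuron benchmark (neuron A receives 100 Poisson spike trains at
200 Hz and drives neuron B through one weight; the loss is the sum of
B's spike times):

```python
from eventprop.experiments import gradient_check_experiment

result = gradient_check_experiment(seed=0, n_input_weights=20)
print(result.n_spikes_a, result.n_spikes_b, result.max_rel_error)
```

prints

```
3 1 8.71602223459804e-09
```

— neuron A fired 3 times, B once, and the worst relative deviation
between the adjoint gradient and the central-difference estimate over 21
weights was about 9e-9.  The same machinery is available from the shell
as `eventprop gradcheck --seed 0 --out gc/`, which writes a per-weight
CSV report.

Training the spiking classifier on the Yin-Yang task (three interlocked
classes on a disc, not linearly separable — a shallow classifier stops
near 64 %):

```python
from eventprop import RunConfig, train

run = RunConfig(n_hidden=120, epochs=15, n_train=1000, n_val=300,
                n_test=1000, seed=1)
res = train(run)
print(res.best_epoch, res.test_acc_best)
```

prints (about three minutes on one core)

```
13 0.954
```

— the network classifies by which output neuron spikes first and reaches
~95 % test accuracy, far above the shallow-classifier ceiling.  The full
published configuration (200 hidden neurons, 5000 training samples, 300
epochs, 10 seeds) reaches ~98 % but takes hours; `eventprop
train-yinyang --config cfg.yaml` runs it.  MNIST training with the
max-voltage loss is available via `eventprop train-mnist --data-dir ...`
(IDX files must be supplied locally; this is a long-running optional
experiment).

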