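# lsmnet

Simulation and analysis of a **non-spiking linear-summation neuron model
(LSM) with dynamic leak**, and of fully recurrent excitatory/inhibitory
networks built from it.

Recurrent E/I circuitry is ubiquitous in the brain but is prone to
self-generating spurious high-frequency activity that is absent from its
sensory input. This package provides the modeling stack needed to study that
phenomenon and its mitigation: the LSM neuron, reference spiking
(Izhikevich) and simplified conductance-based neurons, pseudo-random
PSP-convolved sensory inputs, a fully reciprocally connected two-layer E/I
network with randomized weights and conduction delays, and
continuous-wavelet-transform frequency-power analysis. It is aimed at
computational neuroscientists studying recurrent-network stability and
rate-model design.

## The model

The LSM neuron's instantaneous activity is a normalized signed sum of its
weighted synaptic inputs:

```
A_nodyn = Σᵢ(wᵢ·aᵢ) / (k_static·i + Σᵢ|wᵢ·aᵢ|),        A ≥ 0
```

where `aᵢ` is the activity of input `i`, `wᵢ` its weight (positive for
excitatory, negative for inhibitory afferents), `i` the number of synapses
and `k_static` the static-leak constant. The denominator models the leak
conductance plus activity-dependent shunting and bounds the output strictly
below 1 a.u. The optional **dynamic leak** adds the membrane RC low-pass:

```
τ_dyn · dA_dyn/dt = −A_dyn(t) + A_nodyn(t),     τ_dyn = 10 ms
```

integrated with the exact exponential update. The steady state of the
companion conductance-based model (`dV/dt = −g_leak·V + g_exc(1−V) +
g_inh(−1−V)`, implicit Euler) equals `A_nodyn` when `g_leak = k_static·i`,
which anchors the LSM in membrane biophysics.

The default network is the "5 × 4" architecture — five excitatory and five
inhibitory neurons in layer 1, four of each in layer 2, all pairs
reciprocally connected, six pseudo-random 50-Hz sensors projecting to
layer 1 — driven by 50 jittered (±10 ms) 1-second presentations
concatenated into one 50,000-ms input.

## Worked example

```python
from lsmnet.experiments import (InputConfig, make_sensor_block,
                                network_condition_summary, run_leak_sweep)
from lsmnet.network import NetworkSpec

cfg = InputConfig(rate_hz=50.0, n_presentations=10)
_, signals = make_sensor_block(cfg, seed=1)

for leak in (False, True):
    summary, trace = network_condition_summary(
        NetworkSpec(seed=1), use_dynamic_leak=leak, config=cfg,
        signals=signals, freq_range=(150.0, 500.0))
    print(f"dynamic leak={leak}:  mean max power >200 Hz = "
          f"{summary.band_power((200.0, 500.0)):.3e}")

sweep = run_leak_sweep(config=cfg, seed=1)
print(sweep[sweep.parameter == "tau_dyn"].to_string(index=False))
```

prints

```
dynamic leak=False:  mean max power >200 Hz = 2.295e-06
dynamic leak=True:  mean max power >200 Hz = 8.397e-07
parameter  value       cv
  tau_dyn    1.0 0.216653
  tau_dyn    3.0 0.207875
  tau_dyn   10.0 0.174463
  tau_dyn   30.0 0.130655
  tau_dyn  100.0 0.104843
```

The first two lines show the leak's "rescue" effect: the recurrent network
without dynamic leak carries roughly 2.7× more activity power above 200 Hz
than the same network with the 10-ms leak. The sweep shows the smoothing
cost of that filtering: the coefficient of variation (σ/mean) of an isolated
neuron's output falls monotonically as τ_dyn grows, i.e. stronger leak means
less preserved signal dynamics.

A command-line interface covers the same ground:

```bash
lsmnet gen-input --rate 50 --presentations 50 --seed 1 --out inputs/
lsmnet simulate-network --no-dynamic-leak --mean-delay 4 --seed 1 --out run/
lsmnet analyze --in run/trace.csv --out run/summary.csv
lsmnet reproduce fig4 --seed 1 --scale desk --out out/
```

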