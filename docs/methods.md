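# Methods

## Neuron models

**Linear summation model (LSM).** The neuron is non-spiking: its output is
interpreted as the probability-density-like activity of an ensemble of
similarly connected spiking neurons. The instantaneous drive is

    A_nodyn = Σ(wᵢ·aᵢ) / (k_static·i + Σ|wᵢ·aᵢ|)

with the numerator the signed weighted input sum and the denominator the
static leak (`k_static·i`, leak constant × afferent synapse count) plus the
activity-dependent shunting term. Both `A_nodyn` and the filtered `A_dyn`
are thresholded at zero. Because the denominator exceeds the absolute value
of the numerator by at least `k_static·i > 0`, the output lies in `[0, 1)`
for every finite input — the bound the acceptance script fuzzes.

Inhibition enters as negative signed terms in the numerator and as absolute
values in the denominator; this is the discrete analogue of an inhibitory
conductance pulling the membrane toward a −1 reversal potential while
shunting other inputs.

**Dynamic leak.** `τ_dyn·dA_dyn/dt = −A_dyn + A_nodyn` is a first-order
low-pass with cutoff `1/(2πτ_dyn)` ≈ 16 Hz at the default `τ_dyn = 10 ms`
(1/100 s). We integrate it with the exact exponential update
`A ← D + (A−D)·e^(−dt/τ)`, which is unconditionally stable and exact for
piecewise-constant drive; a forward-Euler mode exists for comparisons.
Note that any fixed-step discretization deviates from the continuous
transfer function `1/√(1+(2πfτ)²)` near the Nyquist frequency: at
`dt = 1 ms` the discrete gain at 400 Hz is ≈1.8× the continuous value, so
closed-form comparisons are made at `dt = 0.1 ms`, where the two agree to
within a few percent up to 500 Hz.

**Izhikevich reference neuron.** Standard quadratic membrane plus linear
recovery variable, forward-Euler at `dt = 1 ms`, spike cutoff +30 mV with
reset `v ← c`, `u ← u + d`. Defaults are the regular-spiking set
(a=0.02, b=0.2, c=−65, d=8, gain k=300). The exploration grid is the full
Cartesian product a∈{0.02,0.07,0.1} × b∈{0.2,0.225,0.25} × c∈{−65,−55,−50}
× d∈{2,4,8} × k∈{100..500} — 405 settings; desk-scale comparisons use an
evenly thinned 27-point subset. The neuron's spike output is convolved with
the same PSP kernel as the inputs so its trace is comparable with the LSM's.
Divergence (|v| > 10⁶) raises rather than silently saturating.

**Simplified conductance-based model.** `dV/dt = −g_leak·V + g_exc(e_exc−V)
+ g_inh(e_inh−V)` with unit capacitance and reversal potentials normalized
to ±1. The implicit-Euler step
`V' = (V + dt(g_exc·e_exc + g_inh·e_inh)) / (1 + dt(g_leak+g_exc+g_inh))`
is unconditionally stable (the update is a convex combination of V and
values inside (−1, 1)); the constant-conductance solution is a single
exponential relaxation toward
`V_ss = (g_exc−g_inh)/(g_leak+g_exc+g_inh)`. Identifying `g_leak =
k_static·i` and the conductances with `|wᵢ·aᵢ|` makes `V_ss` equal the LSM
drive — the formal link between the two models, asserted in tests.

## Sensory inputs

Spike trains are drawn with an exact count — `round(rate·duration/1000)`
distinct integer-millisecond times sampled uniformly without replacement —
rather than as a Poisson process, so the average rate is exact by
construction. Per-presentation variability is uniform ±10 ms jitter of each
spike (a Gaussian option with σ = max_jitter/2 exists but is not default).
Presentations are concatenated without reset and the concatenated train is
convolved once, so PSP tails cross presentation boundaries. Jitter
collisions are deduplicated: a spike train is a set of times.

The PSP kernel `k(t) = τ_km/(τ_kd−τ_kr)·[e^(−t/τ_kd) − e^(−t/τ_kr)]` uses
τ_kd = 4 ms, τ_kr = 12.5 ms, τ_km = 21.3 ms, τ_kl = 0. As printed, the
"decay" constant is shorter than the "rise" constant; the formula is
implemented exactly as given (the prefactor is negative and the bracket
negative for t > 0, so the kernel is non-negative, peaks at ≈6.70 ms with
amplitude ≈1, and integrates to τ_km). The kernel is defined as zero before
the latency (causality) and truncated where its amplitude falls below 10⁻⁶
of the peak.

## Network

Two layers, fully reciprocally connected (100% connection probability, one
synapse per ordered pair); sensors project to layer 1 only. Weight
magnitudes are i.i.d. Gaussian (truncated at zero by resampling), log-normal
(moment-matched so the arithmetic mean is μ and CV is 20%) or binary
(Bernoulli(p)); the sign of every synapse follows the presynaptic neuron's
class. Sensor weights are drawn from the same distribution. The afferent
count `i` includes sensors for layer-1 neurons (default 17+6 = 23) and only
recurrent afferents for layer 2 (17); with autapses each neuron gains one
self-synapse whose sign matches its own class.

The simulation is a synchronous discrete-time loop at `dt = 1 ms`: each
neuron reads the sensors' current samples and the other neurons' activities
at `t − delay`, with a minimum delay of one step — instantaneous mutual
coupling would otherwise be algebraically circular. Conduction delays are
uniform on `[0.5, 1.5]×mean`, rounded to steps. τ_dyn may be scaled with
the synapse count (constant, √(i/i_ref), or i/i_ref, with i_ref = 23 so the
default network keeps τ = 10 ms under every mode).

## Frequency analysis

Continuous wavelet transform with an analytic Morlet (ω₀ = 6, pywt
`cmor2.0-0.954930`), 12 voices per octave over 1–500 Hz. For each frequency
the maximum squared magnitude within each 1-s presentation window is taken;
samples whose cone of influence (√2·scale) crosses the trace boundary are
excluded, and fully masked windows are NaN and dropped from aggregation.
Summaries aggregate by the mean across windows and, for networks, across
neurons. The zero-lag correlation is the coefficient-normalized inner
product `Σxy/√(Σx²Σy²)` (no mean subtraction), and CV is σ/mean of the full
trace.

Wavelet choice: a MATLAB-default generalized Morse wavelet would shift
absolute power values; only relative and directional spectral comparisons
are treated as meaningful here, and the wavelet name is recorded in the
summary metadata.

## Problem sizes

The default experiment protocol (50 presentations, 5 weight redraws,
405-point IZ grid) is what the full-scale drivers run. The test suite and
the desk-scale CLI mode exercise the same code paths at reduced sizes
chosen to keep a complete run on one CPU to about a minute: 5–10
presentations for unit-level checks, the full 50 presentations and 5
redraws for the leak-rescue comparison, a 27-point IZ subgrid for the
fidelity comparison, and 10 presentations for the conduction-delay sweep.

## Known limitations

- With the normalized drive above, an autapse adds one synapse to the
  static-leak denominator; in our simulations this slightly *damps* total
  and high-band power rather than amplifying it. Strong autapse-driven
  amplification of high-frequency components therefore does not reproduce
  under this update scheme; the autapse variant is still implemented and
  bounded, and only its boundedness is asserted.
- The default μ = 0.4 Gaussian network transmits the input's relative
  high-frequency content roughly unchanged (ratio ≈ 0.96–1.0 of the input's
  normalized high-band fraction); clear self-generated excess above the
  input appears only for stronger-weight regimes (e.g. μ = 0.5) and, most
  visibly, as delay-induced supplementary spectral peaks. The leak-rescue
  effect (no-leak ≫ leak above 200 Hz) and the delay-peak shift are robust
  across seeds and are the effects the acceptance tests assert.
- The synthetic sensory input is stationary (fixed per-presentation spike
  count, stateless jitter); real sensory streams are neither stationary nor
  rate-exact, so passing tests demonstrate model behavior under the stated
  protocol, not performance on physiological recordings.
- Layer-2 neurons receive near-balanced excitation and inhibition and can
  sit below the output threshold for entire runs; analyses that normalize
  per neuron skip silent neurons.
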