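"""Fully recurrent two-layer excitatory/inhibitory network of LSM neurons.

Connectivity rules: sensory inputs project as excitatory synapses to all
layer-1 neurons only; all excitatory and inhibitory neurons are fully
reciprocally connected within and between layers (100% connection
probability, one synapse per ordered pair, no self-connections unless
autapses are enabled).  The default "5 x 4" architecture has five excitatory
and five inhibitory neurons in layer 1, four of each in layer 2, and six
sensors.

Weight magnitudes are drawn i.i.d. from a Gaussian, log-normal or binary
distribution; the sign of each synapse is set by the presynaptic neuron's
class (excitatory +, inhibitory -; sensor synapses always excitatory).
Optional conduction delays are randomized per connection.  The dynamic-leak
time constant can be scaled with each neuron's synapse count (constant,
square-root or linear scaling) to emulate larger neurons having longer
membrane time constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .neurons import LSMParams

__all__ = [
    "WeightDistributionSpec",
    "NetworkSpec",
    "NetworkBundle",
    "NetworkTrace",
    "build_network",
    "simulate_network",
    "scale_tau",
]


@dataclass(frozen=True)
class WeightDistributionSpec:
    """Synaptic weight-magnitude distribution.

    ``family`` is one of gaussian / lognormal / binary.  For gaussian and
    lognormal, ``mu`` is the mean magnitude and ``cv`` the coefficient of
    variation in percent (sigma = cv/100 * mu).  For binary, ``p`` is the
    probability of a unit weight (the rest are zero).
    """

    family: str = "gaussian"
    mu: float = 0.4
    p: float = 0.3
    cv: float = 20.0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "lognormal", "binary"):
            raise ValueError(f"unknown weight family {self.family!r}")
        if self.family == "binary" and not (0.0 <= self.p <= 1.0):
            raise ValueError("binary probability p must lie in [0, 1]")
        if self.family != "binary" and self.mu <= 0:
            raise ValueError("mean weight mu must be positive")

    def draw(self, rng: np.random.Generator, size: int | tuple) -> np.ndarray:
        if self.family == "gaussian":
            sigma = self.cv / 100.0 * self.mu
            w = rng.normal(self.mu, sigma, size=size)
            # magnitudes are non-negative; resample the (rare) negative draws
            bad = w < 0
            while bad.any():
                w[bad] = rng.normal(self.mu, sigma, size=int(bad.sum()))
                bad = w < 0
            return w
        if self.family == "lognormal":
            s2 = np.log1p((self.cv / 100.0) ** 2)
            return rng.lognormal(np.log(self.mu) - s2 / 2.0, np.sqrt(s2), size=size)
        return (rng.random(size=size) < self.p).astype(float)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and randomization parameters of the recurrent network."""

    layer1_exc: int = 5
    layer1_inh: int = 5
    layer2_exc: int = 4
    layer2_inh: int = 4
    n_sensors: int = 6
    include_autapses: bool = False
    weight_spec: WeightDistributionSpec = field(default_factory=WeightDistributionSpec)
    mean_delay_ms: float = 0.0
    delay_halfwidth_frac: float = 0.5
    tau_scaling: str = "constant"
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.layer1_exc, self.layer1_inh, self.layer2_exc, self.layer2_inh):
            if n <= 0:
                raise ValueError("layer sizes must be positive")
        if self.n_sensors <= 0:
            raise ValueError("n_sensors must be positive")
        if self.tau_scaling not in ("constant", "sqrt", "linear"):
            raise ValueError(f"unknown tau_scaling {self.tau_scaling!r}")

    @property
    def n_neurons(self) -> int:
        return self.layer1_exc + self.layer1_inh + self.layer2_exc + self.layer2_inh

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weight_spec"] = asdict(self.weight_spec)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        ws = d.pop("weight_spec", {})
        return cls(weight_spec=WeightDistributionSpec(**ws), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class NetworkBundle:
    """Realized connectivity: weights, signs, delays, sensor projections."""

    spec: NetworkSpec
    weights: np.ndarray           # (n, n) non-negative magnitudes, [post, pre]
    signs: np.ndarray             # (n,) +1 excitatory / -1 inhibitory, per presynaptic neuron
    delays_ms: np.ndarray         # (n, n) conduction delays
    sensor_weights: np.ndarray    # (n, n_sensors), nonzero only for layer-1 rows
    layer: np.ndarray             # (n,) 1 or 2
    is_excitatory: np.ndarray     # (n,) bool
    n_synapses: np.ndarray        # (n,) afferent synapse count per neuron

    def export_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.weights).to_csv(out / "weights.csv", index=False)
        pd.DataFrame(self.delays_ms).to_csv(out / "delays_ms.csv", index=False)
        pd.DataFrame(self.sensor_weights).to_csv(out / "sensor_weights.csv", index=False)
        meta = {
            "signs": self.signs.tolist(),
            "layer": self.layer.tolist(),
            "is_excitatory": self.is_excitatory.tolist(),
            "n_synapses": self.n_synapses.tolist(),
            "spec": self.spec.to_dict(),
        }
        (out / "network_meta.json").write_text(json.dumps(meta, indent=2))


@dataclass
class NetworkTrace:
    """Per-neuron activity over the full simulation (rows: time, cols: neuron)."""

    activities: np.ndarray
    dt: float
    layer: np.ndarray
    is_excitatory: np.ndarray

    @property
    def n_neurons(self) -> int:
        return self.activities.shape[1]

    def neuron_labels(self) -> list[str]:
        return [
            f"L{l}{'E' if e else 'I'}{i}"
            for i, (l, e) in enumerate(zip(self.layer, self.is_excitatory))
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.activities, columns=self.neuron_labels())
        df.insert(0, "time_ms", np.arange(len(df)) * self.dt)
        return df

    def export_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
        meta = {
            "dt": self.dt,
            "layer": self.layer.tolist(),
            "is_excitatory": self.is_excitatory.tolist(),
        }
        Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))


def build_network(spec: NetworkSpec) -> NetworkBundle:
    """Realize the connectivity with seeded random weights and delays."""
    n = spec.n_neurons
    rng = np.random.default_rng(spec.seed)
    n1 = spec.layer1_exc + spec.layer1_inh
    layer = np.where(np.arange(n) < n1, 1, 2)
    is_exc = np.zeros(n, dtype=bool)
    is_exc[: spec.layer1_exc] = True
    is_exc[n1 : n1 + spec.layer2_exc] = True
    signs = np.where(is_exc, 1.0, -1.0)

    weights = spec.weight_spec.draw(rng, (n, n))
    if not spec.include_autapses:
        np.fill_diagonal(weights, 0.0)
    sensor_weights = np.zeros((n, spec.n_sensors))
    sensor_weights[:n1] = spec.weight_spec.draw(rng, (n1, spec.n_sensors))

    if spec.mean_delay_ms > 0:
        half = spec.delay_halfwidth_frac * spec.mean_delay_ms
        delays = rng.uniform(spec.mean_delay_ms - half, spec.mean_delay_ms + half, size=(n, n))
    else:
        delays = np.zeros((n, n))

    n_recurrent = n if spec.include_autapses else n - 1
    n_syn = np.full(n, n_recurrent)
    n_syn[:n1] += spec.n_sensors  # layer-2 neurons count only recurrent afferents
    return NetworkBundle(
        spec=spec,
        weights=weights,
        signs=signs,
        delays_ms=delays,
        sensor_weights=sensor_weights,
        layer=layer,
        is_excitatory=is_exc,
        n_synapses=n_syn,
    )


def scale_tau(
    base_tau: float, n_synapses: int, mode: str, reference_synapse_count: int
) -> float:
    """Scale the dynamic-leak time constant with the afferent synapse count.

    The reference count normalizes the scaling so that a default-size neuron
    keeps ``base_tau`` under every mode.
    """
    if n_synapses < 1 or reference_synapse_count < 1:
        raise ValueError("synapse counts must be >= 1")
    ratio = n_synapses / reference_synapse_count
    if mode == "constant":
        return base_tau
    if mode == "sqrt":
        return base_tau * np.sqrt(ratio)
    if mode == "linear":
        return base_tau * ratio
    raise ValueError(f"unknown tau scaling mode {mode!r}")


# synapse count of a default 5x4 layer-1 neuron: 17 recurrent + 6 sensors
DEFAULT_REFERENCE_SYNAPSES = 23


def simulate_network(
    bundle: NetworkBundle,
    sensor_signals: list,
    lsm_params: LSMParams,
    dt: float = 1.0,
) -> NetworkTrace:
    """Run the synchronous discrete-time network simulation.

    At each step, every neuron's synaptic input is the sensors' current
    activity (layer 1 only) plus the other neurons' activities delayed by the
    per-connection conduction delay (minimum one step, avoiding zero-delay
    algebraic loops).  The LSM drive and leak update are applied per neuron;
    neurons see only the previous steps' activities.  Initial activities are
    zero.
    """
    spec = bundle.spec
    if len(sensor_signals) != spec.n_sensors:
        raise ValueError(f"expected {spec.n_sensors} sensor signals, got {len(sensor_signals)}")
    dts = {s.dt for s in sensor_signals}
    lens = {len(s) for s in sensor_signals}
    if len(dts) != 1 or len(lens) != 1:
        raise ValueError("sensor signals must share dt and duration")
    if dts.pop() != dt:
        raise ValueError("sensor signal dt must match simulation dt")
    n_steps = lens.pop()
    n = spec.n_neurons

    sens = np.column_stack([s.values for s in sensor_signals])  # (n_steps, n_sensors)
    w_abs = bundle.weights
    w_signed = w_abs * bundle.signs[None, :]
    s_w = bundle.sensor_weights
    ksi = lsm_params.k_static * bundle.n_synapses.astype(float)

    # per-neuron leak factor, tau scaled with afferent synapse count
    taus = np.array(
        [
            scale_tau(lsm_params.tau_dyn, c, spec.tau_scaling, DEFAULT_REFERENCE_SYNAPSES)
            for c in bundle.n_synapses
        ]
    )
    alphas = np.exp(-dt / taus)

    d_steps = np.maximum(1, np.round(bundle.delays_ms / dt).astype(int))
    max_d = int(d_steps.max())
    hist = np.zeros((n_steps + max_d, n))
    cols = np.broadcast_to(np.arange(n)[None, :], (n, n))

    a_prev = np.zeros(n)
    out = np.empty((n_steps, n))
    use_leak = lsm_params.use_dynamic_leak
    for t in range(n_steps):
        rows = max_d + t - d_steps
        a_del = hist[rows, cols]  # (post, pre)
        sens_drive = s_w @ sens[t]
        num = (w_signed * a_del).sum(axis=1) + sens_drive
        den = ksi + (w_abs * a_del).sum(axis=1) + sens_drive
        drive = np.clip(num / den, 0.0, None)
        if use_leak:
            a = drive + (a_prev - drive) * alphas
            np.clip(a, 0.0, None, out=a)
        else:
            a = drive
        hist[max_d + t] = a
        out[t] = a
        a_prev = a
    return NetworkTrace(
        activities=out, dt=dt, layer=bundle.layer, is_excitatory=bundle.is_excitatory
    )
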