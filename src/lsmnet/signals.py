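"""Pseudo-random sensory spike trains and their conversion to continuous signals.

Sensory input to the neuron models is a set of pseudo-random spike trains
(one per sensor channel) at a prescribed average rate.  Spike times are drawn
on the integer-millisecond grid, jittered per presentation, and convolved with
a double-exponential postsynaptic-potential (PSP) kernel

    k(t) = tau_km / (tau_kd - tau_kr) *
           [exp(-(t - tau_kl)/tau_kd) - exp(-(t - tau_kl)/tau_kr)]

to yield time-continuous activity traces.  With the default constants
(tau_kd = 4 ms, tau_kr = 12.5 ms, tau_km = 21.3 ms, tau_kl = 0) the kernel is
non-negative, peaks near 6.7 ms and integrates to tau_km.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "KernelParams",
    "SpikeTrain",
    "ContinuousSignal",
    "generate_spike_train",
    "jitter_spike_train",
    "psp_kernel",
    "kernel_peak_time",
    "kernel_support",
    "convolve_spikes",
    "build_presentation_block",
    "write_spike_trains_csv",
    "read_spike_trains_csv",
    "write_signals_csv",
    "read_signals_csv",
]


@dataclass(frozen=True)
class KernelParams:
    """PSP kernel constants, all in ms.

    ``tau_kd`` decay time, ``tau_kr`` rise time, ``tau_km`` amplitude scaling
    constant, ``tau_kl`` latency (kernel is zero before the latency elapses).
    """

    tau_kd: float = 4.0
    tau_kr: float = 12.5
    tau_km: float = 21.3
    tau_kl: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.tau_kd, self.tau_kr, self.tau_km, self.tau_kl)
        if not all(np.isfinite(vals)):
            raise ValueError("kernel parameters must be finite")
        if self.tau_kd == self.tau_kr:
            raise ValueError("tau_kd must differ from tau_kr (denominator tau_kd - tau_kr)")
        if self.tau_kl < 0:
            raise ValueError("latency tau_kl must be non-negative")


@dataclass
class SpikeTrain:
    """Ordered spike times (ms) for one input channel.

    Times are sorted, deduplicated and confined to ``[0, duration)``.
    """

    times: np.ndarray
    duration: float
    label: str = ""

    def __post_init__(self) -> None:
        t = np.unique(np.asarray(self.times, dtype=float))
        if t.size and (t[0] < 0 or t[-1] >= self.duration):
            raise ValueError("spike times must lie in [0, duration)")
        self.times = t

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ContinuousSignal:
    """Uniformly sampled activity trace (arbitrary units)."""

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.dt

    def __len__(self) -> int:
        return self.values.size


def generate_spike_train(
    rate: float, duration: float, seed: int | np.random.Generator, label: str = ""
) -> SpikeTrain:
    """Draw a pseudo-random spike train with an exact spike count.

    Exactly ``round(rate * duration / 1000)`` distinct spike times are sampled
    uniformly without replacement from the integer-millisecond grid of
    ``[0, duration)``, mimicking uniform integer draws while guaranteeing the
    requested average rate.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_spikes = int(round(rate * duration / 1000.0))
    n_grid = int(np.floor(duration))
    if n_spikes > n_grid:
        raise ValueError(
            f"cannot place {n_spikes} distinct ms-grid spikes in {n_grid} grid points; "
            "rate and duration are incompatible"
        )
    rng = np.random.default_rng(seed)
    times = np.sort(rng.choice(n_grid, size=n_spikes, replace=False)).astype(float)
    return SpikeTrain(times=times, duration=duration, label=label)


def jitter_spike_train(
    train: SpikeTrain,
    max_jitter: float,
    seed: int | np.random.Generator,
    distribution: str = "uniform",
) -> SpikeTrain:
    """Shift each spike independently by random noise of up to ``max_jitter`` ms.

    ``distribution='uniform'`` draws from U(-max_jitter, +max_jitter) (default);
    ``'gaussian'`` draws from N(0, max_jitter/2) so ~95% of shifts stay within
    the stated bound.  Times are clipped to the train's window, re-sorted and
    deduplicated.
    """
    if max_jitter < 0:
        raise ValueError("max_jitter must be non-negative")
    if max_jitter == 0:
        return SpikeTrain(times=train.times.copy(), duration=train.duration, label=train.label)
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        offsets = rng.uniform(-max_jitter, max_jitter, size=len(train))
    elif distribution == "gaussian":
        offsets = rng.normal(0.0, max_jitter / 2.0, size=len(train))
    else:
        raise ValueError(f"unknown jitter distribution {distribution!r}")
    shifted = np.clip(train.times + offsets, 0.0, np.nextafter(train.duration, 0.0))
    return SpikeTrain(times=shifted, duration=train.duration, label=train.label)


def psp_kernel(t: np.ndarray | float, params: KernelParams = KernelParams()) -> np.ndarray | float:
    """Evaluate the double-exponential PSP kernel at time(s) ``t`` (ms) since spike.

    Causal: returns 0 for ``t < tau_kl``.
    """
    t_arr = np.asarray(t, dtype=float)
    s = t_arr - params.tau_kl
    pref = params.tau_km / (params.tau_kd - params.tau_kr)
    with np.errstate(over="ignore"):
        out = pref * (np.exp(-s / params.tau_kd) - np.exp(-s / params.tau_kr))
    out = np.where(s >= 0, out, 0.0)
    return out if t_arr.ndim else float(out)


def kernel_peak_time(params: KernelParams = KernelParams()) -> float:
    """Time of the kernel maximum: tau_kl + ln(tau_kd/tau_kr)/(1/tau_kr - 1/tau_kd)."""
    a, b = params.tau_kd, params.tau_kr
    return params.tau_kl + np.log(a / b) / (1.0 / b - 1.0 / a)


def kernel_support(params: KernelParams = KernelParams(), rel_tol: float = 1e-6) -> float:
    """Duration (ms) after which the kernel amplitude falls below ``rel_tol`` of its peak.

    Beyond the peak the slower exponential dominates, so the cutoff is solved
    from the slow-tail envelope.
    """
    peak = psp_kernel(kernel_peak_time(params), params)
    tau_slow = max(params.tau_kd, params.tau_kr)
    amp = abs(params.tau_km / (params.tau_kd - params.tau_kr))
    return params.tau_kl + tau_slow * np.log(amp / (rel_tol * peak))


def convolve_spikes(
    train: SpikeTrain, params: KernelParams = KernelParams(), dt: float = 1.0
) -> ContinuousSignal:
    """Superpose PSP kernels from all spikes, sampled on the ``dt`` grid.

    Each kernel is truncated where its amplitude drops below 1e-6 of the peak.
    An empty train yields an all-zero signal.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(train.duration / dt))
    out = np.zeros(n)
    if len(train) == 0:
        return ContinuousSignal(values=out, dt=dt)
    m = int(np.ceil(kernel_support(params, 1e-6) / dt)) + 1
    offsets = np.arange(m)
    for t_s in train.times:
        i0 = int(np.floor(t_s / dt))
        idx = i0 + offsets
        idx = idx[idx < n]
        out[idx] += psp_kernel(idx * dt - t_s, params)
    return ContinuousSignal(values=out, dt=dt)


def build_presentation_block(
    base_trains: list[SpikeTrain],
    n_presentations: int,
    max_jitter: float,
    params: KernelParams = KernelParams(),
    dt: float = 1.0,
    seed: int | np.random.Generator = 0,
    distribution: str = "uniform",
) -> list[ContinuousSignal]:
    """Concatenate jittered presentations of each base train and convolve once.

    Presentation ``k`` of a channel is an independently jittered copy of the
    channel's base train offset by ``k * duration``; copies are concatenated
    without pause or reset so that PSP kernels cross presentation boundaries.
    Returns one continuous signal per channel spanning
    ``n_presentations * duration`` ms.
    """
    if n_presentations < 1:
        raise ValueError("n_presentations must be >= 1")
    durations = {tr.duration for tr in base_trains}
    if len(durations) != 1:
        raise ValueError("all base trains must share one duration")
    duration = durations.pop()
    rng = np.random.default_rng(seed)
    signals = []
    for tr in base_trains:
        chunks = []
        for k in range(n_presentations):
            jit = jitter_spike_train(tr, max_jitter, rng, distribution=distribution)
            chunks.append(jit.times + k * duration)
        total = n_presentations * duration
        # offsets can round a clipped end-of-window time up to the boundary
        times = np.clip(np.concatenate(chunks), 0.0, np.nextafter(total, 0.0))
        long_train = SpikeTrain(times=times, duration=total, label=tr.label)
        signals.append(convolve_spikes(long_train, params, dt))
    return signals


# ---------------------------------------------------------------------------
# I/O: spike trains as two-column CSV, signals as wide CSV + JSON sidecar.

def write_spike_trains_csv(trains: list[SpikeTrain], path: str | Path) -> None:
    rows = [
        {"channel_label": tr.label or str(i), "time_ms": t}
        for i, tr in enumerate(trains)
        for t in tr.times
    ]
    pd.DataFrame(rows, columns=["channel_label", "time_ms"]).to_csv(path, index=False)


def read_spike_trains_csv(path: str | Path, duration: float) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(times=grp["time_ms"].to_numpy(), duration=duration, label=str(lbl))
        for lbl, grp in df.groupby("channel_label", sort=False)
    ]


def write_signals_csv(
    signals: list[ContinuousSignal],
    path: str | Path,
    labels: list[str] | None = None,
    metadata: dict | None = None,
) -> None:
    path = Path(path)
    labels = labels or [f"ch{i}" for i in range(len(signals))]
    df = pd.DataFrame({"time_ms": signals[0].times})
    for lbl, sig in zip(labels, signals):
        df[lbl] = sig.values
    df.to_csv(path, index=False)
    meta = {"dt": signals[0].dt, "t0": signals[0].t0}
    meta.update(metadata or {})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_signals_csv(path: str | Path) -> tuple[list[ContinuousSignal], list[str], dict]:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    t = df["time_ms"].to_numpy()
    dt = meta.get("dt", float(t[1] - t[0]) if len(t) > 1 else 1.0)
    t0 = meta.get("t0", float(t[0]) if len(t) else 0.0)
    labels = [c for c in df.columns if c != "time_ms"]
    sigs = [ContinuousSignal(values=df[c].to_numpy(), dt=dt, t0=t0) for c in labels]
    return sigs, labels, meta
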