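"""Ground-truth simulation of the full all-to-all spiking network.

The network is the discontinuous system (dimensional form)

    C dV_i/dt = k (V_i - V_R)(V_i - V_T) - W_i + I_i + g_i s (E_r - V_i)
    dW_i/dt   = (eta (V_i - V_R) - W_i) / tau_W,i
    ds/dt     = -s / tau_syn + (s_jump / N) * sum of presynaptic spikes

with the reset V_i >= V_peak -> V_i := V_reset, W_i := W_i + W_jump,i.
Integration is fixed-step forward Euler with the spike test applied after
each step; all simultaneous spikes increment s within the same step.  The
threshold crossing time is not interpolated, so per-spike timing error is
O(dt); the dt-halving convergence test bounds the effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import DimensionalParams
from .heterogeneity import HeterogeneitySpec


class IntegrationFailureError(RuntimeError):
    pass


class InvalidWindowError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    N: int = 1000
    params: DimensionalParams = field(default_factory=DimensionalParams)
    het: HeterogeneitySpec = field(default_factory=HeterogeneitySpec)
    T_sim: float = 2000.0      # ms
    dt: float = 0.05           # ms
    seed: int = 0
    record_traces: bool = True
    trace_stride: int = 10     # store every trace_stride-th step
    v_init: float | None = None   # None: uniform on [V_reset, V_peak)

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.dt <= 0 or self.T_sim <= self.dt:
            raise ValueError("need dt > 0 and T_sim > dt")


@dataclass
class SpikeRaster:
    """Per-neuron ordered spike times in ms; ``draws`` records the
    per-neuron heterogeneous parameter values used in the run."""

    spikes: list            # list of 1-D float arrays
    T_sim: float
    draws: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return len(self.spikes)

    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spikes])

    def to_frame(self):
        import pandas as pd
        rows = [(i, t) for i, ts in enumerate(self.spikes) for t in ts]
        return pd.DataFrame(rows, columns=["neuron_id", "spike_time_ms"])


@dataclass
class TraceSet:
    """Network-mean traces on a regular time grid (ms)."""

    t: np.ndarray
    V_mean: np.ndarray
    W_mean: np.ndarray
    s: np.ndarray
    g_mean: np.ndarray      # g_syn_mean * s(t), nS

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "t_ms": self.t, "V_mean_mV": self.V_mean,
            "W_mean_pA": self.W_mean, "s": self.s, "g_mean_nS": self.g_mean,
        })


def simulate_network(cfg: NetworkConfig) -> tuple[SpikeRaster, TraceSet]:
    """Integrate the network and return spike times plus mean traces.

    Per-neuron heterogeneous parameters are drawn from ``cfg.het`` with
    ``cfg.seed``; initial voltages are uniform on [V_reset, V_peak) (a
    desynchronized start), W_i = 0 and s = 0.
    """
    p = cfg.params
    N = cfg.N
    rng = np.random.default_rng(cfg.seed)

    draws = cfg.het.sample_dimensional(N, rng) if cfg.het else {}
    I = np.full(N, p.I_app); I[:] = draws.get("I_app", I)
    G = np.full(N, p.g_syn); G[:] = draws.get("g_syn", G)
    Wj = np.full(N, p.W_jump); Wj[:] = draws.get("W_jump", Wj)
    tw = np.full(N, p.tau_W); tw[:] = draws.get("tau_W", tw)

    if cfg.v_init is None:
        V = rng.uniform(p.V_reset, p.V_peak, size=N)
    else:
        V = np.full(N, float(cfg.v_init))
    W = np.zeros(N)
    s = 0.0

    nsteps = int(round(cfg.T_sim / cfg.dt))
    dt = cfg.dt
    inv_C = 1.0 / p.C
    decay_s = dt / p.tau_syn
    sj_per_N = p.s_jump / N

    spikes: list[list[float]] = [[] for _ in range(N)]
    rec_every = max(1, cfg.trace_stride)
    nrec = nsteps // rec_every + 1
    t_rec = np.empty(nrec); Vm = np.empty(nrec); Wm = np.empty(nrec)
    srec = np.empty(nrec)
    k_rec = 0
    g_mean_scale = float(np.mean(G))

    vmax_guard = 10.0 * abs(p.V_peak) + 1e4
    for step in range(nsteps + 1):
        if cfg.record_traces and step % rec_every == 0 and k_rec < nrec:
            t_rec[k_rec] = step * dt
            Vm[k_rec] = V.mean(); Wm[k_rec] = W.mean(); srec[k_rec] = s
            k_rec += 1
        if step == nsteps:
            break
        dV = (p.k * (V - p.V_R) * (V - p.V_T) - W + I + G * s * (p.E_r - V)) * inv_C
        V += dt * dV
        W += dt * ((p.eta * (V - p.V_R) - W) / tw)
        s -= decay_s * s
        fired = V >= p.V_peak
        nf = int(fired.sum())
        if nf:
            t_now = (step + 1) * dt
            for i in np.flatnonzero(fired):
                spikes[i].append(t_now)
            V[fired] = p.V_reset
            W[fired] += Wj[fired]
            s += sj_per_N * nf
        if not np.all(np.isfinite(V)) or np.nanmax(np.abs(V)) > vmax_guard:
            bad = int(np.argmax(~np.isfinite(V) | (np.abs(V) > vmax_guard)))
            raise IntegrationFailureError(
                f"voltage overflow for neuron {bad} at t = {(step + 1) * dt:.3f} ms; "
                "reduce dt")

    raster = SpikeRaster([np.asarray(ts) for ts in spikes], cfg.T_sim,
                         draws=draws)
    traces = TraceSet(t=t_rec[:k_rec], V_mean=Vm[:k_rec], W_mean=Wm[:k_rec],
                      s=srec[:k_rec], g_mean=g_mean_scale * srec[:k_rec])
    return raster, traces


def steady_rates(raster: SpikeRaster) -> np.ndarray:
    """Per-neuron steady firing rate as the reciprocal of the last
    interspike interval (ms^-1).  Neurons with fewer than two spikes get 0."""
    out = np.zeros(raster.N)
    for i, ts in enumerate(raster.spikes):
        if len(ts) >= 2:
            out[i] = 1.0 / (ts[-1] - ts[-2])
    return out


def classify_neurons(raster: SpikeRaster, window: float | None = None,
                     ratio_threshold: float = 3.0):
    """Label each neuron tonic / bursting / quiescent from its ISIs.

    A neuron with no spikes in the analysis window (default: final 50% of
    the run, excluding the transient) is quiescent; one whose max/min ISI
    ratio in the window exceeds ``ratio_threshold`` is bursting; the rest
    are tonic.  Returns (labels, p_burst).
    """
    if window is None:
        window = raster.T_sim / 2.0
    if window <= 0 or window > raster.T_sim:
        raise InvalidWindowError("analysis window must lie within the run")
    t0 = raster.T_sim - window
    labels = np.empty(raster.N, dtype=object)
    for i, ts in enumerate(raster.spikes):
        ts = ts[ts >= t0]
        if len(ts) == 0:
            labels[i] = "quiescent"
            continue
        if len(ts) < 3:
            # too few spikes to form two ISIs: a lone spike or pair late in
            # a long window is burst-like only if the window could hold more
            labels[i] = "tonic"
            continue
        isi = np.diff(ts)
        labels[i] = "bursting" if isi.max() / isi.min() > ratio_threshold else "tonic"
    p_burst = float(np.mean(labels == "bursting"))
    return labels, p_burst
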