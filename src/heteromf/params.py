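"""Biophysical parameters of the adapting Izhikevich neuron and their
nondimensionalization.

The dimensional model for a single neuron is

    C dV/dt   = k (V - V_R)(V - V_T) - W + I_app + g_syn s (E_r - V)
    tau_W dW/dt = eta (V - V_R) - W

with the reset rule V >= V_peak -> V := V_reset, W := W + W_jump.  The
dimensionless form uses the substitutions

    v = 1 + V / |V_R|,   w = W / (k V_R^2),   t -> t * k |V_R| / C,

which turn the voltage equation into dv/dt = v(v - alpha) - w + I +
g s (e_r - v) with F(v) = v(v - alpha).  All conversions are linear, so
normal parameter distributions stay normal under them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates its physical constraints."""


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional neuron/synapse parameters (pF, nS, mV, pA, ms).

    Defaults are the hippocampal CA3 pyramidal-cell fit used throughout,
    with ``eta = 0`` (the small linear coupling of W to V dropped) and an
    excitatory reversal potential of 0 mV.
    """

    C: float = 250.0          # membrane capacitance, pF
    k: float = 2.5            # quadratic nonlinearity gain, nS/mV
    V_R: float = -65.0        # resting potential, mV
    V_T: float = -24.6        # threshold potential, mV  (V_R + 40 - eta/k with eta = -1)
    V_peak: float = 30.0      # spike cutoff, mV
    V_reset: float = -55.0    # post-spike reset, mV
    W_jump: float = 200.0     # adaptation increment per spike, pA
    tau_W: float = 200.0      # adaptation time constant, ms
    eta: float = 0.0          # linear V->W coupling, nS (0 in all shipped runs)
    I_app: float = 2000.0     # applied current, pA
    g_syn: float = 200.0      # maximal synaptic conductance, nS
    tau_syn: float = 4.0      # synaptic decay time constant, ms
    s_jump: float = 0.8       # gating increment per presynaptic spike
    E_r: float = 0.0          # synaptic reversal potential, mV

    def __post_init__(self) -> None:
        if self.C <= 0 or self.k <= 0 or self.tau_W <= 0 or self.tau_syn <= 0:
            raise InvalidParameterError(
                "C, k, tau_W and tau_syn must all be positive"
            )
        if self.s_jump <= 0:
            raise InvalidParameterError("s_jump must be positive")
        if not (self.V_reset < self.V_peak):
            raise InvalidParameterError("V_reset must be below V_peak")
        if not (self.V_R < self.V_T < self.V_peak):
            raise InvalidParameterError("need V_R < V_T < V_peak")

    @property
    def time_unit(self) -> float:
        """Milliseconds per unit of dimensionless time, C / (k |V_R|)."""
        return self.C / (self.k * abs(self.V_R))

    def with_(self, **kwargs) -> "DimensionalParams":
        return replace(self, **kwargs)

    def asdict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DimensionlessParams:
    alpha: float
    v_peak: float
    v_reset: float
    w_jump: float
    a: float          # 1 / tau_w
    b: float
    I: float
    g: float
    tau_s: float
    s_jump: float
    e_r: float

    def __post_init__(self) -> None:
        if not (self.v_reset < self.v_peak):
            raise InvalidParameterError("v_reset must be below v_peak")
        if self.a <= 0 or self.tau_s <= 0:
            raise InvalidParameterError("a and tau_s must be positive")
        if self.w_jump < 0:
            raise InvalidParameterError("w_jump must be nonnegative")

    @property
    def tau_w(self) -> float:
        return 1.0 / self.a

    def with_(self, **kwargs) -> "DimensionlessParams":
        return replace(self, **kwargs)

    def asdict(self) -> dict:
        return asdict(self)


def nondimensionalize(p: DimensionalParams) -> DimensionlessParams:
    """Map dimensional parameters to their dimensionless counterparts."""
    vr = abs(p.V_R)
    return DimensionlessParams(
        alpha=1.0 + p.V_T / vr,
        v_peak=1.0 + p.V_peak / vr,
        v_reset=1.0 + p.V_reset / vr,
        w_jump=p.W_jump / (p.k * vr**2),
        a=p.C / (p.tau_W * p.k * vr),
        b=p.eta / (p.k * vr),
        I=p.I_app / (p.k * vr**2),
        g=p.g_syn / (p.k * vr),
        tau_s=p.tau_syn * p.k * vr / p.C,
        s_jump=p.s_jump,
        e_r=1.0 + p.E_r / vr,
    )


def dimensionalize(q: DimensionlessParams, C: float = 250.0, k: float = 2.5,
                   V_R: float = -65.0) -> DimensionalParams:
    """Inverse of :func:`nondimensionalize` given the three scale-setting
    parameters (C, k, V_R), which the dimensionless form does not retain."""
    vr = abs(V_R)
    return DimensionalParams(
        C=C,
        k=k,
        V_R=V_R,
        V_T=(q.alpha - 1.0) * vr,
        V_peak=(q.v_peak - 1.0) * vr,
        V_reset=(q.v_reset - 1.0) * vr,
        W_jump=q.w_jump * k * vr**2,
        tau_W=C / (q.a * k * vr),
        eta=q.b * k * vr,
        I_app=q.I * k * vr**2,
        g_syn=q.g * k * vr,
        tau_syn=q.tau_s * C / (k * vr),
        s_jump=q.s_jump,
        E_r=(q.e_r - 1.0) * vr,
    )


# Linear scale factors mapping each dimensional heterogeneous parameter to
# its dimensionless counterpart (value_dimless = value_dim * scale).
def beta_scale(name: str, p: DimensionalParams) -> tuple[str, float]:
    """Return (dimensionless name, multiplicative scale) for a heterogeneous
    dimensional parameter name.

    tau_W maps to the dimensionless adaptation time constant tau_w (not the
    rate a), so that a normal spread in tau_W stays normal.
    """
    vr = abs(p.V_R)
    table = {
        "I_app": ("I", 1.0 / (p.k * vr**2)),
        "g_syn": ("g", 1.0 / (p.k * vr)),
        "W_jump": ("w_jump", 1.0 / (p.k * vr**2)),
        "tau_W": ("tau_w", p.k * vr / p.C),
    }
    try:
        return table[name]
    except KeyError:
        raise InvalidParameterError(
            f"unsupported heterogeneous parameter {name!r}; "
            f"choose from {sorted(table)}"
        ) from None


def rheobase(q: DimensionlessParams) -> float:
    """Minimum dimensionless current for repetitive firing of the uncoupled
    quadratic neuron: min_v F(v) = -alpha^2/4, so I_rh = alpha^2 / 4."""
    return q.alpha**2 / 4.0


def rheobase_dimensional(p: DimensionalParams) -> float:
    """Rheobase in pA for the dimensional parameter set."""
    q = nondimensionalize(p)
    vr = abs(p.V_R)
    return rheobase(q) * p.k * vr**2


TABLE_DEFAULT = DimensionalParams()
"""The shipped default parameter set (eta = 0, E_r = 0 mV)."""


def rate_to_per_ms(R_dimless: float, p: DimensionalParams) -> float:
    """Convert a dimensionless firing rate to spikes per millisecond."""
    return R_dimless / p.time_unit


def rate_to_dimless(R_per_ms: float, p: DimensionalParams) -> float:
    return R_per_ms * p.time_unit


def w_to_dimensional(w: float, p: DimensionalParams) -> float:
    """Dimensionless adaptation -> pA."""
    return w * p.k * p.V_R**2
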