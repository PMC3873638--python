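"""The three mean-field reductions of the heterogeneous network.

All three share the same skeleton: a slow adaptation balance driven by the
quasi-steady firing rate, coupled to the network gating variable s.

* **MFI** closes over the heterogeneous parameters first, so it is exactly
  the homogeneous mean-field system evaluated at the mean parameters: a
  2-D switching ODE for (<w>, s).

* **MFII** closes the adaptation over the whole network (<w|v, beta> =
  <w>) but keeps the beta-resolved conditional firing rate; the rate and
  voltage integrals over the parameter density are discretized on a beta
  grid (Gauss-Hermite for a single normal parameter, Monte Carlo
  otherwise).  Still a 2-D ODE.

* **MFIII** keeps the beta-conditioned adaptation field <w|beta>, a
  transport-free PDE solved by the method of lines on the same kind of
  beta grid: M coupled adaptation ODEs sharing one gating variable.

The right-hand sides are continuous but non-smooth (sqrt-type) on the
switching manifold H = 0; adaptive Runge-Kutta with tight tolerances
handles this without event detection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core import rate_and_mean_v
from .heterogeneity import BetaGrid
from .params import DimensionlessParams


class MFIntegrationError(RuntimeError):
    pass


class MFI:
    """Homogeneous mean-field system at the mean parameters; state (w, s)."""

    dim = 2

    def __init__(self, q: DimensionlessParams):
        self.q = q
        if q.tau_s < 1.0:
            warnings.warn(
                "tau_s < 1: the gating variable is faster than the voltage "
                "relaxation the quasi-steady-state closure assumes",
                stacklevel=2)

    def rate_and_v(self, w: float, s: float) -> tuple[float, float]:
        q = self.q
        c = (q.alpha + q.g * s) / 2.0
        H = q.I - w - c * c + q.g * q.e_r * s
        if H > 0.0:
            rt = math.sqrt(H)
            span = (math.atan((q.v_peak - c) / rt)
                    - math.atan((q.v_reset - c) / rt))
            R = rt / span
            v = 0.5 * R * math.log(((q.v_peak - c) ** 2 + H)
                                   / ((q.v_reset - c) ** 2 + H)) + c
            return R, v
        return 0.0, c - math.sqrt(-H)

    def rhs(self, t, y):
        w, s = y
        q = self.q
        R, v = self.rate_and_v(w, s)
        dw = q.a * (q.b * v - w) + q.w_jump * R
        ds = -s / q.tau_s + q.s_jump * R
        return (dw, ds)

    def mean_rate(self, y) -> float:
        return self.rate_and_v(y[0], y[1])[0]

    def traces(self, y):
        """Derived (R_mean, v_mean, w_mean) along a trajectory array."""
        w = np.atleast_2d(y)[:, 0]
        s = np.atleast_2d(y)[:, 1]
        R = np.empty_like(w); v = np.empty_like(w)
        for i in range(len(w)):
            R[i], v[i] = self.rate_and_v(w[i], s[i])
        return R, v, w


class MFII:
    """Beta-resolved rate, network-wide adaptation closure; state (w, s)."""

    dim = 2

    def __init__(self, q: DimensionlessParams, grid: BetaGrid):
        self.q = q
        self.grid = grid
        r = grid.resolved(q)
        self.I_j = r["I"]; self.g_j = r["g"]
        self.wjump_j = r["w_jump"]
        self.tau_w_mean = float(np.dot(grid.weights, r["tau_w"]))
        self.weights = np.asarray(grid.weights, dtype=float)

    def node_rates_and_v(self, w: float, s: float):
        return rate_and_mean_v(w, s, self.I_j, self.g_j, self.q)

    def rhs(self, t, y):
        w, s = y
        q = self.q
        R_j, v_j = self.node_rates_and_v(w, s)
        v_bar = float(np.dot(self.weights, v_j))
        wjR = float(np.dot(self.weights, self.wjump_j * R_j))
        R_bar = float(np.dot(self.weights, R_j))
        dw = (q.b * v_bar - w) / self.tau_w_mean + wjR
        ds = -s / q.tau_s + q.s_jump * R_bar
        return (dw, ds)

    def mean_rate(self, y) -> float:
        R_j, _ = self.node_rates_and_v(y[0], y[1])
        return float(np.dot(self.weights, R_j))

    def traces(self, y):
        y = np.atleast_2d(y)
        R = np.empty(len(y)); v = np.empty(len(y))
        for i, (w, s) in enumerate(y):
            R_j, v_j = self.node_rates_and_v(w, s)
            R[i] = np.dot(self.weights, R_j)
            v[i] = np.dot(self.weights, v_j)
        return R, v, y[:, 0]


class MFIICurrent:
    """MFII specialized to a normal distribution of applied currents,
    with the parameter integrals evaluated on the firing region only.

    With heterogeneity in I alone, H(<w>, s, I) = I - I*(<w>, s), so the
    rate integral runs over I > I*.  Substituting I = I* + u^2 absorbs
    the sqrt(H) edge behavior into the measure and leaves an integrand
    that is smooth in (w, s); the same trick with I = I* - u^2 handles
    the subthreshold-voltage integral.  Unlike a fixed-node quadrature of
    the hard-switched integrand, the resulting right-hand side has a
    smooth Jacobian, which eigenvalue-based Hopf location needs.  State
    (w, s), dimensionless current distribution N(mu_I, sigma_I^2).
    """

    dim = 2

    def __init__(self, q: DimensionlessParams, mu_I: float, sigma_I: float,
                 n_quad: int = 80, n_sigma: float = 8.0):
        self.q = q
        self.mu_I = mu_I
        self.sigma_I = sigma_I
        self.lo = mu_I - n_sigma * sigma_I
        self.hi = mu_I + n_sigma * sigma_I
        xg, wg = np.polynomial.legendre.leggauss(n_quad)
        self.xg = 0.5 * (xg + 1.0)      # nodes on [0, 1]
        self.wg = 0.5 * wg

    def _pdf(self, I):
        z = (I - self.mu_I) / self.sigma_I
        return np.exp(-0.5 * z * z) / (self.sigma_I * math.sqrt(2.0 * math.pi))

    def moments(self, w: float, s: float):
        """(<R>, <v>) integrated against the current density."""
        q = self.q
        x = (q.alpha + q.g * s) / 2.0
        I_star = w + x * x - q.g * q.e_r * s
        R_bar = 0.0
        v_bar = 0.0
        u_hi = math.sqrt(max(self.hi - I_star, 0.0))
        u_lo = math.sqrt(max(self.lo - I_star, 0.0))
        if u_hi > u_lo:
            u = u_lo + (u_hi - u_lo) * self.xg
            wq = (u_hi - u_lo) * self.wg
            H = u * u
            span = (np.arctan((q.v_peak - x) / u)
                    - np.arctan((q.v_reset - x) / u))
            R = u / span
            rho = self._pdf(I_star + H)
            R_bar = float(np.sum(wq * 2.0 * u * R * rho))
            v_f = 0.5 * R * np.log(((q.v_peak - x) ** 2 + H)
                                   / ((q.v_reset - x) ** 2 + H)) + x
            v_bar = float(np.sum(wq * 2.0 * u * v_f * rho))
        d_hi = math.sqrt(max(I_star - self.lo, 0.0))
        d_lo = math.sqrt(max(I_star - self.hi, 0.0))
        if d_hi > d_lo:
            u = d_lo + (d_hi - d_lo) * self.xg
            wq = (d_hi - d_lo) * self.wg
            rho = self._pdf(I_star - u * u)
            v_bar += float(np.sum(wq * 2.0 * u * (x - u) * rho))
        return R_bar, v_bar

    def rhs(self, t, y):
        w, s = y
        q = self.q
        R_bar, v_bar = self.moments(w, s)
        dw = q.a * (q.b * v_bar - w) + q.w_jump * R_bar
        ds = -s / q.tau_s + q.s_jump * R_bar
        return (dw, ds)

    def mean_rate(self, y) -> float:
        return self.moments(y[0], y[1])[0]

    def traces(self, y):
        y = np.atleast_2d(y)
        R = np.empty(len(y)); v = np.empty(len(y))
        for i, (w, s) in enumerate(y):
            R[i], v[i] = self.moments(w, s)
        return R, v, y[:, 0]


class MFIII:
    """Beta-conditioned adaptation field by the method of lines; state
    (<w|beta_1>, ..., <w|beta_M>, s)."""

    def __init__(self, q: DimensionlessParams, grid: BetaGrid):
        self.q = q
        self.grid = grid
        r = grid.resolved(q)
        self.I_j = r["I"]; self.g_j = r["g"]
        self.wjump_j = r["w_jump"]; self.a_j = 1.0 / r["tau_w"]
        self.weights = np.asarray(grid.weights, dtype=float)
        self.dim = grid.M + 1

    def node_rates_and_v(self, w_j: np.ndarray, s: float):
        return rate_and_mean_v(w_j, s, self.I_j, self.g_j, self.q)

    def rhs(self, t, y):
        q = self.q
        w_j = y[:-1]; s = y[-1]
        R_j, v_j = self.node_rates_and_v(w_j, s)
        dw = self.a_j * (q.b * v_j - w_j) + self.wjump_j * R_j
        ds = -s / q.tau_s + q.s_jump * float(np.dot(self.weights, R_j))
        return np.append(dw, ds)

    def mean_rate(self, y) -> float:
        R_j, _ = self.node_rates_and_v(y[:-1], y[-1])
        return float(np.dot(self.weights, R_j))

    def conditional_mean_w(self, y) -> float:
        """<w> = sum_j weight_j <w|beta_j> (state-to-moment readout)."""
        return float(np.dot(self.weights, np.asarray(y)[..., :-1].T))

    def uniform_state(self, w: float = 0.0, s: float = 0.0) -> np.ndarray:
        return np.append(np.full(self.grid.M, w), s)

    def traces(self, y):
        y = np.atleast_2d(y)
        R = np.empty(len(y)); v = np.empty(len(y)); wbar = np.empty(len(y))
        for i, row in enumerate(y):
            R_j, v_j = self.node_rates_and_v(row[:-1], row[-1])
            R[i] = np.dot(self.weights, R_j)
            v[i] = np.dot(self.weights, v_j)
            wbar[i] = np.dot(self.weights, row[:-1])
        return R, v, wbar


def mfi_rhs(state, q: DimensionlessParams):
    """Functional form of the MFI right-hand side (convenience wrapper)."""
    return np.asarray(MFI(q).rhs(0.0, state))


def mfii_rhs(state, grid: BetaGrid, q: DimensionlessParams):
    return np.asarray(MFII(q, grid).rhs(0.0, state))


def mfiii_rhs(state, grid: BetaGrid, q: DimensionlessParams):
    return np.asarray(MFIII(q, grid).rhs(0.0, state))


def conditional_mean_w(state, grid: BetaGrid) -> float:
    return float(np.dot(grid.weights, np.asarray(state)[:-1]))


@dataclass
class MFSolution:
    """Trajectory of a mean-field system with derived moment traces
    (dimensionless time and units)."""

    t: np.ndarray
    y: np.ndarray           # shape (len(t), dim)
    R_mean: np.ndarray
    v_mean: np.ndarray
    w_mean: np.ndarray
    s: np.ndarray
    system: object = None

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "t": self.t, "w_mean": self.w_mean, "s": self.s,
            "R_mean": self.R_mean, "v_mean": self.v_mean,
        })

    def final_state(self) -> np.ndarray:
        return self.y[-1]


def integrate_mf(system, y0, t_span, rtol: float = 1e-8, atol: float = 1e-8,
                 t_eval=None, max_step=np.inf) -> MFSolution:
    """Adaptive Runge-Kutta integration of a mean-field system.

    Deterministic given its inputs.  Raises :class:`MFIntegrationError` if
    the integrator fails before reaching the end of ``t_span``.
    """
    sol = solve_ivp(system.rhs, t_span, np.asarray(y0, dtype=float),
                    method="RK45", rtol=rtol, atol=atol, t_eval=t_eval,
                    max_step=max_step)
    if not sol.success:
        raise MFIntegrationError(
            f"integration failed at t = {sol.t[-1]:.3f}: {sol.message}")
    y = sol.y.T
    R, v, wbar = system.traces(y)
    return MFSolution(t=sol.t, y=y, R_mean=R, v_mean=v, w_mean=wbar,
                      s=y[:, -1], system=system)
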