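"""Population-level bursting analysis with the beta-conditioned mean field.

When the mean-field attractor is a limit cycle, the conditional firing
rate <R(gamma(t))|beta> over one period tells each slice of the
heterogeneous population apart: a beta whose rate stays positive over the
whole cycle fires tonically (with an oscillatory rate), one whose rate is
zero throughout is quiescent, and one whose rate vanishes over part of the
period is bursting.  Integrating the corresponding indicators against the
parameter density gives the population fractions p_tonic, p_q and p_burst
(the Heaviside convention h(0) = 1 keeps the three exactly summing to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .heterogeneity import HeterogeneitySpec, DistributionSpec, make_beta_grid
from .meanfield import MFIII
from .params import DimensionalParams, nondimensionalize


class UndeterminedAttractorError(RuntimeError):
    pass


@dataclass
class FixedPointReport:
    state: np.ndarray
    node_rates: np.ndarray


@dataclass
class LimitCycle:
    """A sampled steady-state limit cycle of a mean-field system with its
    per-node firing-rate envelopes over one period."""

    period: float
    t: np.ndarray
    y: np.ndarray                  # (n_samples, dim)
    rate_min: np.ndarray           # m(beta_j) = min_t <R|beta_j>
    rate_max: np.ndarray           # M(beta_j)

    def __post_init__(self) -> None:
        assert self.period > 0.0
        assert np.all(self.rate_min <= self.rate_max + 1e-15)


def find_limit_cycle(system, y0=None, t_transient: float = 600.0,
                     t_window: float = 600.0, max_rounds: int = 6,
                     n_eval: int = 2400, amp_tol: float = 1e-6,
                     period_rtol: float = 5e-3, rtol: float = 1e-8,
                     atol: float = 1e-10):
    """Integrate past the transient and extract the steady-state attractor.

    Periodicity is detected on downward crossings of s through its
    trailing mean; at least three consistent successive crossing intervals
    are required.  A fixed point is declared when the oscillation
    amplitude falls below ``amp_tol``, when the right-hand side has
    essentially vanished, or when the amplitude is small and shrinking
    geometrically between windows (a decaying spiral: waiting it out
    would cost unbounded time without changing the answer).  Raises
    :class:`UndeterminedAttractorError` if neither settles within
    ``max_rounds`` extension windows.
    """
    if y0 is None:
        y0 = system.uniform_state() if isinstance(system, MFIII) \
            else np.zeros(system.dim)
    sol = solve_ivp(system.rhs, (0.0, t_transient), np.asarray(y0, float),
                    method="RK45", rtol=rtol, atol=atol)
    y = sol.y[:, -1]
    amp_prev = None
    for _ in range(max_rounds):
        t_eval = np.linspace(0.0, t_window, n_eval)
        sol = solve_ivp(system.rhs, (0.0, t_window), y, method="RK45",
                        rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise UndeterminedAttractorError(sol.message)
        traj = sol.y.T
        y = traj[-1]
        s = traj[:, -1]
        amp = s.max() - s.min()
        is_fp = amp < amp_tol
        is_fp = is_fp or np.max(np.abs(np.asarray(system.rhs(0.0, y)))) < 1e-9
        is_fp = is_fp or (amp_prev is not None and amp < 1e-3
                          and amp < 0.6 * amp_prev)
        if is_fp:
            rates = _node_rates(system, traj[-1])
            return FixedPointReport(state=traj[-1], node_rates=rates)
        amp_prev = amp
        level = s.mean()
        down = np.flatnonzero((s[:-1] >= level) & (s[1:] < level))
        if len(down) >= 4:
            tc = t_eval[down]
            intervals = np.diff(tc)[-3:]
            if intervals.std() / intervals.mean() < period_rtol:
                period = float(np.mean(intervals))
                return _sample_cycle(system, y, period, rtol=rtol, atol=atol)
    raise UndeterminedAttractorError(
        "attractor neither settled to a fixed point nor to a periodic "
        "oscillation within the allotted integration time")


def _rk4_step(f, t, y, dt):
    k1 = f(t, y)
    k2 = f(t + 0.5 * dt, y + 0.5 * dt * k1)
    k3 = f(t + 0.5 * dt, y + 0.5 * dt * k2)
    k4 = f(t + dt, y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _rk4_run(system, y0, T: float, dt: float, store_every: int = 0):
    """Fixed-step RK4; immune to the step-size chatter adaptive solvers
    develop on sliding segments of the switching manifold.  Returns the
    final state, plus (t, traj) arrays when ``store_every`` > 0."""
    f = lambda t, y: np.asarray(system.rhs(t, y), dtype=float)
    y = np.asarray(y0, dtype=float)
    n = int(round(T / dt))
    if store_every:
        m = n // store_every + 1
        ts = np.empty(m); traj = np.empty((m, len(y)))
        k = 0
    for i in range(n + 1):
        if store_every and i % store_every == 0:
            ts[k] = i * dt; traj[k] = y; k += 1
        if i == n:
            break
        y = _rk4_step(f, i * dt, y, dt)
        if not np.all(np.isfinite(y)):
            raise UndeterminedAttractorError(
                f"state became non-finite at t = {(i + 1) * dt:.2f}")
    if store_every:
        return y, ts[:k], traj[:k]
    return y


def attractor_envelopes(system, y0=None, t_transient: float = 600.0,
                        t_window: float = 400.0, dt: float = 0.1,
                        amp_tol: float = 1e-4):
    """One-shot attractor classification for fraction sweeps.

    Integrates past the transient, then records one observation window.
    If the gating variable is steady the point is a fixed point;
    otherwise the per-node rate envelopes are taken directly over the
    window (which spans several oscillation periods), without resolving
    the period itself -- sufficient for the tonic/bursting/quiescent
    fractions and much cheaper than full period detection.
    """
    if y0 is None:
        y0 = system.uniform_state() if isinstance(system, MFIII) \
            else np.zeros(system.dim)
    y = _rk4_run(system, y0, t_transient, dt)
    _, t_eval, traj = _rk4_run(system, y, t_window, dt, store_every=3)
    s = traj[:, -1]
    if s.max() - s.min() < amp_tol:
        return FixedPointReport(state=traj[-1],
                                node_rates=_node_rates(system, traj[-1]))
    rates = _traj_rates(system, traj)
    return LimitCycle(period=t_window, t=t_eval, y=traj,
                      rate_min=rates.min(axis=0), rate_max=rates.max(axis=0))


def _traj_rates(system, traj: np.ndarray) -> np.ndarray:
    """Per-node rates along a trajectory, shape (n_times, M)."""
    if isinstance(system, MFIII):
        from .core import rate_and_mean_v
        w = traj[:, :-1]
        s = traj[:, -1][:, None]
        R, _ = rate_and_mean_v(w, s, system.I_j[None, :],
                               system.g_j[None, :], system.q)
        return R
    return np.stack([_node_rates(system, row) for row in traj])


def _node_rates(system, state) -> np.ndarray:
    if isinstance(system, MFIII):
        R, _ = system.node_rates_and_v(state[:-1], state[-1])
    elif hasattr(system, "node_rates_and_v"):
        R, _ = system.node_rates_and_v(state[0], state[1])
    else:
        R = np.atleast_1d(system.mean_rate(state))
    return np.asarray(R)


def _sample_cycle(system, y, period: float, n: int = 800,
                  rtol: float = 1e-9, atol: float = 1e-11) -> LimitCycle:
    t_eval = np.linspace(0.0, period, n)
    sol = solve_ivp(system.rhs, (0.0, period), y, method="RK45",
                    rtol=rtol, atol=atol, t_eval=t_eval)
    traj = sol.y.T
    rates = _traj_rates(system, traj)
    return LimitCycle(period=period, t=t_eval, y=traj,
                      rate_min=rates.min(axis=0), rate_max=rates.max(axis=0))


def population_fractions(lc, weights, zero_tol: float = 1e-8):
    """(p_tonic, p_q, p_burst) from the per-node rate envelopes.

    A node fires tonically if its rate never drops to zero over the cycle
    (m > zero_tol), is quiescent if its rate never rises above zero
    (M <= zero_tol), and is bursting otherwise.  At a fixed point the
    steady rates replace both envelopes, so p_burst = 0 there.
    """
    weights = np.asarray(weights, dtype=float)
    if isinstance(lc, FixedPointReport):
        m = Mx = lc.node_rates
    else:
        m, Mx = lc.rate_min, lc.rate_max
    p_tonic = float(np.dot(weights, m > zero_tol))
    p_q = float(np.dot(weights, Mx <= zero_tol))
    p_burst = 1.0 - p_q - p_tonic
    return p_tonic, p_q, max(p_burst, 0.0)


def sweep_pburst(I_values, g_values, sigma_I: float, p: DimensionalParams,
                 M: int = 31, mode: str = "deterministic", seed=None,
                 zero_tol: float = 1e-8, **lc_kw):
    """p_burst / p_tonic / p_q over a (I_app, g_syn) mesh for a normal
    spread of applied currents.

    Returns a dict of 2-D arrays indexed [i_I, i_g].  Points where the
    attractor cannot be classified are recorded as NaN rather than
    aborting the sweep.
    """
    shape = (len(I_values), len(g_values))
    out = {k: np.full(shape, np.nan) for k in ("p_burst", "p_tonic", "p_q")}
    for i, I_app in enumerate(I_values):
        if sigma_I > 0:
            het = HeterogeneitySpec(
                {"I_app": DistributionSpec("normal", mu=I_app, sigma=sigma_I)})
        else:
            het = HeterogeneitySpec({})
        for j, g_syn in enumerate(g_values):
            pp = p.with_(I_app=I_app, g_syn=g_syn)
            grid = make_beta_grid(het, pp, M if het else 1, mode="auto",
                                  seed=seed)
            system = MFIII(nondimensionalize(pp), grid)
            try:
                lc = attractor_envelopes(system, **lc_kw)
            except UndeterminedAttractorError:
                continue
            pt, pq, pb = population_fractions(lc, grid.weights, zero_tol)
            out["p_tonic"][i, j] = pt
            out["p_q"][i, j] = pq
            out["p_burst"][i, j] = pb
    return out


def pburst_contours(field: np.ndarray, I_values, g_values,
                    eps: float = 1e-3):
    """0% and 100% bursting contour polylines of a p_burst field, by
    marching squares.  Returns {"zero": [...], "full": [...]} where each
    polyline is an (n, 2) array of (I_app, g_syn) points."""
    from skimage import measure
    out = {}
    I_values = np.asarray(I_values, float)
    g_values = np.asarray(g_values, float)
    for name, level in (("zero", eps), ("full", 1.0 - eps)):
        lines = []
        for c in measure.find_contours(np.nan_to_num(field), level):
            I_pts = np.interp(c[:, 0], np.arange(len(I_values)), I_values)
            g_pts = np.interp(c[:, 1], np.arange(len(g_values)), g_values)
            lines.append(np.column_stack([I_pts, g_pts]))
        out[name] = lines
    return out


def full_burst_area(field: np.ndarray, I_values, g_values,
                    level: float = 0.999) -> float:
    """Area (in parameter units) of the mesh cells whose p_burst reaches
    the given level; a simple monotone proxy for the area enclosed by the
    100% contour."""
    dI = np.mean(np.diff(I_values))
    dg = np.mean(np.diff(g_values))
    return float(np.nansum(field >= level) * dI * dg)
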