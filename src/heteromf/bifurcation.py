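"""Bifurcation location for the two-dimensional mean-field systems.

The planar systems (MFI, and MFII on a deterministic quadrature grid) are
smooth away from the switching manifold, so equilibria and Hopf points are
found by root finding and eigenvalue bisection.  The non-smooth events that
organize the onset of bursting -- the grazing of a limit cycle with the
switching manifold and the non-smooth saddle-node of limit cycles -- are
located by bisection on quantities measured from direct simulation:

* unstable cycles are obtained as attractors of the time-reversed flow,
  started near the stable tonic-firing focus they surround;
* the grazing parameter is where the minimum of H over the tracked cycle
  crosses zero;
* the saddle-node of limit cycles is the smallest parameter at which a
  forward simulation from a bursting state still settles on a limit cycle
  whose firing rate vanishes over part of the period.

Hopf criticality is classified from simulation: the amplitude of the
post-Hopf attractor is measured at several parameter offsets on the
unstable side; square-root growth marks a supercritical Hopf, an
offset-independent jump to a large-amplitude attractor a subcritical one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .heterogeneity import HeterogeneitySpec, make_beta_grid
from .meanfield import MFI, MFII, MFIICurrent
from .params import DimensionalParams, beta_scale, nondimensionalize


class RootFailureError(RuntimeError):
    pass


class NoBifurcationError(RuntimeError):
    pass


class UndeterminedAttractorError(RuntimeError):
    pass


@dataclass
class EquilibriumReport:
    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool
    branch: str                     # "firing" or "quiescent"
    residual: float

    @property
    def re_lead(self) -> float:
        return float(np.max(self.eigenvalues.real))


@dataclass
class BifurcationPoint:
    kind: str                       # "hopf" | "grazing" | "lc_saddle_node"
    param: str
    value: float
    criticality: str = "unknown"    # for Hopf: "super" | "sub" | "unknown"
    eigenvalues: np.ndarray | None = None
    bracket: tuple = ()
    extras: dict = field(default_factory=dict)


def make_mf_system(p: DimensionalParams, het: HeterogeneitySpec | None = None,
                   g_syn: float | None = None, I_app: float | None = None,
                   M: int = 20):
    """MFI for a homogeneous spec; for heterogeneity in the applied
    current alone, the firing-region-quadrature MFII (smooth Jacobian,
    which eigenvalue work requires); Gauss-Hermite MFII otherwise.
    """
    if g_syn is not None:
        p = p.with_(g_syn=g_syn)
    if I_app is not None:
        p = p.with_(I_app=I_app)
    q = nondimensionalize(p)
    if het is None or not het:
        return MFI(q)
    if set(het.names) == {"I_app"} and het.specs["I_app"].kind == "normal":
        spec = het.specs["I_app"]
        _, scale = beta_scale("I_app", p)
        return MFIICurrent(q, mu_I=spec.mu * scale, sigma_I=spec.sigma * scale)
    grid = make_beta_grid(het, p, M, mode="deterministic")
    return MFII(q, grid)


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------

def _default_guess(system) -> np.ndarray:
    """Damped self-consistency iteration toward the firing fixed point
    (generic systems without mean-field structure start at the origin)."""
    q = getattr(system, "q", None)
    if q is None or not hasattr(q, "tau_w"):
        return np.zeros(getattr(system, "dim", 2))
    w, s = 0.0, 0.0
    for _ in range(200):
        R = system.mean_rate((w, s))
        w_new = q.tau_w * q.w_jump * R
        s_new = q.tau_s * q.s_jump * R
        w = 0.7 * w + 0.3 * w_new
        s = 0.7 * s + 0.3 * s_new
    return np.array([w, s])


def _jacobian(system, state, h: float = 1e-7) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    n = len(state)
    J = np.empty((n, n))
    for j in range(n):
        dx = h * max(1.0, abs(state[j]))
        xp = state.copy(); xp[j] += dx
        xm = state.copy(); xm[j] -= dx
        J[:, j] = (np.asarray(system.rhs(0.0, xp))
                   - np.asarray(system.rhs(0.0, xm))) / (2 * dx)
    return J


def find_equilibrium(system, guess=None, raise_tol: float = 1e-9
                     ) -> EquilibriumReport:
    """Locate a fixed point of a planar mean-field system by Newton
    iteration from ``guess`` (default: damped self-consistency iterate),
    retrying from the self-consistency iterate and jittered starts if the
    first solve stalls.

    ``raise_tol`` is the residual above which the search is reported as
    failed.  The default is tight; callers scanning a quadrature-averaged
    system may loosen it, because when a quadrature node sits exactly on
    its switching manifold the sqrt-type kink puts a floor (~1e-8) on the
    achievable Newton residual even though the root exists.
    """
    guesses = []
    if guess is not None:
        guesses.append(np.asarray(guess, dtype=float))
    base = _default_guess(system)
    guesses.append(base)
    guesses.extend(base * f for f in (0.9, 1.1, 0.5))
    def polish(x):
        # damped Newton refinement; hybr can stall when a quadrature node
        # sits near its switching point (sqrt-type derivative blow-up)
        x = np.asarray(x, dtype=float)
        for _ in range(60):
            F = np.asarray(system.rhs(0.0, x))
            if np.max(np.abs(F)) < 1e-13:
                break
            try:
                step = np.linalg.solve(_jacobian(system, x), F)
            except np.linalg.LinAlgError:
                break
            lam = 1.0
            r0 = np.max(np.abs(F))
            for _ in range(20):
                r1 = np.max(np.abs(system.rhs(0.0, x - lam * step)))
                if r1 < r0:
                    break
                lam *= 0.5
            else:
                break
            x = x - lam * step
        return x

    sol = None
    best_x, best_res = None, np.inf
    for g0 in guesses:
        sol = root(lambda y: np.asarray(system.rhs(0.0, y)), g0,
                   method="hybr", tol=1e-13)
        x = polish(sol.x)
        res = float(np.max(np.abs(system.rhs(0.0, x))))
        if res < best_res:
            best_x, best_res = x, res
        if res < 1e-10:
            break
    if best_res > raise_tol:
        raise RootFailureError(
            f"equilibrium search failed (residual {best_res:.2e}); "
            "try multistart")
    x, res = best_x, best_res
    J = _jacobian(system, x)
    eig = np.linalg.eigvals(J)
    branch = "firing" if system.mean_rate(x) > 0.0 else "quiescent"
    return EquilibriumReport(state=x, eigenvalues=eig,
                             stable=bool(np.max(eig.real) < 0.0),
                             branch=branch, residual=res)


# ---------------------------------------------------------------------------
# Hopf bisection
# ---------------------------------------------------------------------------

def hopf_bisect(factory, lo: float, hi: float, param: str = "g_syn",
                tol: float = 1e-3, guess=None,
                eq_tol: float = 1e-6) -> BifurcationPoint:
    """Bisect on the leading eigenvalue real part of the continued
    equilibrium.  ``factory(value)`` must build the system at a parameter
    value; the equilibrium is continued by warm-starting each solve."""

    def relead(val, guess):
        eq = find_equilibrium(factory(val), guess, raise_tol=eq_tol)
        return eq.re_lead, eq

    f_lo, eq_lo = relead(lo, guess)
    f_hi, eq_hi = relead(hi, eq_lo.state)
    if f_lo == 0.0:
        return BifurcationPoint("hopf", param, lo, eigenvalues=eq_lo.eigenvalues)
    if f_hi == 0.0:
        return BifurcationPoint("hopf", param, hi, eigenvalues=eq_hi.eigenvalues)
    if np.sign(f_lo) == np.sign(f_hi):
        raise NoBifurcationError(
            f"no sign change of Re(lambda) on [{lo}, {hi}] "
            f"({f_lo:.3e} vs {f_hi:.3e})")
    state = eq_lo.state
    eig = eq_lo.eigenvalues
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid, eq_mid = relead(mid, state)
        state, eig = eq_mid.state, eq_mid.eigenvalues
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    value = 0.5 * (lo + hi)
    return BifurcationPoint("hopf", param, value, eigenvalues=eig,
                            bracket=(lo, hi))


# ---------------------------------------------------------------------------
# attractor amplitude probe (used by the criticality classifier)
# ---------------------------------------------------------------------------

def _attractor_amplitude(system, y0, chunk: float = 2500.0,
                         max_chunks: int = 24, settle_rtol: float = 0.03,
                         cap: float = 1e3, n_eval: int = 1200,
                         reverse: bool = False):
    """Integrate until the oscillation amplitude of the last state
    component settles; returns (amplitude, last chunk t, y).  Divergence
    beyond ``cap`` reports amplitude = cap."""
    rhs = system.rhs
    if reverse:
        rhs = lambda t, y, _f=system.rhs: -np.asarray(_f(t, y))
    y = np.asarray(y0, dtype=float)
    prev_amp = None
    t_eval = np.linspace(0.0, chunk, n_eval)
    for _ in range(max_chunks):
        with np.errstate(over="ignore", invalid="ignore"):
            sol = solve_ivp(rhs, (0.0, chunk), y, method="RK45",
                            rtol=1e-8, atol=1e-10, t_eval=t_eval)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            return cap, sol.t, sol.y.T
        traj = sol.y.T
        if np.max(np.abs(traj)) > cap:
            return cap, sol.t, traj
        y = traj[-1]
        tail = traj[len(traj) // 2:, -1]
        amp = float(tail.max() - tail.min())
        if prev_amp is not None:
            scale = max(amp, prev_amp, 1e-12)
            if abs(amp - prev_amp) / scale < settle_rtol:
                return amp, sol.t, traj
        prev_amp = amp
    return prev_amp if prev_amp is not None else 0.0, sol.t, traj


def classify_criticality(factory, hopf_value: float,
                         offsets=(0.01, 0.02, 0.04, 0.08),
                         perturb: float = 1e-4,
                         slope_super: float = 0.3,
                         slope_sub: float = 0.2) -> str:
    """Classify a Hopf point as supercritical or subcritical by the scaling
    of the post-Hopf attractor amplitude with the parameter offset.

    Supercritical: amplitude grows like the square root of the offset
    (log-log slope near 0.5).  Subcritical: the trajectory jumps to a
    distant attractor (or diverges) whose amplitude does not scale with
    the offset (slope near 0).  Returns "super", "sub" or "unknown".
    """
    # which side of the Hopf is unstable
    probe = 0.002 * abs(hopf_value)
    try:
        re_plus = find_equilibrium(factory(hopf_value + probe),
                                   raise_tol=1e-6).re_lead
    except RootFailureError:
        re_plus = -1.0
    side = 1.0 if re_plus > 0.0 else -1.0

    amps = []
    for d in offsets:
        val = hopf_value * (1.0 + side * d)
        system = factory(val)
        eq = find_equilibrium(system, raise_tol=1e-6)
        scale = max(abs(eq.state[-1]), 1e-3)
        y0 = eq.state.copy()
        y0[-1] += perturb * scale
        amp, _, _ = _attractor_amplitude(system, y0)
        amps.append(max(amp, 1e-14))
    amps = np.asarray(amps)
    slope = np.polyfit(np.log(np.asarray(offsets)), np.log(amps), 1)[0]
    if slope >= slope_super:
        return "super"
    if slope < slope_sub and amps[0] > 0.1 * amps[-1]:
        return "sub"
    return "unknown"


# ---------------------------------------------------------------------------
# unstable cycles by time reversal, grazing, saddle-node of limit cycles
# ---------------------------------------------------------------------------

@dataclass
class CycleSample:
    t: np.ndarray
    y: np.ndarray
    period: float
    min_H: float


def _peak_times(t: np.ndarray, x: np.ndarray):
    """Times and values of strict local maxima of a sampled signal."""
    i = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])) + 1
    return t[i], x[i]


def track_unstable_cycle(system, eq: EquilibriumReport | None = None,
                         perturb: float = 1e-3, chunk: float = 1500.0,
                         max_chunks: int = 40, peak_rtol: float = 2e-4,
                         cap: float = 1e3) -> CycleSample | None:
    """Track the unstable limit cycle surrounding a stable focus by
    integrating the time-reversed flow from a small perturbation off the
    equilibrium.  Returns the sampled cycle (one period, forward-time
    orientation) or None if the reversed flow diverges before settling.

    The reversed cycle is only weakly attracting near the fold of limit
    cycles, so integration tolerances are kept very tight; looser settings
    let local error kick the trajectory across the cycle into the
    divergent exterior.
    """
    if eq is None:
        eq = find_equilibrium(system)
    rhs_rev = lambda t, y: -np.asarray(system.rhs(0.0, y))
    y = eq.state.copy()
    y[-1] += perturb * max(abs(eq.state[-1]), 1e-3)
    n_eval = 3000
    period = None
    for _ in range(max_chunks):
        t_eval = np.linspace(0.0, chunk, n_eval)
        with np.errstate(over="ignore", invalid="ignore"):
            sol = solve_ivp(rhs_rev, (0.0, chunk), y, method="RK45",
                            rtol=1e-10, atol=1e-12, t_eval=t_eval)
        if not sol.success or np.max(np.abs(sol.y)) > cap:
            return None
        traj = sol.y.T
        y = traj[-1]
        pt, pv = _peak_times(sol.t, traj[:, -1])
        if len(pv) >= 4:
            last = pv[-4:]
            spread = (last.max() - last.min()) / max(abs(last.mean()), 1e-12)
            if spread < peak_rtol:
                period = float(np.mean(np.diff(pt[-4:])))
                break
    if period is None:
        return None
    # sample exactly one period densely, starting from the converged state
    t_eval = np.linspace(0.0, period, 2001)
    sol = solve_ivp(rhs_rev, (0.0, period), y, method="RK45",
                    rtol=1e-11, atol=1e-13, t_eval=t_eval)
    cyc = sol.y.T[::-1]     # forward-time orientation
    H = _cycle_H(system, cyc)
    return CycleSample(t=t_eval, y=cyc, period=period, min_H=float(H.min()))


def _cycle_H(system, traj: np.ndarray) -> np.ndarray:
    """H(<w>, s) along a planar trajectory, evaluated at the system's
    (mean) parameters."""
    q = system.q
    w = traj[:, 0]; s = traj[:, 1]
    c = q.alpha + q.g * s
    return q.I - w - c * c / 4.0 + q.g * q.e_r * s


def locate_grazing(factory, hi: float, param: str = "g_syn",
                   tol: float = 0.02, scan_step: float | None = None,
                   lo: float | None = None) -> BifurcationPoint:
    """Bisect on the sign of min_t H along the tracked unstable cycle.

    The unstable cycle born at the subcritical Hopf shrinks toward the
    equilibrium as the parameter approaches the Hopf value and expands
    away from it, so min_t H increases toward the Hopf.  ``hi`` must lie
    between the grazing and the Hopf (smooth cycle, min H > 0).  If
    ``lo`` is not supplied, the sign change is bracketed by stepping down
    from ``hi`` in steps of ``scan_step`` (default ``hi``/100) until the
    cycle becomes non-smooth."""

    def minH(val):
        """min_t H on the tracked cycle; -inf when the cycle no longer
        exists (past the fold, hence certainly below the grazing)."""
        cyc = track_unstable_cycle(factory(val))
        return -np.inf if cyc is None else cyc.min_H

    f_hi = minH(hi)
    if f_hi <= 0.0:
        raise NoBifurcationError(f"cycle already non-smooth at {param} = {hi}")
    if lo is None:
        step = scan_step if scan_step else hi / 100.0
        val = hi
        while True:
            val -= step
            if val <= 0.0:
                raise NoBifurcationError("scan reached zero without grazing")
            f = minH(val)
            if f <= 0.0:
                lo, f_lo = val, f
                break
            hi, f_hi = val, f
    else:
        f_lo = minH(lo)
        if f_lo > 0.0:
            raise NoBifurcationError(
                f"min H does not change sign on [{lo}, {hi}]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if minH(mid) > 0.0:
            hi = mid
        else:
            lo = mid
    return BifurcationPoint("grazing", param, 0.5 * (lo + hi),
                            bracket=(lo, hi))


def _is_bursting_attractor(system, y0, t_settle: float = 3000.0,
                           n_eval: int = 6000, amp_tol: float = 1e-3,
                           rate_tol: float = 1e-7) -> tuple[bool, np.ndarray]:
    """Forward-simulate and test whether the trajectory settles on a limit
    cycle whose firing rate vanishes over part of the period."""
    sol = solve_ivp(system.rhs, (0.0, t_settle), np.asarray(y0, dtype=float),
                    method="RK45", rtol=1e-8, atol=1e-10,
                    t_eval=np.linspace(0.0, t_settle, n_eval))
    if not sol.success:
        raise UndeterminedAttractorError(sol.message)
    traj = sol.y.T
    tail = traj[int(0.7 * len(traj)):]
    amp = tail[:, -1].max() - tail[:, -1].min()
    if amp < amp_tol:
        return False, traj[-1]
    rates = np.array([system.mean_rate(y) for y in tail])
    return bool(rates.min() <= rate_tol), traj[-1]


def locate_lc_saddle_node(factory, lo: float, hi: float, param: str = "g_syn",
                          tol: float = 0.02, t_settle: float = 3000.0,
                          y_burst=None) -> BifurcationPoint:
    """Bisect on the existence of the stable bursting limit cycle.

    ``hi`` must carry the bursting attractor; the initial condition for
    each probe is the attractor state harvested at ``hi`` (continuation by
    inheritance), so that the probe starts inside the cycle's basin
    whenever the cycle exists.  ``y_burst`` seeds the harvest at ``hi``
    (useful in bistable bands where a cold start converges to the
    equilibrium instead)."""
    system_hi = factory(hi)
    y0 = np.array([0.0, 0.0]) if y_burst is None else np.asarray(y_burst)
    exists_hi, y_burst = _is_bursting_attractor(system_hi, y0,
                                                t_settle=t_settle)
    if not exists_hi:
        raise NoBifurcationError(
            f"no bursting attractor at {param} = {hi}")
    exists_lo, _ = _is_bursting_attractor(factory(lo), y_burst,
                                          t_settle=t_settle)
    if exists_lo:
        raise NoBifurcationError(
            f"bursting attractor persists down to {param} = {lo}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        exists, y_end = _is_bursting_attractor(factory(mid), y_burst,
                                               t_settle=t_settle)
        if exists:
            hi = mid
            y_burst = y_end
        else:
            lo = mid
    return BifurcationPoint("lc_saddle_node", param, 0.5 * (lo + hi),
                            bracket=(lo, hi))


def locate_nonsmooth_bifurcation(factory, lo: float, hi: float,
                                 kind: str, param: str = "g_syn",
                                 tol: float = 0.02, **kw) -> BifurcationPoint:
    if kind == "grazing":
        return locate_grazing(factory, hi, lo=lo, param=param, tol=tol, **kw)
    if kind == "lc_saddle_node":
        return locate_lc_saddle_node(factory, lo, hi, param=param, tol=tol, **kw)
    raise ValueError(f"unknown non-smooth bifurcation kind {kind!r}")


def hopf_curve_2param(p: DimensionalParams, I_values, g_lo: float,
                      g_hi: float, het: HeterogeneitySpec | None = None,
                      M: int = 20, tol: float = 0.5,
                      classify: bool = False):
    """Low- and high-conductance Hopf points for each applied current.

    Returns a list of dicts (one per current value) with the two crossings
    and, optionally, the criticality of the low-conductance Hopf.  Slices
    where the equilibrium never destabilizes are recorded as None.
    """
    out = []
    for I_app in I_values:
        if het and "I_app" in het.names:
            # the slice current is the mean of the current distribution
            from dataclasses import replace as _replace
            spec = het.specs["I_app"]
            shifted = (_replace(spec, mu=float(I_app))
                       if spec.kind == "normal"
                       else spec)
            het_I = HeterogeneitySpec({**het.specs, "I_app": shifted})
        else:
            het_I = het
        factory = lambda g, _I=I_app, _h=het_I: make_mf_system(
            p, _h, g_syn=g, I_app=_I, M=M)
        # coarse scan for an interior unstable point
        gs = np.linspace(g_lo, g_hi, 25)
        res = []
        for g in gs:
            try:
                res.append(find_equilibrium(factory(g), raise_tol=1e-6).re_lead)
            except RootFailureError:
                res.append(np.nan)
        res = np.asarray(res)
        unstable = np.flatnonzero(res > 0.0)
        entry = {"I_app": float(I_app), "g_low": None, "g_high": None,
                 "criticality_low": None}
        if len(unstable):
            g_mid = gs[unstable[len(unstable) // 2]]
            try:
                low = hopf_bisect(factory, g_lo, g_mid, tol=tol)
                entry["g_low"] = low.value
                if classify:
                    entry["criticality_low"] = classify_criticality(
                        factory, low.value)
            except NoBifurcationError:
                pass
            try:
                high = hopf_bisect(factory, g_mid, g_hi, tol=tol)
                entry["g_high"] = high.value
            except NoBifurcationError:
                pass
        out.append(entry)
    return out
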