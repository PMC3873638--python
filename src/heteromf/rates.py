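"""Steady-state firing-rate distributions: forward prediction and inversion.

In a tonically firing heterogeneous network each neuron's steady rate is a
function of its heterogeneous parameter, R_i = g(beta_i), and this map is
well approximated by the steady state of the beta-conditioned mean field:
g(beta) ~ <R_i|beta>.  Treating g as a transformation of a random variable
gives the network's rate density

    rho_R(r) = rho_beta(g^{-1}(r)) |d g^{-1}/dr|,

and, symmetrically, a measured rate density can be pushed back through the
map to recover the parameter density,

    rho_beta(beta) = rho_R(g(beta)) |dg/dbeta|,

because at steady state the gating variable is pinned to
s_bar = tau_s s_jump <R>, which depends on the rate distribution only
through its (measurable) mean.  Both directions require g to be monotone.

Dimensional conventions: beta values are in the dimensional units of the
heterogeneous parameter (pA, nS, ms); rates at this interface are in
spikes per ms, matching the network simulator's last-ISI estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.signal import argrelmax

from .core import firing_rate_izh
from .heterogeneity import (BetaGrid, DistributionSpec, HeterogeneitySpec,
                            make_beta_grid)
from .meanfield import MFIII
from .params import (DimensionalParams, beta_scale, nondimensionalize)


class NotTonicError(RuntimeError):
    """The mean-field attractor is oscillatory; there is no steady rate map."""


class InvertibilityError(RuntimeError):
    """The conditional rate map is not monotone (or not differentiable)."""


class RangeError(ValueError):
    pass


@dataclass
class RateMap:
    """Tabulated steady-state conditional rate g(beta) = <R|beta>.

    ``beta`` is sorted ascending in the dimensional units of ``param``;
    ``rate`` is in spikes/ms.  ``s_bar`` records the self-consistent
    steady gating value (dimensionless) the map was computed at.
    """

    param: str
    beta: np.ndarray
    rate: np.ndarray
    s_bar: float

    @property
    def monotonic(self) -> bool:
        d = np.diff(self.rate)
        return bool(np.all(d > 0) or np.all(d < 0))

    def _strict(self):
        if not self.monotonic:
            raise InvertibilityError(
                "conditional rate map is not monotone on its grid")
        if self.rate[-1] < self.rate[0]:
            return self.beta[::-1], self.rate[::-1]
        return self.beta, self.rate

    def forward(self):
        """PCHIP interpolant of g(beta) (monotone-preserving)."""
        return PchipInterpolator(self.beta, self.rate)

    def inverse(self):
        """PCHIP interpolant of g^{-1}(rate)."""
        b, r = self._strict()
        return PchipInterpolator(r, b)


@dataclass
class DensityEstimate:
    """A density tabulated on a sorted support grid, normalized to 1."""

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.clip(np.asarray(self.density, dtype=float), 0.0, None)
        z = np.trapezoid(self.density, self.grid)
        if z <= 0:
            raise ValueError("density integrates to zero")
        self.density = self.density / z

    @property
    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))

    def cdf(self, x):
        c = np.concatenate([[0.0], cumulative_trapezoid(self.density, self.grid)])
        c = c / c[-1]
        return np.interp(x, self.grid, c, left=0.0, right=1.0)

    def mode_count(self, rel_height: float = 0.1) -> int:
        """Number of local maxima rising above rel_height of the peak."""
        idx = argrelmax(self.density, order=3)[0]
        peak = self.density.max()
        cand = [i for i in idx if self.density[i] >= rel_height * peak]
        if self.density[0] > self.density[1] and self.density[0] >= rel_height * peak:
            cand.append(0)
        return max(len(cand), 1)


# ---------------------------------------------------------------------------
# forward map
# ---------------------------------------------------------------------------

def _mfiii_steady_state(system: MFIII, t_chunk: float = 400.0,
                        max_chunks: int = 40, tol: float = 1e-9) -> np.ndarray:
    y = system.uniform_state()
    for _ in range(max_chunks):
        sol = solve_ivp(system.rhs, (0.0, t_chunk), y, method="RK45",
                        rtol=1e-9, atol=1e-11)
        y = sol.y[:, -1]
        if np.max(np.abs(system.rhs(0.0, y))) < tol:
            return y
    raise NotTonicError(
        "beta-conditioned mean field did not reach a fixed point; "
        "the network is not in the tonic-firing regime")


def _fixed_sbar_rates(q, grid: BetaGrid, s_bar: float):
    """Per-node steady (w, R) at a pinned gating value: solves
    w = tau_w w_jump R(w, s_bar, beta) node by node."""
    r = grid.resolved(q)
    I_j, g_j = r["I"], r["g"]
    wj, tw = r["w_jump"], r["tau_w"]
    w_out = np.empty(grid.M)
    R_out = np.empty(grid.M)
    for j in range(grid.M):
        def bal(w):
            return tw[j] * wj[j] * float(
                firing_rate_izh(w, s_bar, I_j[j], q, g=g_j[j])) - w
        hi = tw[j] * wj[j] * float(
            firing_rate_izh(0.0, s_bar, I_j[j], q, g=g_j[j])) + 1e-12
        if bal(0.0) <= 0.0:
            w_out[j] = 0.0
        else:
            w_out[j] = brentq(bal, 0.0, hi, xtol=1e-14)
        R_out[j] = float(firing_rate_izh(w_out[j], s_bar, I_j[j], q, g=g_j[j]))
    return w_out, R_out


def steady_conditional_rate_map(het: HeterogeneitySpec, p: DimensionalParams,
                                M: int = 200, mode: str = "from-dynamics",
                                R_bar: float | None = None,
                                grid: BetaGrid | None = None,
                                seed=None) -> RateMap:
    """Steady-state map beta -> <R|beta> for a single heterogeneous
    parameter.

    ``from-dynamics`` integrates the beta-conditioned mean field to its
    fixed point.  ``from-fixed-sbar`` pins the gating variable to
    s_bar = tau_s s_jump <R> (``R_bar``, dimensionless; taken from the
    converged dynamics when omitted) and solves the per-node adaptation
    balance by root finding -- the form used when inverting measured rate
    distributions, where <R> is known but the parameter density is not.
    """
    if len(het.specs) != 1:
        raise ValueError("rate maps require exactly one heterogeneous parameter")
    (name, _), = het.specs.items()
    q = nondimensionalize(p)
    if grid is None:
        grid = make_beta_grid(het, p, M, mode="auto", seed=seed)
    dname, scale = beta_scale(name, p)
    beta_dimless = grid.values[dname]
    order = np.argsort(beta_dimless)

    if mode == "from-dynamics":
        system = MFIII(q, grid)
        y = _mfiii_steady_state(system)
        R_j, _ = system.node_rates_and_v(y[:-1], y[-1])
        s_bar = float(y[-1])
    elif mode == "from-fixed-sbar":
        if R_bar is None:
            system = MFIII(q, grid)
            y = _mfiii_steady_state(system)
            R_bar = system.mean_rate(y)
        s_bar = q.tau_s * q.s_jump * float(R_bar)
        _, R_j = _fixed_sbar_rates(q, grid, s_bar)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    beta_dim = beta_dimless[order] / scale
    rate_per_ms = np.asarray(R_j)[order] / p.time_unit
    return RateMap(param=name, beta=beta_dim, rate=rate_per_ms, s_bar=s_bar)


def predict_rate_density(rate_map: RateMap, spec: DistributionSpec,
                         n_grid: int = 2000) -> DensityEstimate:
    """Push the parameter density through the rate map:
    rho_R(r) = rho_beta(beta) / |dg/dbeta| at r = g(beta)."""
    firing = rate_map.rate > 0.0
    if firing.sum() < 4:
        raise InvertibilityError("too few firing grid nodes to form a map")
    sub = RateMap(rate_map.param, rate_map.beta[firing],
                  rate_map.rate[firing], rate_map.s_bar)
    if not sub.monotonic:
        raise InvertibilityError("rate map is not monotone over the firing range")
    g = sub.forward()
    lo, hi = spec.support(nsigma=6.0)
    lo = max(lo, sub.beta[0]); hi = min(hi, sub.beta[-1])
    beta = np.linspace(lo, hi, n_grid)
    slope = g.derivative()(beta)
    if np.any(slope == 0.0):
        raise InvertibilityError("rate map has a flat spot in the support")
    r = g(beta)
    dens = spec.density(beta) / np.abs(slope)
    order = np.argsort(r)
    return DensityEstimate(grid=r[order], density=dens[order])


def smoothed_fI(spec_I: DistributionSpec, I_syn, q, M: int = 200):
    """Population-averaged f-I curve: F(I_syn) = E_I[ R(I + I_syn) ] for a
    distributed background current (dimensionless throughout, g = 0,
    w = 0).  A zero-width distribution reduces to the single-neuron curve;
    any spread smooths the square-root onset of firing.

    Normal spreads integrate over the firing region with the exact
    sqrt-absorbing substitution (machine-precision accurate); mixtures
    fall back to Monte Carlo with ``M`` deterministic-seeded samples per
    component handled through their normal parts.
    """
    from .meanfield import MFIICurrent
    I_syn = np.atleast_1d(np.asarray(I_syn, dtype=float))
    out = np.empty_like(I_syn)
    q0 = q.with_(g=0.0)
    if spec_I.kind == "normal" and spec_I.sigma == 0.0:
        out[:] = firing_rate_izh(0.0, 0.0, spec_I.mu + I_syn, q0)
    elif spec_I.kind == "normal":
        for i, Is in enumerate(I_syn):
            sys_i = MFIICurrent(q0, mu_I=spec_I.mu + Is,
                                sigma_I=spec_I.sigma, n_quad=M)
            out[i] = sys_i.moments(0.0, 0.0)[0]
    else:
        nodes, weights = spec_I.quadrature_nodes(M, "montecarlo", rng=0)
        for i, Is in enumerate(I_syn):
            out[i] = float(np.dot(weights,
                                  firing_rate_izh(0.0, 0.0, nodes + Is, q0)))
    return out if out.shape != (1,) else float(out[0])


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

_DEFAULT_BETA_RANGE = {
    "I_app": (200.0, 20000.0),
    "g_syn": (1.0, 900.0),
    "W_jump": (1.0, 900.0),
    "tau_W": (5.0, 1200.0),
}


def _uniform_grid_map(name: str, p: DimensionalParams, lo: float, hi: float,
                      M: int, R_bar_dimless: float) -> RateMap:
    dname, scale = beta_scale(name, p)
    nodes = np.linspace(lo, hi, M) * scale
    grid = BetaGrid(values={dname: nodes}, weights=np.full(M, 1.0 / M))
    het = HeterogeneitySpec({name: DistributionSpec("normal", mu=0.5 * (lo + hi),
                                                    sigma=(hi - lo) / 6)})
    return steady_conditional_rate_map(het, p, mode="from-fixed-sbar",
                                       R_bar=R_bar_dimless, grid=grid)


def invert_rate_density(rate_density: DensityEstimate, param: str,
                        p: DimensionalParams, beta_range=None,
                        M: int = 400) -> DensityEstimate:
    """Recover the parameter density from a measured steady-state rate
    density: pin s_bar from the density's mean rate, build the rate map,
    and apply rho_beta(beta) = rho_R(g(beta)) |dg/dbeta|."""
    R_bar = rate_density.mean * p.time_unit   # dimensionless mean rate
    lo, hi = beta_range if beta_range is not None else _DEFAULT_BETA_RANGE[param]
    wide = _uniform_grid_map(param, p, lo, hi, 150, R_bar)
    firing = wide.rate > 0.0
    sub = RateMap(param, wide.beta[firing], wide.rate[firing], wide.s_bar)
    if not sub.monotonic:
        raise InvertibilityError("rate map not monotone over the scan range")
    inv = sub.inverse()
    r_lo, r_hi = rate_density.grid[0], rate_density.grid[-1]
    r_lo = max(r_lo, sub.rate.min()); r_hi = min(r_hi, sub.rate.max())
    b_lo, b_hi = sorted((float(inv(r_lo)), float(inv(r_hi))))
    span = b_hi - b_lo
    fine = _uniform_grid_map(param, p, max(lo, b_lo - 0.05 * span),
                             min(hi, b_hi + 0.05 * span), M, R_bar)
    g = fine.forward()
    beta = np.linspace(fine.beta[0], fine.beta[-1], 4 * M)
    slope = g.derivative()(beta)
    dens = np.interp(g(beta), rate_density.grid, rate_density.density,
                     left=0.0, right=0.0) * np.abs(slope)
    return DensityEstimate(grid=beta, density=dens)


def recover_individual_params(rates_per_ms, rate_map: RateMap,
                              clamp: bool = True) -> np.ndarray:
    """Per-neuron parameter estimates beta_hat_i = g^{-1}(R_i) by monotone
    interpolation of the tabulated map.  Out-of-range rates are clamped to
    the map image (with a warning) unless ``clamp`` is False."""
    inv = rate_map.inverse()
    r = np.asarray(rates_per_ms, dtype=float)
    r_lo, r_hi = rate_map.rate.min(), rate_map.rate.max()
    out_of_range = (r < r_lo) | (r > r_hi)
    if np.any(out_of_range):
        if not clamp:
            raise RangeError(
                f"{int(out_of_range.sum())} rates outside the map image")
        warnings.warn(
            f"clamping {int(out_of_range.sum())} rates to the map image",
            stacklevel=2)
        r = np.clip(r, r_lo, r_hi)
    return inv(r)


def histogram_density(samples, bins="fd") -> DensityEstimate:
    """Density estimate of a sample by histogram (Freedman-Diaconis bins
    by default), on bin centers."""
    samples = np.asarray(samples, dtype=float)
    counts, edges = np.histogram(samples, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityEstimate(grid=centers, density=counts)


def ks_distance(density: DensityEstimate, samples) -> float:
    """Kolmogorov-Smirnov distance between a predicted density and an
    empirical sample."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    F = density.cdf(x)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(F - ecdf_hi)), np.max(np.abs(F - ecdf_lo))))


# ---------------------------------------------------------------------------
# multiple heterogeneous parameters
# ---------------------------------------------------------------------------

@dataclass
class MultiParamRates:
    """Sampled (beta_i, R_i) pairs from the steady beta-conditioned mean
    field with several heterogeneous parameters; the sampled rates
    estimate the rate density directly, and interpolation over the pairs
    predicts the rate of any neuron with known parameters."""

    names: tuple
    samples: dict                  # dimensional, one array per name
    rates: np.ndarray              # spikes/ms
    _interp: object = None

    def predict(self, query: dict) -> np.ndarray:
        """Interpolated rates at new parameter points (dimensional)."""
        pts = np.column_stack([np.asarray(query[n], float) for n in self.names])
        if self._interp is None:
            from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
            known = np.column_stack([self.samples[n] for n in self.names])
            lin = LinearNDInterpolator(known, self.rates)
            near = NearestNDInterpolator(known, self.rates)
            def f(xy, _lin=lin, _near=near):
                v = _lin(xy)
                bad = np.isnan(v)
                if np.any(bad):
                    v[bad] = _near(xy[bad])
                return v
            self._interp = f
        return self._interp(pts)


def recover_applied_currents(p: DimensionalParams, mu_I: float,
                             sigma_I: float, N: int = 1000,
                             T_sim: float = 2000.0, dt: float = 0.01,
                             seed: int = 0, map_points: int = 400) -> dict:
    """End-to-end recovery of per-neuron applied currents from spikes.

    Simulates a tonically firing network with normally distributed
    I_app,i, estimates each neuron's steady rate from its last interspike
    interval, builds the conditional rate map at the self-consistent
    s_bar implied by the measured mean rate, and inverts it neuron by
    neuron.  Returns the truth, the estimates, and the mean relative
    absolute error (as a fraction).
    """
    from .network import NetworkConfig, simulate_network, steady_rates

    het = HeterogeneitySpec(
        {"I_app": DistributionSpec("normal", mu=mu_I, sigma=sigma_I)})
    cfg = NetworkConfig(N=N, params=p, het=het, T_sim=T_sim, dt=dt,
                        seed=seed, record_traces=False)
    raster, _ = simulate_network(cfg)
    rates = steady_rates(raster)
    firing = rates > 0.0
    I_true = raster.draws["I_app"]

    R_bar = float(rates[firing].mean()) * p.time_unit
    lo = min(I_true.min(), mu_I - 5 * sigma_I)
    hi = max(I_true.max(), mu_I + 5 * sigma_I)
    wide = _uniform_grid_map("I_app", p, lo, hi, map_points, R_bar)
    fmask = wide.rate > 0.0
    sub = RateMap("I_app", wide.beta[fmask], wide.rate[fmask], wide.s_bar)
    I_hat = recover_individual_params(rates[firing], sub)
    err = np.abs(I_hat - I_true[firing]) / np.abs(I_true[firing])
    return {
        "I_true": I_true[firing], "I_hat": np.asarray(I_hat),
        "rates_per_ms": rates[firing], "n_firing": int(firing.sum()),
        "mean_rel_abs_error": float(err.mean()),
        "s_bar": wide.s_bar,
    }


def multiparam_rate_interpolation(het: HeterogeneitySpec,
                                  p: DimensionalParams, M: int = 600,
                                  seed=0) -> MultiParamRates:
    """Steady rates on a Monte Carlo sample of a multi-parameter
    heterogeneity spec (tonic regime required)."""
    grid = make_beta_grid(het, p, M, mode="montecarlo", seed=seed)
    q = nondimensionalize(p)
    system = MFIII(q, grid)
    y = _mfiii_steady_state(system)
    R_j, _ = system.node_rates_and_v(y[:-1], y[-1])
    samples = {}
    for name in het.names:
        dname, scale = beta_scale(name, p)
        samples[name] = grid.values[dname] / scale
    return MultiParamRates(names=tuple(het.names), samples=samples,
                           rates=np.asarray(R_j) / p.time_unit)
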