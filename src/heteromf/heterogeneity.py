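"""Parameter heterogeneity: distributions over single parameters, sampling,
quadrature, and the beta grids used by the beta-resolved mean-field systems.

A network draws each heterogeneous parameter independently from either a
normal distribution or a two-component normal mixture (the smooth stand-in
for two discrete subpopulations, e.g. strongly versus weakly adapting
cells).  All distributions are specified in the dimensional units of the
parameter they describe; the nondimensionalizing maps are linear, so the
same machinery serves the dimensionless side after a scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import roots_hermitenorm

from .params import DimensionalParams, DimensionlessParams, beta_scale


class DegenerateDistributionError(ValueError):
    """Density evaluation requested for a zero-width (point mass) spec."""


class UnsupportedModeError(ValueError):
    """Deterministic quadrature requested where only Monte Carlo applies."""


@dataclass(frozen=True)
class DistributionSpec:
    """A normal distribution or a two-component normal mixture.

    For ``kind='normal'`` use ``mu`` and ``sigma``.  For ``kind='mixture'``
    the density is m * N(mu1, sigma1) + (1 - m) * N(mu2, sigma2).
    """

    kind: str = "normal"
    mu: float = 0.0
    sigma: float = 0.0
    mu1: float = 0.0
    sigma1: float = 0.0
    mu2: float = 0.0
    sigma2: float = 0.0
    m: float = 0.5
    truncate_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "mixture"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        sigmas = (self.sigma,) if self.kind == "normal" else (self.sigma1, self.sigma2)
        if any(s < 0 for s in sigmas):
            raise ValueError("sigma must be nonnegative")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("mixture weight m must lie in [0, 1]")

    # -- moments ---------------------------------------------------------
    @property
    def mean(self) -> float:
        if self.kind == "normal":
            return self.mu
        return self.m * self.mu1 + (1.0 - self.m) * self.mu2

    @property
    def std(self) -> float:
        if self.kind == "normal":
            return self.sigma
        ex2 = (self.m * (self.mu1**2 + self.sigma1**2)
               + (1.0 - self.m) * (self.mu2**2 + self.sigma2**2))
        return float(np.sqrt(ex2 - self.mean**2))

    def support(self, nsigma: float = 8.0) -> tuple[float, float]:
        """An interval carrying all but ~1e-15 of the probability mass."""
        if self.kind == "normal":
            lo, hi = self.mu - nsigma * self.sigma, self.mu + nsigma * self.sigma
        else:
            lo = min(self.mu1 - nsigma * self.sigma1, self.mu2 - nsigma * self.sigma2)
            hi = max(self.mu1 + nsigma * self.sigma1, self.mu2 + nsigma * self.sigma2)
        if self.truncate_at_zero:
            lo = max(lo, 0.0)
        return lo, hi

    # -- density / sampling / quadrature ---------------------------------
    def density(self, beta) -> np.ndarray:
        beta = np.asarray(beta, dtype=float)
        if self.kind == "normal":
            if self.sigma == 0.0:
                raise DegenerateDistributionError(
                    "point mass has no density; sigma = 0")
            out = stats.norm.pdf(beta, self.mu, self.sigma)
        else:
            if self.sigma1 == 0.0 or self.sigma2 == 0.0:
                raise DegenerateDistributionError(
                    "mixture component with sigma = 0 has no density")
            out = (self.m * stats.norm.pdf(beta, self.mu1, self.sigma1)
                   + (1.0 - self.m) * stats.norm.pdf(beta, self.mu2, self.sigma2))
        if self.truncate_at_zero:
            mass = 1.0 - self.cdf_untruncated(0.0)
            out = np.where(beta < 0.0, 0.0, out / mass)
        return out

    def cdf_untruncated(self, x) -> np.ndarray:
        if self.kind == "normal":
            return stats.norm.cdf(x, self.mu, self.sigma)
        return (self.m * stats.norm.cdf(x, self.mu1, self.sigma1)
                + (1.0 - self.m) * stats.norm.cdf(x, self.mu2, self.sigma2))

    def cdf(self, x) -> np.ndarray:
        c = self.cdf_untruncated(x)
        if self.truncate_at_zero:
            c0 = self.cdf_untruncated(0.0)
            c = np.clip((c - c0) / (1.0 - c0), 0.0, 1.0)
        return c

    def sample(self, n: int, rng) -> np.ndarray:
        """Draw ``n`` reproducible values; ``rng`` is a seed or Generator."""
        rng = np.random.default_rng(rng)
        if self.kind == "normal":
            draws = rng.normal(self.mu, self.sigma, size=n)
        else:
            pick1 = rng.random(n) < self.m
            draws = np.where(
                pick1,
                rng.normal(self.mu1, self.sigma1, size=n),
                rng.normal(self.mu2, self.sigma2, size=n),
            )
        if self.truncate_at_zero:
            bad = draws < 0.0
            while np.any(bad):  # redraw; truncation mass is assumed small
                draws[bad] = self.sample(int(bad.sum()), rng)
                bad = draws < 0.0
        return draws

    def quadrature_nodes(self, M: int, mode: str = "deterministic",
                         rng=None) -> tuple[np.ndarray, np.ndarray]:
        """Nodes and weights for integrals against this density.

        ``deterministic`` gives Gauss-Hermite nodes mapped to (mu, sigma)
        and is exact for polynomials of degree 2M-1; it is only available
        for an untruncated 1-D normal.  ``montecarlo`` gives M i.i.d.
        samples with uniform weights 1/M.
        """
        if M < 1:
            raise ValueError("M must be >= 1")
        if mode == "deterministic":
            if self.kind != "normal" or self.truncate_at_zero:
                raise UnsupportedModeError(
                    "deterministic quadrature supports only untruncated normals")
            x, wts = roots_hermitenorm(M)
            nodes = self.mu + self.sigma * x
            weights = wts / wts.sum()
            return nodes, weights
        if mode == "montecarlo":
            nodes = self.sample(M, rng)
            return nodes, np.full(M, 1.0 / M)
        raise ValueError(f"unknown quadrature mode {mode!r}")

    def scaled(self, c: float) -> "DistributionSpec":
        """The distribution of c * beta (linear unit change)."""
        if self.kind == "normal":
            return DistributionSpec("normal", mu=c * self.mu,
                                    sigma=abs(c) * self.sigma,
                                    truncate_at_zero=self.truncate_at_zero)
        return DistributionSpec(
            "mixture", mu1=c * self.mu1, sigma1=abs(c) * self.sigma1,
            mu2=c * self.mu2, sigma2=abs(c) * self.sigma2, m=self.m,
            truncate_at_zero=self.truncate_at_zero)


_KNOWN_PARAMS = ("I_app", "g_syn", "W_jump", "tau_W")


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Mapping of dimensional parameter names to their distributions.

    Parameters absent from the mapping are homogeneous at the base value.
    Heterogeneous parameters are drawn independently of one another.
    """

    specs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.specs:
            if name not in _KNOWN_PARAMS:
                raise ValueError(
                    f"unknown heterogeneous parameter {name!r}; "
                    f"choose from {_KNOWN_PARAMS}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.specs)

    def __bool__(self) -> bool:
        return bool(self.specs)

    def sample_dimensional(self, n: int, rng) -> dict[str, np.ndarray]:
        """Independent per-neuron draws, one array per heterogeneous
        parameter, in dimensional units."""
        rng = np.random.default_rng(rng)
        return {name: spec.sample(n, rng) for name, spec in self.specs.items()}


@dataclass(frozen=True)
class BetaGrid:
    """Discretization of the heterogeneous-parameter distribution used by
    the beta-resolved mean-field systems.

    ``values`` maps dimensionless parameter names (I, g, w_jump, tau_w) to
    node arrays of common length M; ``weights`` sum to one.  Deterministic
    (Gauss-Hermite) grids exist only for a single normal parameter; the
    general case is a Monte Carlo grid whose nodes are density samples with
    uniform weights.
    """

    values: dict
    weights: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("grid weights must sum to 1")
        M = len(w)
        for name, arr in self.values.items():
            if len(arr) != M:
                raise ValueError(f"node array {name!r} has wrong length")

    @property
    def M(self) -> int:
        return len(self.weights)

    def resolved(self, q: DimensionlessParams) -> dict[str, np.ndarray]:
        """Per-node dimensionless parameters, broadcast to length M, with
        homogeneous parameters filled in from ``q``."""
        M = self.M
        out = {
            "I": np.full(M, q.I),
            "g": np.full(M, q.g),
            "w_jump": np.full(M, q.w_jump),
            "tau_w": np.full(M, 1.0 / q.a),
        }
        for name, arr in self.values.items():
            out[name] = np.asarray(arr, dtype=float)
        return out


def make_beta_grid(het: HeterogeneitySpec, p: DimensionalParams, M: int,
                   mode: str = "auto", seed=None) -> BetaGrid:
    """Build a dimensionless beta grid from a dimensional heterogeneity spec.

    ``mode='auto'`` picks Gauss-Hermite for a single normal parameter
    (smooth in parameters, which root finding needs) and Monte Carlo
    otherwise.
    """
    if not het:
        return BetaGrid(values={}, weights=np.array([1.0]), seed=None)
    if mode == "auto":
        single_normal = (len(het.specs) == 1
                         and next(iter(het.specs.values())).kind == "normal"
                         and not next(iter(het.specs.values())).truncate_at_zero)
        mode = "deterministic" if single_normal else "montecarlo"
    if mode == "deterministic":
        if len(het.specs) != 1:
            raise UnsupportedModeError(
                "deterministic grids support a single heterogeneous parameter")
        (name, spec), = het.specs.items()
        dname, scale = beta_scale(name, p)
        nodes, weights = spec.scaled(scale).quadrature_nodes(M, "deterministic")
        return BetaGrid(values={dname: nodes}, weights=weights, seed=None)
    rng = np.random.default_rng(seed)
    values = {}
    for name, spec in het.specs.items():
        dname, scale = beta_scale(name, p)
        values[dname] = spec.scaled(scale).sample(M, rng)
    return BetaGrid(values=values, weights=np.full(M, 1.0 / M),
                    seed=seed if isinstance(seed, int) else None)
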