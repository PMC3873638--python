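"""Quasi-steady-state firing-rate building blocks shared by all mean-field
systems.

Under the quasi-steady-state closure the fast voltage density equilibrates
instantaneously relative to the slow adaptation and gating variables, and
the population firing rate becomes an algebraic function of (<w>, s).  The
rate switches between zero and the positive branch on the manifold

    H(<w>, s) = I - <w> + min_v [ F(v) + g (e_r - v) s ],

which for the quadratic F(v) = v(v - alpha) evaluates to

    H = I - <w> - (alpha + g s)^2 / 4 + g e_r s.

On the firing branch (H >= 0) the rate is the reciprocal of the transit
time of the deterministic voltage from v_reset to v_peak, which has a
closed arctan form; the rate tends to 0 continuously as H -> 0+.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .params import DimensionlessParams


class InconsistentModelError(RuntimeError):
    """The voltage drift changes sign inside [v_reset, v_peak] while the
    switching function claims the neuron is firing."""


def _resolve(I, g, p: DimensionlessParams):
    I = p.I if I is None else I
    g = p.g if g is None else g
    return I, g


def switching_H(w_mean, s, I=None, p: DimensionlessParams = None, *, g=None):
    """Switching function H(<w>, s) of the quadratic model.

    ``I`` and ``g`` default to the values carried by ``p``; passing arrays
    broadcasts, which is how the beta-resolved mean-field systems evaluate
    their conditional rates in one call.
    """
    I, g = _resolve(I, g, p)
    c = p.alpha + g * np.asarray(s, dtype=float)
    return I - np.asarray(w_mean, dtype=float) - c * c / 4.0 + g * p.e_r * s


def firing_rate_izh(w_mean, s, I=None, p: DimensionlessParams = None, *, g=None):
    """Closed-form quasi-steady population firing rate of the Izhikevich
    model (dimensionless time).  Returns 0 on the quiescent branch H <= 0."""
    I, g = _resolve(I, g, p)
    w = np.asarray(w_mean, dtype=float)
    s_arr = np.asarray(s, dtype=float)
    c = (p.alpha + g * s_arr) / 2.0
    H = I - w - c * c + g * p.e_r * s_arr
    scalar = np.ndim(H) == 0
    H = np.atleast_1d(H)
    c = np.broadcast_to(np.atleast_1d(c), H.shape)
    out = np.zeros_like(H)
    pos = H > 0.0
    if np.any(pos):
        rt = np.sqrt(H[pos])
        cc = c[pos]
        span = np.arctan((p.v_peak - cc) / rt) - np.arctan((p.v_reset - cc) / rt)
        out[pos] = rt / span
    return out[0] if scalar else out


def mean_v_izh(w_mean, s, I=None, p: DimensionlessParams = None, *, g=None):
    """Quasi-steady network-mean voltage <v>.

    Firing branch: time average of v over the reset-to-peak transit.
    Quiescent branch: the stable subthreshold equilibrium, the smaller
    root of F(v) - <w> + I + g (e_r - v) s = 0.
    """
    I, g = _resolve(I, g, p)
    w = np.asarray(w_mean, dtype=float)
    s_arr = np.asarray(s, dtype=float)
    c = (p.alpha + g * s_arr) / 2.0
    H = I - w - c * c + g * p.e_r * s_arr
    scalar = np.ndim(H) == 0
    H = np.atleast_1d(H)
    c = np.broadcast_to(np.atleast_1d(c).astype(float), H.shape).copy()
    out = np.empty_like(H)
    pos = H >= 0.0
    if np.any(pos):
        rt = np.sqrt(H[pos])
        cc = c[pos]
        with np.errstate(divide="ignore", invalid="ignore"):
            span = np.arctan((p.v_peak - cc) / rt) - np.arctan((p.v_reset - cc) / rt)
            R = np.where(rt > 0.0, rt / span, 0.0)
        num = (p.v_peak - cc) ** 2 + H[pos]
        den = (p.v_reset - cc) ** 2 + H[pos]
        out[pos] = 0.5 * R * np.log(num / den) + cc
    neg = ~pos
    if np.any(neg):
        out[neg] = c[neg] - np.sqrt(-H[neg])
    return out[0] if scalar else out


def rate_and_mean_v(w, s, I, g, p: DimensionlessParams):
    """Joint vectorized evaluation of (R, <v>) used by the mean-field
    right-hand sides; computes H once."""
    w = np.asarray(w, dtype=float)
    I = np.asarray(I, dtype=float)
    g = np.asarray(g, dtype=float)
    c = (p.alpha + g * s) / 2.0
    H = I - w - c * c + g * p.e_r * s
    H, c = np.broadcast_arrays(np.atleast_1d(H), np.atleast_1d(c))
    R = np.zeros_like(H)
    v = np.empty_like(H)
    pos = H > 0.0
    if np.any(pos):
        rt = np.sqrt(H[pos])
        cc = c[pos]
        span = np.arctan((p.v_peak - cc) / rt) - np.arctan((p.v_reset - cc) / rt)
        R[pos] = rt / span
        num = (p.v_peak - cc) ** 2 + H[pos]
        den = (p.v_reset - cc) ** 2 + H[pos]
        v[pos] = 0.5 * R[pos] * np.log(num / den) + cc
    neg = ~pos
    if np.any(neg):
        v[neg] = c[neg] - np.sqrt(-H[neg])
    return R, v


def rate_by_quadrature(w_mean, s, I, p: DimensionlessParams, *, g=None,
                       F=None, tol: float = 1e-12):
    """Firing rate via adaptive quadrature of the transit-time integral

        R = [ integral_{v_reset}^{v_peak} dv / (F(v) - w + I + g (e_r - v) s) ]^{-1}

    for a general membrane nonlinearity ``F`` (defaults to the quadratic).
    Serves as the general-model fallback and the numerical oracle for the
    closed forms.
    """
    I, g = _resolve(I, g, p)
    if F is None:
        F = lambda v: v * (v - p.alpha)
    drift = lambda v: F(v) - w_mean + I + g * (p.e_r - v) * s
    # switching value: minimum of the drift over all v
    res = minimize_scalar(drift, bounds=(p.v_reset - 10.0, p.v_peak + 10.0),
                          method="bounded")
    H = res.fun
    if H < 0.0:
        return 0.0
    lo = min(drift(p.v_reset), drift(p.v_peak), drift(0.5 * (p.v_reset + p.v_peak)))
    if lo <= 0.0:
        raise InconsistentModelError(
            "drift changes sign inside [v_reset, v_peak] although H >= 0"
        )
    val, _ = quad(lambda v: 1.0 / drift(v), p.v_reset, p.v_peak,
                  epsabs=tol, epsrel=tol, limit=200)
    return 1.0 / val


def mean_v_by_quadrature(w_mean, s, I, p: DimensionlessParams, *, g=None,
                         tol: float = 1e-12):
    """Time-averaged voltage R * integral v dv / drift(v); oracle for
    :func:`mean_v_izh` on the firing branch."""
    I, g = _resolve(I, g, p)
    drift = lambda v: v * (v - p.alpha) - w_mean + I + g * (p.e_r - v) * s
    inv, _ = quad(lambda v: 1.0 / drift(v), p.v_reset, p.v_peak,
                  epsabs=tol, epsrel=tol, limit=200)
    num, _ = quad(lambda v: v / drift(v), p.v_reset, p.v_peak,
                  epsabs=tol, epsrel=tol, limit=200)
    return num / inv
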