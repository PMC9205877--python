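"""Wiener first-passage-time machinery for the two-boundary drift-diffusion model.

The accumulator starts at ``z`` between an absorbing lower boundary at 0 and an
upper boundary at ``a``, drifts with rate ``v`` and unit diffusion coefficient,
and the observed response time is the first-passage time plus a non-decision
offset ``t0``.  Throughout the package the *upper* boundary codes cooperation.

Densities use the dual small-time / large-time series representation with an
accuracy-based switch between the two expansions; both are evaluated fully
vectorised over response times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["DDMParams", "fpt_density", "choice_probability", "simulate"]


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters on the unit-diffusion scale.

    a : boundary separation (evidence units), > 0
    z : starting point, 0 < z < a
    v : drift rate (evidence units / s); positive drifts toward the upper boundary
    t0 : non-decision time (s), >= 0
    eta : inter-trial SD of drift (optional)
    sz : inter-trial range of the starting point (optional)
    st : inter-trial range of the non-decision time (optional)
    """

    a: float
    z: float
    v: float
    t0: float
    eta: float = 0.0
    sz: float = 0.0
    st: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if not (0 < self.z < self.a):
            raise ValueError(f"starting point must satisfy 0 < z < a, got z={self.z}, a={self.a}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time must be nonnegative, got t0={self.t0}")
        if min(self.eta, self.sz, self.st) < 0:
            raise ValueError("inter-trial variabilities must be nonnegative")
        if self.sz >= 2 * min(self.z, self.a - self.z):
            raise ValueError("sz must be < 2*min(z, a-z) so the start point stays inside")
        if self.st > 0 and self.st >= 2 * self.t0:
            raise ValueError("st must be < 2*t0 so non-decision time stays positive")

    @property
    def b(self) -> float:
        """Starting bias z/a, in (0, 1); 0.5 means no initial preference."""
        return self.z / self.a

    @classmethod
    def from_scale(cls, a: float, z: float, v: float, t0: float, s: float = 0.1, **kw) -> "DDMParams":
        """Convert parameters quoted with diffusion coefficient ``s`` (legacy
        toolboxes use s = 0.1) to the unit-diffusion scale used internally.

        The diffusion process is scale-free: dividing a, z, v (and eta, sz) by
        s leaves every first-passage probability and time unchanged.
        """
        eta = kw.pop("eta", 0.0) / s
        sz = kw.pop("sz", 0.0) / s
        st = kw.pop("st", 0.0)
        return cls(a / s, z / s, v / s, t0, eta=eta, sz=sz, st=st)

    def replace(self, **kw) -> "DDMParams":
        return replace(self, **kw)


def _f0_lower(tnorm: np.ndarray, w: float, eps: float) -> np.ndarray:
    """Density of first passage through the lower boundary for the normalised
    process (a=1, v=0, start w) at normalised time tnorm.

    Evaluates whichever of the small-time and large-time series needs fewer
    terms for truncation error <= eps, per element.
    """
    t = np.asarray(tnorm, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    if tp.size == 0:
        return out

    # required number of terms in each expansion
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = 2.0 * np.sqrt(2.0 * np.pi * tp) * eps
        ks = np.where(
            arg < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * tp * np.log(np.maximum(arg, 1e-300)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(tp) + 1.0)
        argl = np.pi * tp * eps
        kl = np.where(
            argl < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.maximum(argl, 1e-300)), 0.0) / (np.pi**2 * tp)),
            1.0 / (np.pi * np.sqrt(tp)),
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(tp)))

    use_small = ks < kl
    res = np.empty_like(tp)

    if np.any(use_small):
        ts = tp[use_small]
        K = int(math.ceil((ks[use_small].max() - 1.0) / 2.0))
        k = np.arange(-K, K + 1)[:, None]
        term = (w + 2.0 * k) * np.exp(-((w + 2.0 * k) ** 2) / (2.0 * ts[None, :]))
        res[use_small] = term.sum(axis=0) / np.sqrt(2.0 * np.pi * ts**3)

    if np.any(~use_small):
        tl = tp[~use_small]
        K = max(int(math.ceil(kl[~use_small].max())), 1)
        k = np.arange(1, K + 1)[:, None]
        term = k * np.exp(-(k**2) * (np.pi**2) * tl[None, :] / 2.0) * np.sin(k * np.pi * w)
        res[~use_small] = np.pi * term.sum(axis=0)

    out[pos] = np.maximum(res, 0.0)
    return out


def _density_lower(t_dec: np.ndarray, a: float, z: float, v: float, eps: float) -> np.ndarray:
    """First-passage density at the lower boundary as a function of decision
    time (response time minus non-decision time)."""
    t_dec = np.asarray(t_dec, dtype=float)
    w = z / a
    tnorm = t_dec / a**2
    f0 = _f0_lower(tnorm, w, eps)
    with np.errstate(over="ignore"):
        fac = np.exp(-v * a * w - (v**2) * t_dec / 2.0) / a**2
    return f0 * fac


def _quad_nodes(params: DDMParams, n_eta: int = 7, n_unif: int = 7):
    """Node/weight grids integrating over enabled inter-trial variabilities.

    Returns a list of (DDMParams-without-variability, weight) pairs whose
    weighted densities average to the variability-mixed density.
    """
    grids = [(params.replace(eta=0.0, sz=0.0, st=0.0), 1.0)]
    if params.eta > 0:
        x, w = np.polynomial.hermite_e.hermegauss(n_eta)  # N(0,1) nodes
        w = w / w.sum()
        grids = [(p.replace(v=p.v + params.eta * xi), wt * wi) for (p, wt) in grids for xi, wi in zip(x, w)]
    if params.sz > 0:
        x, w = np.polynomial.legendre.leggauss(n_unif)
        w = w / w.sum()
        grids = [(p.replace(z=p.z + params.sz * xi / 2.0), wt * wi) for (p, wt) in grids for xi, wi in zip(x, w)]
    if params.st > 0:
        x, w = np.polynomial.legendre.leggauss(n_unif)
        w = w / w.sum()
        grids = [(p.replace(t0=p.t0 + params.st * xi / 2.0), wt * wi) for (p, wt) in grids for xi, wi in zip(x, w)]
    return grids


def fpt_density(t, params: DDMParams, boundary: str = "upper", eps: float = 1e-12) -> np.ndarray:
    """Density (1/s) of a response at ``boundary`` at response time ``t``.

    ``t`` is the full response time; the density is zero for t <= t0 by
    convention.  Inter-trial variabilities, when set, are integrated by
    Gauss-Hermite (drift) and Gauss-Legendre (start point, non-decision time)
    quadrature.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    for p, wt in _quad_nodes(params):
        t_dec = t - p.t0
        if boundary == "lower":
            d = _density_lower(t_dec, p.a, p.z, p.v, eps)
        else:
            d = _density_lower(t_dec, p.a, p.a - p.z, -p.v, eps)
        out += wt * d
    return out


def _prob_upper(a: float, z: float, v: float) -> float:
    if abs(v) < 1e-10:
        return z / a
    # (1 - exp(-2 v z)) / (1 - exp(-2 v a)), written with expm1 for stability
    num = -math.expm1(-2.0 * v * z)
    den = -math.expm1(-2.0 * v * a)
    return num / den


def choice_probability(params: DDMParams, boundary: str = "upper") -> float:
    """Probability of absorption at ``boundary`` (upper + lower = 1)."""
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    p_up = 0.0
    for p, wt in _quad_nodes(params):
        p_up += wt * _prob_upper(p.a, p.z, p.v)
    return p_up if boundary == "upper" else 1.0 - p_up


def simulate(
    params: DDMParams,
    n: int,
    rng: np.random.Generator,
    dt: float = 1e-3,
    t_max: float = 20.0,
    bridge: bool = False,
):
    """Simulate ``n`` first passages by the Euler scheme.

    Returns ``(upper, rt)`` where ``upper`` is a boolean array (True = upper
    boundary) and ``rt`` the response times including non-decision time.
    Trajectories not absorbed by ``t_max`` (vanishingly rare for sensible
    parameters) are assigned the nearer boundary at ``t_max``.

    With ``bridge=True`` an exact Brownian-bridge crossing probability is
    added for undetected within-step boundary crossings, removing most of the
    O(sqrt(dt)) discretisation bias of the plain scheme.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    v = np.full(n, params.v)
    if params.eta > 0:
        v = v + params.eta * rng.standard_normal(n)
    x = np.full(n, params.z)
    if params.sz > 0:
        x = x + params.sz * (rng.random(n) - 0.5)
    t0 = np.full(n, params.t0)
    if params.st > 0:
        t0 = t0 + params.st * (rng.random(n) - 0.5)

    a = params.a
    sqdt = math.sqrt(dt)
    alive = np.arange(n)
    upper = np.zeros(n, dtype=bool)
    rt = np.full(n, t_max)
    n_steps = int(round(t_max / dt))
    for step in range(1, n_steps + 1):
        m = alive.size
        if m == 0:
            break
        x_old = x[alive]
        x_new = x_old + v[alive] * dt + sqdt * rng.standard_normal(m)
        hit_up = x_new >= a
        hit_lo = x_new <= 0.0
        if bridge:
            open_ = ~(hit_up | hit_lo)
            if np.any(open_):
                xo, xn = x_old[open_], x_new[open_]
                p_up = np.exp(-2.0 * (a - xo) * (a - xn) / dt)
                p_lo = np.exp(-2.0 * xo * xn / dt)
                u = rng.random(open_.sum())
                cross_up = u < p_up
                cross_lo = (u >= p_up) & (u < p_up + p_lo)
                tmp_up = hit_up.copy()
                tmp_lo = hit_lo.copy()
                tmp_up[np.flatnonzero(open_)[cross_up]] = True
                tmp_lo[np.flatnonzero(open_)[cross_lo]] = True
                hit_up, hit_lo = tmp_up, tmp_lo
        done = hit_up | hit_lo
        if np.any(done):
            idx = alive[done]
            upper[idx] = hit_up[done]
            rt[idx] = step * dt
            alive = alive[~done]
            x[alive] = x_new[~done]
        else:
            x[alive] = x_new
    if alive.size:  # force unabsorbed walkers to the nearer boundary
        upper[alive] = x[alive] >= a / 2.0
    return upper, rt + t0
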