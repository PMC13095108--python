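"""Planar normalizing-flow calculus.

A planar flow is the invertible map

    z' = z + u_hat * tanh(w.z + b)

whose Jacobian determinant has the closed rank-one form
``1 + tanh'(w.z + b) * (w.u_hat)``. Composing K such steps transforms a
diagonal-Gaussian base density into a flexible, potentially multimodal one
while keeping exact densities via the change-of-variables formula: the
log-density of a flowed point is the base log-density minus the
accumulated log|det Jacobian|.

Invertibility is guaranteed by reparameterizing the direction vector so
that ``w.u_hat >= -1 + eps`` (softplus construction); the scalar map
``a -> a + (w.u_hat) * tanh(a + b)`` is then strictly monotone, which both
proves bijectivity and gives the numerical inversion route used here
(bracketed 1-D root-find).

All forward-path functions accept either numpy arrays or
:class:`~snpflow.autodiff.Tensor`, so the same code evaluates densities
numerically and sits inside a differentiable training graph. Inversion and
exact log-density evaluation are numpy-only (they are never
differentiated through).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from . import autodiff as ad

_EPS = 1e-6  # invertibility margin: w.u_hat >= -1 + softplus margin
_LOG_FLOOR = 1e-12

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class FlowStep:
    """Parameters of one planar transformation.

    ``u`` is the (unconstrained) direction vector, ``w`` the gating vector
    and ``b`` the scalar bias. The activation is fixed to tanh. Parameters
    may be numpy arrays or autodiff Tensors.
    """

    u: Any
    w: Any
    b: Any
    activation: str = "tanh"


@dataclass
class FlowChain:
    """An ordered composition of planar steps acting on a D-dim space."""

    steps: List[FlowStep] = field(default_factory=list)
    dim: int = 0

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class FlowedDensity:
    """A diagonal-Gaussian base density pushed through a flow chain."""

    mu: Any
    sigma: Any
    chain: FlowChain


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, ad.Tensor) else np.asarray(x, dtype=np.float64)


def constrain_direction(step: FlowStep):
    """Return the constrained direction u_hat with ``w.u_hat >= -1 + eps``.

    Uses the smooth reparameterization
    ``u_hat = u + (m(a) - a) w / ||w||^2`` with ``a = w.u`` and
    ``m(a) = -1 + softplus(a)``, which maps any u onto the invertible
    region while leaving already-valid directions nearly unchanged for
    large ``a``.
    """
    u, w = step.u, step.w
    wnorm2 = ad.asum(w * w)
    if float(_data(wnorm2)) < 1e-24:
        raise ValueError("degenerate planar step: w has (near-)zero norm")
    a = ad.asum(w * u)
    m = -1.0 + ad.softplus(a)
    return u + ((m - a) / wnorm2) * w


def constrain_step(step: FlowStep) -> FlowStep:
    """A copy of ``step`` whose direction is the constrained u_hat."""
    return FlowStep(u=constrain_direction(step), w=step.w, b=step.b,
                    activation=step.activation)


def planar_forward(z, step: FlowStep) -> Tuple[Any, Any]:
    """Apply one planar step to ``z`` (shape (..., D)).

    The step is taken as already constrained (its ``u`` is the direction
    u_hat satisfying ``w.u >= -1``); pass raw parameters through
    :func:`constrain_step` first. Returns ``(z', logdet)`` where ``logdet``
    has the batch shape of ``z`` minus the trailing feature axis.
    """
    u_hat, w, b = step.u, step.w, step.b
    a = ad.asum(z * w, axis=-1) + b  # (...,)
    h = ad.tanh(a)
    hprime = 1.0 - h * h
    wu = ad.asum(w * u_hat)
    det = 1.0 + hprime * wu  # > 0 when the invertibility constraint holds
    logdet = ad.log(ad.clip(det, _LOG_FLOOR, np.inf))
    if _data(z).ndim == 1:
        z_new = z + u_hat * h
    else:
        hcol = h.reshape(*_data(h).shape, 1) if isinstance(h, ad.Tensor) else h[..., None]
        z_new = z + hcol * u_hat
    return z_new, logdet


def planar_inverse(z_prime: np.ndarray, step: FlowStep, tol: float = 1e-12,
                   max_iter: int = 200) -> np.ndarray:
    """Invert one planar step (numpy only).

    Reduces to the scalar monotone equation ``a + c tanh(a + b) = w.z'``
    with ``c = w.u_hat >= -1 + eps``, solved by bracketed Brent iteration,
    then reconstructs ``z = z' - u_hat tanh(a + b)``. Requires a
    constrained step (monotonicity fails otherwise).
    """
    u_hat = _data(step.u)
    w = _data(step.w)
    b = float(_data(step.b))
    if float(w @ u_hat) < -1.0 - 1e-9:
        raise ValueError("planar_inverse needs a constrained step (w.u >= -1)")
    zp = np.asarray(z_prime, dtype=np.float64)
    single = zp.ndim == 1
    zp2 = zp[None, :] if single else zp.reshape(-1, zp.shape[-1])

    c = float(w @ u_hat)
    t = zp2 @ w
    margin = abs(c) + 1.0
    a_sol = np.empty_like(t)
    for i, ti in enumerate(t):
        f = lambda a: a + c * np.tanh(a + b) - ti
        a_sol[i] = brentq(f, ti - margin, ti + margin, xtol=tol, maxiter=max_iter)
    z = zp2 - np.tanh(a_sol + b)[:, None] * u_hat[None, :]
    return z[0] if single else z.reshape(zp.shape)


def chain_forward(z0, chain: FlowChain) -> Tuple[Any, Any]:
    """Push ``z0`` through every step; total logdet is the sum of per-step logdets."""
    z = z0
    total = None
    for step in chain.steps:
        z, ld = planar_forward(z, step)
        total = ld if total is None else total + ld
    if total is None:
        zshape = _data(z0).shape[:-1]
        total = np.zeros(zshape) if zshape else 0.0
    return z, total


def chain_inverse(zK: np.ndarray, chain: FlowChain) -> np.ndarray:
    z = np.asarray(zK, dtype=np.float64)
    for step in reversed(chain.steps):
        z = planar_inverse(z, step)
    return z


def gaussian_log_density(z, mu, sigma):
    """Diagonal-Gaussian log pdf, summed over the trailing feature axis."""
    d = (z - mu) / sigma
    return -0.5 * ad.asum(d * d + 2.0 * ad.log(sigma) + LOG_2PI, axis=-1)


def flowed_log_density(zK: np.ndarray, fd: FlowedDensity) -> np.ndarray:
    """Exact log-density of flowed points: invert the chain, correct by logdet."""
    z0 = chain_inverse(zK, fd.chain)
    _, total_logdet = chain_forward(z0, fd.chain)
    return gaussian_log_density(z0, _data(fd.mu), _data(fd.sigma)) - total_logdet


def sample_flowed(fd: FlowedDensity, n: int, rng: np.random.Generator) -> np.ndarray:
    mu, sigma = _data(fd.mu), _data(fd.sigma)
    z0 = mu + sigma * rng.standard_normal((n, mu.shape[-1]))
    zK, _ = chain_forward(z0, fd.chain)
    return zK


def kl_between_flowed(fd1: FlowedDensity, fd2: FlowedDensity, n_samples: int = 1,
                      seed: Optional[int] = 0):
    """Monte-Carlo KL(q1 || q2) between two flow-transformed densities.

    Samples the shared base variable ``z0`` from fd1's base and evaluates

        E[ log p1(z0) - log p2(z0) + logdet_2(z0) - logdet_1(z0) ]

    i.e. the base log-ratio corrected by both chains' log-det Jacobians at
    the same base point. The estimate is zero pointwise when fd1 and fd2
    coincide, and deterministic given the seed. When both chains are empty
    the diagonal-Gaussian KL is returned in closed form instead (exact, no
    sampling) — this keeps a zero-depth flow model's objective identical
    to the flow-free model's.

    Differentiable in the parameters of both densities (reparameterized
    base sample).
    """
    mu1, s1 = fd1.mu, fd1.sigma
    mu2, s2 = fd2.mu, fd2.sigma
    d1, d2 = _data(mu1).shape[-1], _data(mu2).shape[-1]
    if d1 != d2:
        raise ValueError(f"dimension mismatch: {d1} vs {d2}")
    if len(fd1.chain) == 0 and len(fd2.chain) == 0:
        r = s1 / s2
        dm = (mu1 - mu2) / s2
        kl = 0.5 * ad.asum(r * r + dm * dm - 1.0) - ad.asum(ad.log(r))
        return kl
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_samples, d1))
    z0 = mu1 + s1 * eps  # reparameterized; broadcasts over samples
    logp1 = gaussian_log_density(z0, mu1, s1)
    logp2 = gaussian_log_density(z0, mu2, s2)
    _, ld1 = chain_forward(z0, fd1.chain)
    _, ld2 = chain_forward(z0, fd2.chain)
    return ad.amean(logp1 - logp2 + ld2 - ld1)


def random_step(dim: int, rng: np.random.Generator, scale: float = 1.0,
                constrained: bool = True) -> FlowStep:
    """A random planar step, constrained (invertible) by default."""
    step = FlowStep(
        u=rng.normal(scale=scale, size=dim),
        w=rng.normal(scale=scale, size=dim),
        b=float(rng.normal(scale=scale)),
    )
    return constrain_step(step) if constrained else step


def random_chain(dim: int, depth: int, rng: np.random.Generator, scale: float = 1.0) -> FlowChain:
    return FlowChain(steps=[random_step(dim, rng, scale) for _ in range(depth)], dim=dim)
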