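"""Curvature-parametrized Poincare-ball geometry.

Two layers of API live here:

* private array-level kernels (``_mobius_add`` ...) written against an
  ``xp`` namespace so the same formulas run on raw numpy arrays *and* on
  :mod:`hyperseg.tensor` autodiff graphs (the network imports these);
* a typed, validated surface (:class:`BallPoint`, :func:`mobius_add`, ...)
  used by the oracle test-suite and by optimizer code.

The ball of curvature ``k > 0`` is ``{p : k * ||p||^2 < 1}`` with conformal
factor ``lambda_p = 2 / (1 - k * ||p||^2)``.  All norms carry a tiny floor
before division and arctanh arguments are clamped to ``1 - 1e-7``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, DomainError, InvalidParameterError

NORM_FLOOR = 1e-12
ATANH_CLAMP = 1.0 - 1e-7
_DEN_FLOOR = 1e-12

__all__ = [
    "ManifoldParams", "BallPoint", "TangentVector", "ClassPlane",
    "curvature_value", "conformal_factor", "mobius_add", "mobius_scalar_mul",
    "exp_map", "log_map", "project_to_ball", "dist_to_plane",
    "riemannian_sgd_step",
]


# ---------------------------------------------------------------------------
# array-level kernels (generic over xp = numpy | hyperseg.tensor)
# ---------------------------------------------------------------------------

def _sqnorm(x, axis, xp):
    return xp.sum(x * x, axis=axis, keepdims=True)


def _norm(x, axis, xp):
    # 1e-30 inside the sqrt keeps gradients finite at exactly zero vectors
    return xp.maximum(xp.sqrt(_sqnorm(x, axis, xp) + 1e-30), NORM_FLOOR)


def _mobius_add(x, y, k, axis, xp):
    x2 = _sqnorm(x, axis, xp)
    y2 = _sqnorm(y, axis, xp)
    xy = xp.sum(x * y, axis=axis, keepdims=True)
    num = (1.0 + 2.0 * k * xy + k * y2) * x + (1.0 - k * x2) * y
    den = 1.0 + 2.0 * k * xy + (k * k) * x2 * y2
    return num / xp.maximum(den, _DEN_FLOOR)


def _mobius_scalar_mul(s, x, k, axis, xp):
    n = _norm(x, axis, xp)
    sk = xp.sqrt(k) if not np.isscalar(k) else float(np.sqrt(k))
    arg = xp.minimum(sk * n, ATANH_CLAMP)
    return xp.tanh(s * xp.arctanh(arg)) * x / (sk * n)


def _conformal(p, k, axis, xp):
    return 2.0 / (1.0 - k * _sqnorm(p, axis, xp))


def _exp_map(p, v, k, axis, xp):
    sk = xp.sqrt(k) if not np.isscalar(k) else float(np.sqrt(k))
    vn = _norm(v, axis, xp)
    lam = _conformal(p, k, axis, xp)
    second = xp.tanh(sk * lam * vn / 2.0) * v / (sk * vn)
    return _mobius_add(p, second, k, axis, xp)


def _log_map(p, q, k, axis, xp):
    sk = xp.sqrt(k) if not np.isscalar(k) else float(np.sqrt(k))
    w = _mobius_add(-p, q, k, axis, xp)
    wn = _norm(w, axis, xp)
    lam = _conformal(p, k, axis, xp)
    return (2.0 / (sk * lam)) * xp.arctanh(xp.minimum(sk * wn, ATANH_CLAMP)) * w / wn


def _dist_to_plane(z, p, a, k, axis, xp):
    sk = xp.sqrt(k) if not np.isscalar(k) else float(np.sqrt(k))
    w = _mobius_add(-p, z, k, axis, xp)
    an = _norm(a, axis, xp)
    num = 2.0 * sk * xp.sum(w * a, axis=axis, keepdims=True)
    den = (1.0 - k * _sqnorm(w, axis, xp)) * an
    return xp.arcsinh(num / xp.maximum(den, _DEN_FLOOR)) / sk


def _project(x, k, eps, axis, xp):
    sk = xp.sqrt(k) if not np.isscalar(k) else float(np.sqrt(k))
    n = _norm(x, axis, xp)
    max_norm = (1.0 - eps) / sk
    return x * xp.minimum(max_norm / n, 1.0)


# ---------------------------------------------------------------------------
# typed surface
# ---------------------------------------------------------------------------

@dataclass
class ManifoldParams:
    """Learnable-curvature state: k = exp(l_k * sigma) + l_0."""

    sigma: float = 0.0
    l_k: float = 1.0
    l_0: float = 1e-3
    eps_ball: float = 1e-5

    def __post_init__(self):
        if not np.isfinite(self.sigma):
            raise InvalidParameterError(f"sigma must be finite, got {self.sigma}")
        if self.l_0 <= 0:
            raise InvalidParameterError(f"l_0 must be > 0, got {self.l_0}")
        if not (0.0 < self.eps_ball <= 0.01):
            raise InvalidParameterError(f"eps_ball must lie in (0, 0.01], got {self.eps_ball}")

    @property
    def curvature(self) -> float:
        return curvature_value(self)


def curvature_value(m: ManifoldParams) -> float:
    """Derived curvature ``k = exp(l_k * sigma) + l_0`` (> l_0 for finite sigma)."""
    if not np.isfinite(m.sigma):
        raise InvalidParameterError(f"sigma must be finite, got {m.sigma}")
    k = float(np.exp(m.l_k * m.sigma) + m.l_0)
    # l_0 is a *strict* floor; guard against float absorption of tiny exp terms
    if k <= m.l_0:
        k = float(np.nextafter(m.l_0, np.inf))
    return k


@dataclass
class BallPoint:
    """A vector strictly inside the ball of its curvature."""

    coords: np.ndarray
    curvature: float

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.all(np.isfinite(self.coords)):
            raise DomainError("ball point has non-finite coordinates")
        if self.curvature * float(self.coords @ self.coords) >= 1.0:
            raise DomainError(
                f"point with k*||p||^2 = {self.curvature * float(self.coords @ self.coords):.6g} "
                "is not inside the open ball")


@dataclass
class TangentVector:
    coords: np.ndarray
    base: BallPoint

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.all(np.isfinite(self.coords)):
            raise InvalidParameterError("tangent vector has non-finite coordinates")


@dataclass
class ClassPlane:
    """HMLR class parameters: offset point p_y, normal a_y, logit scale zeta."""

    offset: BallPoint
    normal: np.ndarray
    zeta: float = 1.0

    def __post_init__(self):
        self.normal = np.asarray(self.normal, dtype=np.float64)
        if float(np.linalg.norm(self.normal)) <= 0.0:
            raise InvalidParameterError("plane normal must be nonzero")
        if self.zeta <= 0:
            raise InvalidParameterError("zeta must be positive")


def _check_in_ball(q: BallPoint, k: float) -> None:
    if k * float(q.coords @ q.coords) >= 1.0:
        raise DomainError("point lies outside the open ball for this curvature")


def conformal_factor(p: BallPoint, k: float) -> float:
    """lambda_p = 2 / (1 - k * ||p||^2); >= 2 inside the ball."""
    s = k * float(p.coords @ p.coords)
    if s >= 1.0:
        raise DomainError(f"k*||p||^2 = {s:.6g} >= 1: outside the ball")
    return 2.0 / (1.0 - s)


def project_to_ball(x: np.ndarray, k: float, eps: float = 1e-5) -> BallPoint:
    """Rescale x onto norm (1-eps)/sqrt(k) if it falls outside that radius."""
    x = np.asarray(x, dtype=np.float64)
    n = float(np.linalg.norm(x))
    max_norm = (1.0 - eps) / np.sqrt(k)
    if n > max_norm:
        x = x * (max_norm / max(n, NORM_FLOOR))
    return BallPoint(x, k)


def mobius_add(q1: BallPoint, q2: BallPoint, k: float, eps: float = 1e-5) -> BallPoint:
    _check_in_ball(q1, k)
    _check_in_ball(q2, k)
    x, y = q1.coords, q2.coords
    x2, y2, xy = float(x @ x), float(y @ y), float(x @ y)
    den = 1.0 + 2.0 * k * xy + k * k * x2 * y2
    if den < _DEN_FLOOR:
        raise DegenerateInputError(f"Mobius denominator {den:.3g} below {_DEN_FLOOR}")
    num = (1.0 + 2.0 * k * xy + k * y2) * x + (1.0 - k * x2) * y
    return project_to_ball(num / den, k, eps)


def mobius_scalar_mul(s: float, q: BallPoint, k: float, eps: float = 1e-5) -> BallPoint:
    _check_in_ball(q, k)
    n = float(np.linalg.norm(q.coords))
    if n < NORM_FLOOR:
        return BallPoint(np.zeros_like(q.coords), k)
    sk = np.sqrt(k)
    out = np.tanh(s * np.arctanh(min(sk * n, ATANH_CLAMP))) * q.coords / (sk * n)
    return project_to_ball(out, k, eps)


def exp_map(P: BallPoint, v: TangentVector, k: float, eps: float = 1e-5) -> BallPoint:
    _check_in_ball(P, k)
    vec = v.coords if isinstance(v, TangentVector) else np.asarray(v, dtype=np.float64)
    vn = float(np.linalg.norm(vec))
    if vn < NORM_FLOOR:
        return BallPoint(P.coords.copy(), k)
    sk = np.sqrt(k)
    lam = conformal_factor(P, k)
    second = BallPoint(np.tanh(sk * lam * vn / 2.0) * vec / (sk * vn) * (1 - 1e-15), k)
    return mobius_add(P, second, k, eps)


def log_map(P: BallPoint, q: BallPoint, k: float) -> TangentVector:
    _check_in_ball(P, k)
    _check_in_ball(q, k)
    negP = BallPoint(-P.coords, k)
    w = mobius_add(negP, q, k).coords
    wn = float(np.linalg.norm(w))
    if wn < NORM_FLOOR:
        return TangentVector(np.zeros_like(P.coords), P)
    sk = np.sqrt(k)
    lam = conformal_factor(P, k)
    out = (2.0 / (sk * lam)) * np.arctanh(min(sk * wn, ATANH_CLAMP)) * w / wn
    return TangentVector(out, P)


def dist_to_plane(z: BallPoint, plane: ClassPlane, k: float) -> float:
    """Signed hyperbolic distance from z to the class plane (positive on the
    normal's side); take ``abs`` where a metric distance is needed."""
    _check_in_ball(z, k)
    a = plane.normal
    an = float(np.linalg.norm(a))
    if an <= 0:
        raise InvalidParameterError("plane normal must be nonzero")
    negP = BallPoint(-plane.offset.coords, k)
    w = mobius_add(negP, z, k).coords
    sk = np.sqrt(k)
    num = 2.0 * sk * float(w @ a)
    den = (1.0 - k * float(w @ w)) * an
    return float(np.arcsinh(num / max(den, _DEN_FLOOR)) / sk)


def riemannian_sgd_step(param: BallPoint, euclidean_grad: np.ndarray,
                        lr: float, k: float, eps: float = 1e-5) -> BallPoint:
    """One Riemannian SGD step.

    The Euclidean gradient is rescaled by ``4 / lambda_p^2``, i.e.
    ``r = grad * (1 - k*||p||^2)^2``, then retracted with the exponential map
    and projected back into the ball.  This normalization makes the k -> 0
    limit of the update exactly ``p - lr * grad`` (plain gradient descent).
    """
    _check_in_ball(param, k)
    g = np.asarray(euclidean_grad, dtype=np.float64)
    scale = (1.0 - k * float(param.coords @ param.coords)) ** 2
    r = g * scale
    stepped = exp_map(param, TangentVector(-lr * r, param), k, eps)
    return project_to_ball(stepped.coords, k, eps)
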