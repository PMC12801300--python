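"""Analytical real-root solvers for cubics and quartics, and the ray-torus intersection.

The ray-torus intersection problem reduces to finding the real roots of a monic
quartic.  Iterative root finders (Sturm bracketing, generic polynomial solvers)
are both slower and, at loose tolerances, a source of missed grazing
intersections; the solvers here follow Cardano's procedure for the resolvent
cubic and Ferrari's factorization of the quartic into two quadratics, arranged
so that no complex arithmetic is performed and no division by a vanishing
coefficient can occur.  A short guarded Newton polish is applied to each root,
which costs a few flops and brings residuals down to rounding level.

All thresholds that the classical derivations leave open are named constants
below and documented where they are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Quartic",
    "Torus",
    "solve_cubic_largest_positive",
    "solve_quadratic",
    "solve_quartic",
    "ray_torus_intersect",
    "ray_torus_quartic",
]

# The 4e(x - d) change of unknown is tried only when the direct factorization
# leaves residuals above this relative level (a symptom of double-precision
# cancellation) and the constant term is meaningfully nonzero; whichever
# solution verifies better is kept.
_RESIDUAL_LIMIT = 1.0e-9
_RESCALE_MIN_E = 1.0e-300

# "m close to zero" branch of Ferrari's method: below this the resolvent root
# carries no usable information and the depressed quartic is treated as
# biquadratic.  Relative to the quadratic coefficient of the resolvent.
_M_ZERO_REL = 1.0e-12

# Negative quadratic discriminants no larger than this (relative to the
# coefficient scale) are clamped to zero, returning a double root: the grazing
# (tangential) case.  Downstream 2-point skipping removes such pairs.
_GRAZE_CLAMP_REL = 1.0e-10


def _check_finite(*vals: float) -> None:
    for v in vals:
        if not math.isfinite(v):
            raise ValueError(f"non-finite polynomial coefficient: {v!r}")


@dataclass(frozen=True)
class Quartic:
    """Monic quartic x^4 + b x^3 + c x^2 + d x + e."""

    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        _check_finite(self.b, self.c, self.d, self.e)

    @property
    def discriminant(self) -> float:
        b, c, d, e = self.b, self.c, self.d, self.e
        return (
            256.0 * e**3
            - 192.0 * b * d * e**2
            - 128.0 * c**2 * e**2
            + 144.0 * c * d**2 * e
            - 27.0 * d**4
            + 144.0 * b**2 * c * e**2
            - 6.0 * b**2 * d**2 * e
            - 80.0 * b * c**2 * d * e
            + 18.0 * b * c * d**3
            + 16.0 * c**4 * e
            - 4.0 * c**3 * d**2
            - 27.0 * b**4 * e**2
            + 18.0 * b**3 * c * d * e
            - 4.0 * b**3 * d**3
            - 4.0 * b**2 * c**3 * e
            + b**2 * c**2 * d**2
        )

    def __call__(self, x: float) -> float:
        return (((x + self.b) * x + self.c) * x + self.d) * x + self.e

    def deriv(self, x: float) -> float:
        return ((4.0 * x + 3.0 * self.b) * x + 2.0 * self.c) * x + self.d


@dataclass(frozen=True)
class Torus:
    """Circular torus: ring of radius ``ring_radius`` about ``axis``, tube radius
    ``tube_radius``.  Spindle tori (ring < tube) are legal; they arise in the
    SES when the probe circle is tight."""

    center: np.ndarray
    axis: np.ndarray
    ring_radius: float
    tube_radius: float
    frame: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        a = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(a)
        if not np.isfinite(n) or n == 0.0:
            raise ValueError("torus axis must be a nonzero vector")
        a = a / n
        if self.tube_radius <= 0.0 or self.ring_radius <= 0.0:
            raise ValueError("torus radii must be positive")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "axis", a)
        if self.frame is None:
            object.__setattr__(self, "frame", _axis_frame(a))

    def implicit(self, p: np.ndarray) -> float:
        """Implicit function F(p); zero on the torus surface."""
        q = np.asarray(p, dtype=float) - self.center
        z = float(q @ self.axis)
        rho2 = float(q @ q) - z * z
        s = float(q @ q) + self.ring_radius**2 - self.tube_radius**2
        return s * s - 4.0 * self.ring_radius**2 * rho2

    def implicit_gradient(self, p: np.ndarray) -> np.ndarray:
        q = np.asarray(p, dtype=float) - self.center
        z = float(q @ self.axis)
        s = float(q @ q) + self.ring_radius**2 - self.tube_radius**2
        return 4.0 * s * q - 8.0 * self.ring_radius**2 * (q - z * self.axis)


def _axis_frame(axis: np.ndarray) -> np.ndarray:
    """Deterministic right-handed orthonormal frame (u, v, axis).

    The in-plane direction u is seeded from the coordinate axis least aligned
    with ``axis`` so that the frame depends only on the axis itself - required
    for bitwise reproducibility across slab decompositions.
    """
    k = int(np.argmin(np.abs(axis)))
    seed = np.zeros(3)
    seed[k] = 1.0
    u = seed - axis * float(seed @ axis)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return np.stack([u, v, axis])


def solve_quadratic(b: float, c: float) -> list[float]:
    """Real roots of x^2 + b x + c, ascending; numerically stable form."""
    _check_finite(b, c)
    disc = b * b - 4.0 * c
    if disc < 0.0:
        if disc >= -_GRAZE_CLAMP_REL * max(1.0, b * b, abs(c)):
            x = -0.5 * b
            return [x, x]
        return []
    s = math.sqrt(disc)
    # Avoid cancellation: compute the large-magnitude root first.
    if b >= 0.0:
        q = -0.5 * (b + s)
    else:
        q = -0.5 * (b - s)
    if q == 0.0:
        return [0.0, 0.0]
    r1, r2 = q, c / q
    return [r1, r2] if r1 <= r2 else [r2, r1]


def _cubic_real_roots(p2: float, p1: float, p0: float) -> list[float]:
    """All real roots of the monic cubic x^3 + p2 x^2 + p1 x + p0.

    Cardano's procedure on the depressed cubic; the single-real-root branch
    uses the hyperbolic forms, which need neither complex arithmetic nor a
    division by a possibly tiny leading quantity.
    """
    _check_finite(p2, p1, p0)
    shift = p2 / 3.0
    p = p1 - p2 * shift
    q = p0 + shift * (2.0 * shift * shift - p1)
    roots: list[float]
    if p == 0.0 and q == 0.0:
        roots = [0.0, 0.0, 0.0]
    elif abs(p) < 1e-300:
        roots = [math.copysign(abs(q) ** (1.0 / 3.0), -q)]
    else:
        disc = -4.0 * p * p * p - 27.0 * q * q
        t = 2.0 * math.sqrt(abs(p) / 3.0)
        if p < 0.0:
            arg = 3.0 * q / (p * t)  # = 3q / (2p) * sqrt(3/|p|), sign folded in
            if disc >= 0.0:
                # Three real roots: trigonometric branch (clamp guards rounding
                # when the discriminant sits on the multiple-root boundary).
                theta = math.acos(min(1.0, max(-1.0, arg)))
                roots = [t * math.cos((theta - 2.0 * math.pi * k) / 3.0) for k in range(3)]
            else:
                a = max(abs(arg), 1.0)
                roots = [-math.copysign(t, q) * math.cosh(math.acosh(a) / 3.0)]
        else:
            arg = 3.0 * q / (p * t)
            roots = [-t * math.sinh(math.asinh(arg) / 3.0)]
    out = []
    for y in roots:
        x = y - shift
        # One Newton step tightens the trigonometric/hyperbolic evaluations.
        f = ((x + p2) * x + p1) * x + p0
        fp = (3.0 * x + 2.0 * p2) * x + p1
        if fp != 0.0 and math.isfinite(f / fp):
            x -= f / fp
        out.append(x)
    return sorted(out)


def solve_cubic_largest_positive(p2: float, p1: float, p0: float) -> float | None:
    """Largest strictly positive real root of x^3 + p2 x^2 + p1 x + p0.

    Returns ``None`` when no positive real root exists.  This is the resolvent
    step of Ferrari's method, where only the largest positive solution m is
    needed to factor the quartic.
    """
    pos = [r for r in _cubic_real_roots(p2, p1, p0) if r > 0.0]
    return max(pos) if pos else None


def _solve_depressed(p: float, q: float, r: float) -> list[float]:
    """Real roots of y^4 + p y^2 + q y + r via Ferrari factorization."""
    if q == 0.0:
        return _biquadratic(p, r)
    # Resolvent cubic m^3 + p m^2 + (p^2/4 - r) m - q^2/8 = 0.  Its value at
    # m = 0 is -q^2/8 < 0, so a positive real root always exists for q != 0.
    m = solve_cubic_largest_positive(p, 0.25 * p * p - r, -0.125 * q * q)
    if m is None or m <= _M_ZERO_REL * max(1.0, abs(p)):
        return _biquadratic(p, r)
    s = math.sqrt(2.0 * m)
    half = 0.5 * p + m
    shift = q / (2.0 * s)
    roots = solve_quadratic(-s, half + shift) + solve_quadratic(s, half - shift)
    return sorted(roots)


def _biquadratic(p: float, r: float) -> list[float]:
    roots: list[float] = []
    for z in solve_quadratic(p, r):
        if z < 0.0:
            if z >= -_GRAZE_CLAMP_REL * max(1.0, abs(p), abs(r)):
                z = 0.0
            else:
                continue
        s = math.sqrt(z)
        roots.extend([-s, s])
    return sorted(roots)


def _polish(q: Quartic, x: float, iters: int = 2) -> float:
    for _ in range(iters):
        f = q(x)
        if f == 0.0:
            break
        fp = q.deriv(x)
        if fp == 0.0:
            break
        step = f / fp
        if not math.isfinite(step):
            break
        # Guarded step: near multiple roots (or with denormal coefficients)
        # Newton can overshoot; accept only residual-reducing moves.
        lim = 1.0 + abs(x)
        if abs(step) > lim:
            step = math.copysign(lim, step)
        cand = x - step
        if abs(q(cand)) >= abs(f):
            break
        x = cand
    return x


def _solve_direct(q: Quartic) -> list[float]:
    b = q.b
    b2 = b * b
    p = q.c - 0.375 * b2
    qq = q.d - 0.5 * b * q.c + 0.125 * b2 * b
    r = q.e - 0.25 * b * q.d + 0.0625 * b2 * q.c - (3.0 / 256.0) * b2 * b2
    roots = [_polish(q, y - 0.25 * b) for y in _solve_depressed(p, qq, r)]
    roots.sort()
    return roots


def _max_rel_residual(q: Quartic, roots: list[float]) -> float:
    if not roots:
        return 0.0
    return max(abs(q(x)) / max(1.0, x * x * x * x) for x in roots)


def solve_quartic(q: Quartic, _allow_rescale: bool = True) -> list[float]:
    """All real roots of the monic quartic, ascending (0, 2 or 4 of them).

    The depressed quartic is factored into two quadratics via the largest
    positive resolvent-cubic root (Ferrari).  When cancellation leaves the
    direct solution with poor residuals and the constant term is nonzero, the
    equation is additionally solved in the rescaled unknown
    xhat = 4 e (x - d) and mapped back; the better-verifying root set wins.
    """
    roots = _solve_direct(q)
    if not _allow_rescale or abs(q.e) <= _RESCALE_MIN_E:
        return roots
    res = _max_rel_residual(q, roots)
    if roots and res <= _RESIDUAL_LIMIT:
        return roots
    alt = _solve_rescaled(q)
    alt_res = _max_rel_residual(q, alt)
    if not roots:
        # No real roots found directly; accept the rescaled set only if it
        # actually verifies - an empty answer is often the correct one.
        return alt if (alt and alt_res <= _RESIDUAL_LIMIT) else roots
    return alt if (alt and alt_res < res) else roots


def _solve_rescaled(q: Quartic) -> list[float]:
    s = 4.0 * q.e
    d0 = q.d
    # Taylor shift p(y + d0) by repeated synthetic division, then scale y = xhat / s.
    a = [1.0, q.b, q.c, q.d, q.e]
    for k in range(4):
        for j in range(1, 5 - k):
            a[j] = a[j] + d0 * a[j - 1]
    # a is now p(y + d0) coefficients, highest first.  Scale to xhat.
    bh = a[1] * s
    ch = a[2] * s * s
    dh = a[3] * s * s * s
    eh = a[4] * s * s * s * s
    if not all(map(math.isfinite, (bh, ch, dh, eh))):
        return []                          # rescaling overflowed
    inner = _solve_direct(Quartic(bh, ch, dh, eh))
    roots = sorted(_polish(q, x / s + d0) for x in inner)
    return roots


def ray_torus_intersect(origin: np.ndarray, direction: np.ndarray, torus: Torus) -> list[float]:
    """Sorted ray parameters t of the intersections of ``origin + t*direction``
    with the torus surface.  ``direction`` must be unit length.

    Substituting the ray into the implicit equation
    ``(|p|^2 + R^2 - r^2)^2 = 4 R^2 |p_perp|^2``  (p in the torus frame)
    yields a monic quartic in t, solved analytically.  Tangential grazings are
    reported as coincident double roots.
    """
    o = np.asarray(origin, dtype=float).reshape(3)
    dvec = np.asarray(direction, dtype=float).reshape(3)
    if abs(np.linalg.norm(dvec) - 1.0) > 1e-9:
        raise ValueError("ray direction must be a unit vector")
    oc = o - torus.center
    R2 = torus.ring_radius**2
    r2 = torus.tube_radius**2
    # Quick exact reject: the torus lies inside the sphere of radius R + r.
    # Distance from the ray line to the center exceeding that bound means the
    # quartic has no real roots.
    perp = oc - dvec * float(oc @ dvec)
    if float(perp @ perp) > (torus.ring_radius + torus.tube_radius) ** 2 + 1e-9:
        return []
    return solve_quartic(ray_torus_quartic(o, dvec, torus))


def ray_torus_quartic(origin: np.ndarray, direction: np.ndarray, torus: Torus) -> Quartic:
    """Monic quartic in the ray parameter whose real roots are the
    intersections of the (unit, axis-aligned or oblique) ray with the torus."""
    o = np.asarray(origin, dtype=float).reshape(3)
    dvec = np.asarray(direction, dtype=float).reshape(3)
    oc = o - torus.center
    R2 = torus.ring_radius**2
    r2 = torus.tube_radius**2
    beta = float(oc @ dvec)
    gamma = float(oc @ oc) + R2 - r2
    az = float(torus.axis @ dvec)
    oz = float(torus.axis @ oc)
    # |p_perp|^2 along the ray: a2 t^2 + a1 t + a0.
    a2 = 1.0 - az * az
    a1 = 2.0 * (float(oc @ dvec) - oz * az)
    a0 = float(oc @ oc) - oz * oz
    b = 4.0 * beta
    c = 4.0 * beta * beta + 2.0 * gamma - 4.0 * R2 * a2
    d = 4.0 * beta * gamma - 4.0 * R2 * a1
    e = gamma * gamma - 4.0 * R2 * a0
    return Quartic(b, c, d, e)
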