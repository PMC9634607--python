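"""Closed-form radial building blocks of the shell decomposition.

This module evaluates, without any Fourier transforms:

* the 3D interference function ``G`` — the inverse Fourier transform of the
  indicator of a reciprocal-space ball, normalized to ``G(0) = 1``;
* the isotropic 3D Gaussian ``g(r; B)`` in the crystallographic B-factor
  convention (its reciprocal transform is ``exp(-B s^2 / 4)``, ``s = 1/d``);
* the blurred-shell function ``Omega(r; mu, nu)`` — a unit-mass uniform
  spherical-surface distribution of radius ``mu`` convolved with
  ``g(.; nu)``;
* exact transformation rules for shell decompositions: disorder transfer
  (``nu -> nu + B``) and rescaling of a dimensionless decomposition of ``G``
  to the physical point-atom image at resolution ``D``.

All radial evaluations are vectorized elementwise over arrays of radii.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ShellTerm",
    "ShellDecomposition",
    "interference_G",
    "gaussian_g",
    "omega",
    "transfer_disorder",
    "rescale_to_resolution",
    "point_image",
]

# Switch to the Taylor branch of G below this value of u = 2*pi*x.
_G_SMALL_U = 1e-3
# Switch omega to the sinh-product branch below this value of t = 2*A*mu*r.
_OMEGA_SINH_BRANCH = 30.0


@dataclass(frozen=True)
class ShellTerm:
    """One term ``kappa * Omega(r; mu, nu)`` of a shell decomposition.

    ``mu`` is the shell radius (dimensionless for decompositions of G,
    angstrom for atomic images), ``nu`` the Gaussian blurring parameter on
    the B-factor scale of ``mu**2``, and ``kappa`` a signed weight —
    successive Fourier ripples alternate the sign of ``kappa``.
    """

    mu: float
    nu: float
    kappa: float

    def __post_init__(self) -> None:
        if not self.nu > 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")


@dataclass(frozen=True)
class ShellDecomposition:
    """An ordered set of shell terms approximating a radial function."""

    terms: tuple[ShellTerm, ...]
    domain_radius: float
    target_id: str = ""
    max_error: float = 0.0
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if not self.domain_radius > 0:
            raise ValueError("domain_radius must be > 0")
        if self.max_error < 0:
            raise ValueError("max_error must be >= 0")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (mu, nu, kappa) as float arrays, in term order."""
        mu = np.array([t.mu for t in self.terms], dtype=float)
        nu = np.array([t.nu for t in self.terms], dtype=float)
        kappa = np.array([t.kappa for t in self.terms], dtype=float)
        return mu, nu, kappa


def interference_G(x):
    """3D interference function ``G(x) = 3 (sin u - u cos u) / u**3``, u = 2*pi*x.

    ``G`` is the inverse Fourier transform of the indicator of the unit
    reciprocal ball, normalized so that ``G(0) = 1``.  A Taylor branch
    (``1 - u**2/10 + u**4/280 - u**6/15120``) is used for ``u < 1e-3`` to
    avoid the removable 0/0 at the origin.

    Parameters
    ----------
    x : array_like
        Dimensionless radius, ``x >= 0``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("interference_G requires x >= 0")
    u = 2.0 * np.pi * x
    out = np.empty_like(u)
    small = u < _G_SMALL_U
    us = u[small]
    u2 = us * us
    out[small] = 1.0 + u2 * (-1.0 / 10.0 + u2 * (1.0 / 280.0 - u2 / 15120.0))
    ub = u[~small]
    out[~small] = 3.0 * (np.sin(ub) - ub * np.cos(ub)) / ub**3
    return out if out.ndim else float(out)


def gaussian_g(r, B):
    """Normalized isotropic 3D Gaussian in the B-factor convention.

    ``g(r; B) = (4*pi/B)**1.5 * exp(-4*pi**2 r**2 / B)``; its 3D Fourier
    transform is ``exp(-B s**2 / 4)`` with ``s = 1/d``, and the total 3D
    integral is 1.  Convolution adds the parameters: g(B1) * g(B2) = g(B1+B2).
    """
    if not B > 0:
        raise ValueError(f"B must be > 0, got {B}")
    r = np.asarray(r, dtype=float)
    out = (4.0 * np.pi / B) ** 1.5 * np.exp(-4.0 * np.pi**2 * r * r / B)
    return out if out.ndim else float(out)


def omega(r, mu, nu):
    """Gaussian-blurred unit-mass spherical shell ``Omega(r; mu, nu)``.

    The uniform distribution on the sphere of radius ``mu`` convolved with
    ``gaussian_g(.; nu)``.  Closed form (A = 4*pi**2/nu):

        Omega(r) = (4*pi/nu)**1.5 * exp(-A (r**2 + mu**2)) * sinh(t)/t,
        t = 2*A*mu*r,

    evaluated as an explicit difference of exponentials when ``t`` is large
    (to avoid sinh overflow) and by the series of ``sinh(t)/t`` for small
    ``t`` (finite at r = 0 and for mu = 0, where it reduces to the Gaussian).
    Total 3D integral is 1 for every (mu, nu).
    """
    if not nu > 0:
        raise ValueError(f"nu must be > 0, got {nu}")
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("omega requires r >= 0")
    scalar = r.ndim == 0
    r = np.atleast_1d(r)

    A = 4.0 * np.pi**2 / nu
    t = 2.0 * A * mu * r
    out = np.empty_like(r)

    big = t > _OMEGA_SINH_BRANCH
    if np.any(big):
        rb = r[big]
        # C = sqrt(pi/nu)/(2*pi); Omega = C/(mu r) [e^{-A(r-mu)^2} - e^{-A(r+mu)^2}]
        C = math.sqrt(np.pi / nu) / (2.0 * np.pi)
        out[big] = (
            C / (mu * rb) * (np.exp(-A * (rb - mu) ** 2) - np.exp(-A * (rb + mu) ** 2))
        )
    if np.any(~big):
        rs = r[~big]
        ts = t[~big]
        tiny = ts < 1e-6
        shs = np.empty_like(ts)
        shs[tiny] = 1.0 + ts[tiny] ** 2 / 6.0
        shs[~tiny] = np.sinh(ts[~tiny]) / ts[~tiny]
        out[~big] = (4.0 * np.pi / nu) ** 1.5 * np.exp(-A * (rs * rs + mu * mu)) * shs

    return float(out[0]) if scalar else out


def transfer_disorder(dec: ShellDecomposition, B: float) -> ShellDecomposition:
    """Apply isotropic positional disorder ``B`` by shifting every ``nu``.

    Convolution with ``gaussian_g(.; B)`` maps each term
    ``Omega(.; mu, nu)`` exactly onto ``Omega(.; mu, nu + B)``; ``mu`` and
    ``kappa`` are unchanged.  Negative ``B`` (de-blurring) is rejected.
    """
    if B < 0:
        raise ValueError("disorder transfer requires B >= 0 (no de-blurring)")
    if B == 0:
        return dec
    terms = tuple(replace(t, nu=t.nu + B) for t in dec.terms)
    return replace(dec, terms=terms, target_id=f"{dec.target_id} + B={B:g}")


def rescale_to_resolution(dec: ShellDecomposition, D: float) -> ShellDecomposition:
    """Convert a dimensionless decomposition of G into the point-atom image.

    The image of an immobile point atom at resolution ``D`` is
    ``(4*pi/3) D**-3 G(r/D)``; since ``D**-3 Omega(r/D; mu, nu) =
    Omega(r; mu*D, nu*D**2)``, each term maps to
    ``(mu*D, nu*D**2, kappa * 4*pi/3)``.  Summing the rescaled terms with
    :func:`omega` reproduces :func:`point_image` to the fit's accuracy.
    """
    if not D > 0:
        raise ValueError(f"D must be > 0, got {D}")
    amp = 4.0 * np.pi / 3.0
    terms = tuple(
        ShellTerm(mu=t.mu * D, nu=t.nu * D * D, kappa=t.kappa * amp) for t in dec.terms
    )
    return replace(
        dec,
        terms=terms,
        domain_radius=dec.domain_radius * D,
        target_id=f"point image, D = {D:g} A (from {dec.target_id or 'G'})",
    )


def point_image(r, D):
    """Exact D-resolution image of an immobile point atom.

    ``delta^d(r; D) = (4*pi/3) * D**-3 * G(r/D)`` — the 3D inverse Fourier
    transform of the indicator of the reciprocal ball of radius ``1/D``.
    At the origin this equals the ball volume ``(4*pi/3) / D**3``.
    """
    if not D > 0:
        raise ValueError(f"D must be > 0, got {D}")
    r = np.asarray(r, dtype=float)
    out = (4.0 * np.pi / 3.0) / D**3 * interference_G(r / D)
    return out if np.ndim(out) else float(out)
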