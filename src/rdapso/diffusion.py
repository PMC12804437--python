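"""Closed-form quantities for isotropic two-dimensional diffusion.

A point release of many independent diffusers with coefficient ``D``
(m^2/day) yields, at time ``t`` (days), a radial presence density

    P_t(r) = r / (2 D t) * exp(-r^2 / (4 D t)),

i.e. the radial marginal of a centered bivariate Gaussian with variance
``2 D t`` per axis.  Everything the continuum estimators need follows in
closed form: annulus occupancy probabilities, the mean distance traveled
(MDT) ``sqrt(pi D t)`` and the mean square distance ``4 D t``.

Distances are meters and times are days throughout.  Infinite outer radii
are valid and evaluated exactly (``exp(-inf) = 0``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["presence_pdf", "annulus_prob", "mean_distance", "mean_square_distance"]


def _check_Dt(D: float, t) -> None:
    if D <= 0:
        raise ValueError("diffusion coefficient D must be positive")
    if np.any(np.asarray(t) <= 0):
        raise ValueError("time t must be positive")


def presence_pdf(r, D: float, t: float):
    """Radial presence density ``P_t(r)`` in 1/m; vectorized over ``r``."""
    _check_Dt(D, t)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius r must be non-negative")
    out = r / (2.0 * D * t) * np.exp(-(r**2) / (4.0 * D * t))
    return out if out.ndim else float(out)


def annulus_prob(r_a, r_b, D: float, t) -> float:
    """Probability ``Q_t(r_a, r_b)`` of presence in the annulus ``(r_a, r_b]``.

    ``r_b = np.inf`` is allowed and gives the exact tail probability.
    """
    _check_Dt(D, t)
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    if np.any(r_a < 0):
        raise ValueError("inner radius must be non-negative")
    if np.any(r_a >= r_b):
        raise ValueError("need r_a < r_b")
    t = np.asarray(t, dtype=float)
    out = np.exp(-(r_a**2) / (4.0 * D * t)) - np.exp(-(r_b**2) / (4.0 * D * t))
    return out if out.ndim else float(out)


def mean_distance(D: float, t: float) -> float:
    """Mean distance traveled after ``t`` days: ``<r>_t = sqrt(pi D t)`` (m)."""
    if D < 0 or t < 0:
        raise ValueError("D and t must be non-negative")
    return float(np.sqrt(np.pi * D * t))


def mean_square_distance(D: float, t: float) -> float:
    """Mean square distance after ``t`` days: ``<r^2>_t = 4 D t`` (m^2)."""
    if D < 0 or t < 0:
        raise ValueError("D and t must be non-negative")
    return 4.0 * D * t
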