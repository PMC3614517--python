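"""Restricted cubic splines in log time.

The spline basis used throughout the package is the truncated-power
restricted cubic spline: piecewise cubic in ``ln(t)``, continuous through
the second derivative at every knot and constrained to be *linear* beyond
the boundary knots.  With knots :math:`n_1 < \\dots < n_N` the derived
variables are

.. math::

    z_1 &= \\ln t \\\\
    z_j &= (\\ln t - n_j)_+^3 - \\phi_j (\\ln t - n_1)_+^3
           - (1 - \\phi_j)(\\ln t - n_N)_+^3, \\qquad j = 2, \\dots, N-1

with :math:`\\phi_j = (n_N - n_j)/(n_N - n_1)` and
:math:`(u)_+ = \\max(u, 0)`.  A basis with ``N`` knots therefore spends
``N - 1`` degrees of freedom (plus an intercept when one is included in
the model).  Derivatives with respect to ``ln(t)`` are computed
analytically from the :math:`3 u_+^2` terms, never by differencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KnotVector", "SplineBasis", "place_knots", "basis", "basis_deriv"]


@dataclass(frozen=True)
class KnotVector:
    """Ordered knots on the log-time scale for one spline term.

    Parameters
    ----------
    knots : array-like of float
        Strictly increasing knot locations in ``ln(t)``.  The first and
        last entries are the boundary knots.
    """

    knots: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.knots, dtype=float)
        if k.ndim != 1 or k.size < 2:
            raise ValueError("need at least 2 knots (boundary knots)")
        if not np.all(np.diff(k) > 0):
            raise ValueError(f"knots must be strictly increasing, got {k!r}")
        object.__setattr__(self, "knots", k)

    @property
    def n_knots(self) -> int:
        return self.knots.size

    @property
    def n_internal(self) -> int:
        return self.knots.size - 2

    @property
    def n_basis(self) -> int:
        """Number of derived variables z_1..z_{N-1} (excluding intercept)."""
        return self.knots.size - 1

    def to_list(self) -> list[float]:
        return [float(x) for x in self.knots]

    @classmethod
    def from_list(cls, values) -> "KnotVector":
        return cls(np.asarray(values, dtype=float))


@dataclass
class SplineBasis:
    """Spline design columns and their analytic d/d ln(t) derivatives.

    ``values`` has one column per derived variable z_j (column 0 is
    exactly ``ln t``); ``derivs`` holds dz_j/d ln(t), same shape.
    """

    values: np.ndarray
    derivs: np.ndarray
    knots: KnotVector = field(repr=False, default=None)


def place_knots(
    event_times: np.ndarray,
    df: int,
    *,
    scale: str = "log",
) -> KnotVector:
    """Place knots at centiles of the (uncensored) event times.

    Boundary knots go at the log of the smallest and largest distinct
    event times; the ``df - 1`` internal knots at equally spaced centiles
    (``df=4`` gives the 25th/50th/75th centiles).  ``df=1`` gives boundary
    knots only, i.e. a Weibull-shaped (linear in log time) baseline.

    Parameters
    ----------
    event_times : array-like of positive float
        Uncensored event times, natural scale.
    df : int
        Degrees of freedom of the spline; the basis has ``df`` columns
        and ``df + 1`` knots.
    scale : {"log", "natural"}
        Whether centiles are computed on log event times (default) or on
        the natural scale before taking logs.  The two differ only when
        the empirical quantile falls between order statistics.

    Returns
    -------
    KnotVector

    Raises
    ------
    ValueError
        If fewer than two distinct event times are supplied, or centile
        ties produce duplicate knots (df too large for the data).
    """
    t = np.asarray(event_times, dtype=float)
    if t.size == 0:
        raise ValueError("event_times is empty")
    if np.any(t <= 0):
        raise ValueError("event times must be positive")
    df = int(df)
    if df < 1:
        raise ValueError("df must be >= 1")
    distinct = np.unique(t)
    if distinct.size < 2:
        raise ValueError("need at least 2 distinct event times for boundary knots")
    lo, hi = np.log(distinct[0]), np.log(distinct[-1])
    if df == 1:
        return KnotVector(np.array([lo, hi]))
    probs = np.arange(1, df) / df
    if scale == "log":
        internal = np.quantile(np.log(t), probs)
    elif scale == "natural":
        internal = np.log(np.quantile(t, probs))
    else:
        raise ValueError(f"scale must be 'log' or 'natural', got {scale!r}")
    knots = np.concatenate([[lo], internal, [hi]])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            f"duplicate knots from tied centiles (df={df} too large for "
            f"{distinct.size} distinct event times): {knots!r}"
        )
    return KnotVector(knots)


def basis(log_t: np.ndarray, knots: KnotVector) -> SplineBasis:
    """Evaluate the restricted cubic spline derived variables.

    Returns both the values z_1..z_{N-1} and their analytic derivatives
    with respect to ``ln(t)``.  With two knots the single column is
    ``ln(t)`` itself (the Weibull special case, ``ln H = ln lambda +
    gamma ln t``).
    """
    x = np.atleast_1d(np.asarray(log_t, dtype=float))
    kn = knots.knots
    N = kn.size
    vals = np.empty((x.size, N - 1))
    ders = np.empty((x.size, N - 1))
    vals[:, 0] = x
    ders[:, 0] = 1.0
    if N > 2:
        n1, nN = kn[0], kn[-1]
        u1 = np.maximum(x - n1, 0.0)
        uN = np.maximum(x - nN, 0.0)
        for j in range(1, N - 1):
            nj = kn[j]
            phi = (nN - nj) / (nN - n1)
            uj = np.maximum(x - nj, 0.0)
            vals[:, j] = uj**3 - phi * u1**3 - (1.0 - phi) * uN**3
            ders[:, j] = 3.0 * (uj**2 - phi * u1**2 - (1.0 - phi) * uN**2)
    return SplineBasis(values=vals, derivs=ders, knots=knots)


def basis_deriv(log_t: np.ndarray, knots: KnotVector) -> np.ndarray:
    """Analytic dz/d ln(t) only (convenience wrapper over :func:`basis`)."""
    return basis(log_t, knots).derivs
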