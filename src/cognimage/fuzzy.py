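"""Piecewise-linear fuzzy membership functions.

A fuzzy function maps a scalar feature value (in native feature units,
typically mm, mm**3 or cm**2) to a confidence in [0, 1].  It is defined by an
ordered list of (feature_value, confidence) vertices; evaluation interpolates
linearly between vertices and extrapolates flat beyond the first and last
vertex.  These functions encode soft prior expectations for object features,
e.g. "an abdominal cross-section of 100 cm**2 or less has confidence 0, rising
linearly to full confidence at 500 cm**2 or more".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FuzzyFunction"]

#: Relative shoulder width used when a fuzzy set is built from a printed
#: plausibility range [a, b]: full confidence on [a, b] with linear shoulders
#: of width ``SHOULDER_FRACTION * (b - a)`` on each side.
SHOULDER_FRACTION = 0.2


@dataclass(frozen=True)
class FuzzyFunction:
    """Piecewise-linear membership over a scalar feature.

    Parameters
    ----------
    vertices
        Ordered ``(feature_value, confidence)`` pairs.  Feature values must be
        strictly increasing and confidences must lie in [0, 1].  A single
        vertex yields a constant function.
    """

    vertices: tuple[tuple[float, float], ...]
    _xs: np.ndarray = field(init=False, repr=False, compare=False)
    _ys: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(c)) for x, c in self.vertices)
        if len(verts) < 1:
            raise ValueError("a fuzzy function needs at least one vertex")
        xs = np.array([v[0] for v in verts], dtype=float)
        ys = np.array([v[1] for v in verts], dtype=float)
        if np.any(np.diff(xs) <= 0):
            raise ValueError(f"feature values must be strictly increasing: {xs.tolist()}")
        if np.any((ys < 0) | (ys > 1)):
            raise ValueError(f"confidences must lie in [0, 1]: {ys.tolist()}")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "_xs", xs)
        object.__setattr__(self, "_ys", ys)

    def __call__(self, value):
        """Evaluate the membership at ``value`` (scalar or array)."""
        out = np.interp(value, self._xs, self._ys)
        return float(out) if np.isscalar(value) or np.ndim(value) == 0 else out

    @property
    def support(self) -> tuple[float, float]:
        """Interval outside which the membership is constant."""
        return float(self._xs[0]), float(self._xs[-1])

    @classmethod
    def from_range(cls, low: float, high: float,
                   shoulder: float = SHOULDER_FRACTION) -> "FuzzyFunction":
        """Trapezoid with full confidence on [low, high].

        Linear shoulders of width ``shoulder * (high - low)`` fall to zero on
        each side.  Used to translate printed plausibility ranges such as
        "typically 50-100 mm" into membership functions.  A degenerate range
        (low == high) falls back to a fixed 1 mm shoulder so the function
        still has a nonzero support.
        """
        low, high = float(low), float(high)
        if high < low:
            raise ValueError(f"invalid range [{low}, {high}]")
        w = shoulder * (high - low)
        if w <= 0:
            w = 1.0
        return cls(((low - w, 0.0), (low, 1.0), (high, 1.0), (high + w, 0.0)))

    @classmethod
    def from_tolerance(cls, tol: float,
                       shoulder: float = SHOULDER_FRACTION) -> "FuzzyFunction":
        """Membership over a non-negative distance: 1 within ``tol``, falling
        to 0 over a shoulder of width ``shoulder * 2 * tol`` beyond it."""
        tol = float(tol)
        if tol <= 0:
            raise ValueError("tolerance must be positive")
        w = shoulder * 2.0 * tol
        return cls(((tol, 1.0), (tol + w, 0.0)))
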