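"""Legendre polynomial basis over a standardized age interval.

Random-regression models parameterize trajectories as linear combinations of
Legendre polynomials evaluated at a standardized age ``x in [-1, 1]``.  Under
the normalized convention used throughout quantitative genetics the basis
functions are ``phi_k(x) = sqrt((2k+1)/2) * P_k(x)``, which are orthonormal on
[-1, 1]; with the raw convention they are the plain ``P_k``.  All downstream
genetic parameters (heritability, correlations) are invariant to the choice as
long as estimation and evaluation share it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LegendreBasis", "legendre_values"]


def legendre_values(x: np.ndarray, order: int) -> np.ndarray:
    """Evaluate P_0..P_order at ``x`` by the three-term recurrence.

    (k+1) P_{k+1}(x) = (2k+1) x P_k(x) - k P_{k-1}(x)

    Returns an array of shape ``(len(x), order + 1)``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty((x.shape[0], order + 1))
    out[:, 0] = 1.0
    if order >= 1:
        out[:, 1] = x
    for k in range(1, order):
        out[:, k + 1] = ((2 * k + 1) * x * out[:, k] - k * out[:, k - 1]) / (k + 1)
    return out


@dataclass(frozen=True)
class LegendreBasis:
    """Legendre basis of a given order on an age interval in months.

    Parameters
    ----------
    order:
        Highest polynomial order (the basis has ``order + 1`` functions).
    t_min, t_max:
        Age bounds (months) mapped linearly onto [-1, 1].
    normalized:
        If True (default) use ``sqrt((2k+1)/2) * P_k``, orthonormal on [-1, 1].
    """

    order: int
    t_min: float
    t_max: float
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("polynomial order must be >= 0")
        if not self.t_max > self.t_min:
            raise ValueError(
                f"age bounds require t_max > t_min, got ({self.t_min}, {self.t_max})"
            )

    @property
    def n_coef(self) -> int:
        return self.order + 1

    def standardize(self, t, clamp: bool = False) -> np.ndarray:
        """Map age in months to x = -1 + 2 (t - t_min)/(t_max - t_min)."""
        t = np.asarray(t, dtype=float)
        x = -1.0 + 2.0 * (t - self.t_min) / (self.t_max - self.t_min)
        if clamp:
            return np.clip(x, -1.0, 1.0)
        bad = (x < -1.0 - 1e-12) | (x > 1.0 + 1e-12)
        if np.any(bad):
            offending = np.atleast_1d(t)[np.atleast_1d(bad)][:5]
            raise ValueError(
                f"ages {offending.tolist()} outside bounds "
                f"({self.t_min}, {self.t_max}); pass clamp=True to clamp"
            )
        return np.clip(x, -1.0, 1.0)

    def matrix(self, t, clamp: bool = False) -> np.ndarray:
        """Basis rows for an array of ages: shape (n, order + 1)."""
        x = np.atleast_1d(self.standardize(t, clamp=clamp))
        vals = legendre_values(x, self.order)
        if self.normalized:
            k = np.arange(self.order + 1)
            vals = vals * np.sqrt((2 * k + 1) / 2.0)
        return vals

    def row(self, t: float, clamp: bool = False) -> np.ndarray:
        """Basis vector phi(t) of length order + 1 for a single age."""
        return self.matrix([t], clamp=clamp)[0]

    def grid(self, step: float = 1.0) -> np.ndarray:
        """Integer-month evaluation grid from t_min to t_max inclusive."""
        return np.arange(self.t_min, self.t_max + step / 2, step, dtype=float)
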