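"""Distances between a fitted and a true single-year density.

All three measures are discrete sums over a common unit grid (no dx
weighting — the grid step is one year): integrated absolute error,
integrated squared error, and the Kullback–Leibler distance. Lower is
better; all are zero iff the densities coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grouped import FineGrid

__all__ = ["DensityPair", "iae", "ise", "kl"]


@dataclass(frozen=True)
class DensityPair:
    """True and fitted density values on a shared fine grid."""

    grid: FineGrid
    f_true: np.ndarray
    f_hat: np.ndarray

    def __post_init__(self) -> None:
        ft = np.asarray(self.f_true, dtype=float)
        fh = np.asarray(self.f_hat, dtype=float)
        if ft.shape != fh.shape or ft.size != self.grid.J:
            raise ValueError("density arrays must both have length grid.J")
        if np.any(ft < 0) or np.any(fh < 0):
            raise ValueError("densities must be non-negative")
        object.__setattr__(self, "f_true", ft)
        object.__setattr__(self, "f_hat", fh)


def _arrays(pair) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pair, DensityPair):
        return pair.f_true, pair.f_hat
    ft, fh = pair
    ft = np.asarray(ft, dtype=float)
    fh = np.asarray(fh, dtype=float)
    if ft.shape != fh.shape:
        raise ValueError("density arrays must have equal length")
    return ft, fh


def iae(pair) -> float:
    """Integrated absolute error: sum |f_hat - f_true|."""
    ft, fh = _arrays(pair)
    return float(np.sum(np.abs(fh - ft)))


def ise(pair) -> float:
    """Integrated squared error: sum (f_hat - f_true)^2."""
    ft, fh = _arrays(pair)
    return float(np.sum((fh - ft) ** 2))


def kl(pair, floor: float = 1e-12) -> float:
    """Kullback–Leibler distance sum f * log(f / f_hat), natural log.

    Both densities are renormalized to sum to one on the comparison grid
    and the fitted density floored at ``floor``, so the result is finite
    and non-negative; terms with f = 0 contribute nothing.
    """
    ft, fh = _arrays(pair)
    ft = ft / ft.sum()
    fh = np.maximum(fh, floor)
    fh = fh / fh.sum()
    mask = ft > 0
    return float(np.sum(ft[mask] * np.log(ft[mask] / fh[mask])))
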