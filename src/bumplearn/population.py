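"""Grid populations and the bump coding scheme.

A population of ``n**d`` binary neurons is arranged on a d-dimensional grid.
Neuron ``i = (i_1, ..., i_d)`` (1-based indices, each in ``1..n``) has
preferred value ``(i_1/n, ..., i_d/n)``, so the grid tiles ``(0, 1]^d``.
A parameter value is represented by a *bump*: the hyper-cubic set of neurons
within ``k/2`` grid steps of a center neuron on every axis.  The bump center
encodes the value; the width ``k`` encodes the tuning breadth (broad tuning =
many co-active neurons).

Two boundary conventions are supported: ``bounded`` clamps axis intervals to
``[1, n]`` (bumps shrink at the edges), ``circular`` wraps them modulo ``n``
(ring populations, e.g. head-direction or orientation codes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Tuple

import numpy as np

__all__ = [
    "PopulationGrid",
    "BumpActivation",
    "interval_k",
    "encode_value",
    "decode_center",
    "make_bump",
]

BOUNDED = "bounded"
CIRCULAR = "circular"


class InvalidIndexError(IndexError):
    """A neuron index lies outside ``1..n``."""


class DomainError(ValueError):
    """An encoded value lies outside ``[0, 1]``."""


@dataclass(frozen=True)
class PopulationGrid:
    """Geometry of a d-dimensional neuron grid.

    Parameters
    ----------
    d : int
        Dimensionality of the encoded parameter.
    n : int
        Neurons per axis; the population holds ``n**d`` neurons.
    topology : {"bounded", "circular"}
        Boundary convention for bumps.
    """

    d: int
    n: int
    topology: str = BOUNDED

    def __post_init__(self) -> None:
        if self.d < 1 or self.n < 1:
            raise ValueError(f"d and n must be positive, got d={self.d}, n={self.n}")
        if self.topology not in (BOUNDED, CIRCULAR):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def size(self) -> int:
        """Total neuron count ``n**d``."""
        return self.n**self.d

    @property
    def shape(self) -> Tuple[int, ...]:
        return (self.n,) * self.d

    def validate_index(self, i) -> np.ndarray:
        i = np.atleast_1d(np.asarray(i, dtype=np.int64))
        if i.shape != (self.d,):
            raise InvalidIndexError(
                f"index {tuple(i)} has wrong dimensionality for d={self.d}"
            )
        if np.any(i < 1) or np.any(i > self.n):
            raise InvalidIndexError(f"index {tuple(i)} outside 1..{self.n}")
        return i

    def ravel(self, i) -> int:
        """Flat 0-based position of 1-based index tuple ``i``."""
        i = self.validate_index(i)
        return int(np.ravel_multi_index(i - 1, self.shape))

    def unravel(self, flat: int) -> Tuple[int, ...]:
        """1-based index tuple of a flat 0-based position."""
        return tuple(int(c) + 1 for c in np.unravel_index(flat, self.shape))


def interval_k(a: int, k: int, grid: PopulationGrid) -> np.ndarray:
    """Axis indices within ``k/2`` of ``a``: the integers in ``[a-k/2, a+k/2]``.

    Bounded grids clamp the interval to ``[1, n]``; circular grids wrap it
    modulo ``n``.  The result is sorted, nonempty, and always contains ``a``.
    """
    if k < 0:
        raise ValueError(f"width k must be nonnegative, got {k}")
    n = grid.n
    if not 1 <= a <= n:
        raise InvalidIndexError(f"axis index {a} outside 1..{n}")
    lo = math.ceil(a - k / 2)
    hi = math.floor(a + k / 2)
    if grid.topology == CIRCULAR:
        if hi - lo + 1 >= n:
            return np.arange(1, n + 1, dtype=np.int64)
        idx = (np.arange(lo, hi + 1, dtype=np.int64) - 1) % n + 1
        return np.sort(idx)
    return np.arange(max(1, lo), min(n, hi) + 1, dtype=np.int64)


@dataclass(frozen=True)
class BumpActivation:
    """A width-``k`` hyper-cubic set of co-active neurons around a center.

    ``axes`` holds the per-axis index sets; the active neuron set is their
    Cartesian product.
    """

    center: Tuple[int, ...]
    width: int
    axes: Tuple[Tuple[int, ...], ...]
    grid: PopulationGrid = field(repr=False)

    @property
    def size(self) -> int:
        return int(np.prod([len(ax) for ax in self.axes]))

    def __iter__(self) -> Iterator[Tuple[int, ...]]:
        """Iterate over active neuron index tuples (row-major)."""
        import itertools

        return iter(itertools.product(*self.axes))

    @property
    def neurons(self) -> set:
        return set(self)

    def flat_indices(self) -> np.ndarray:
        """Flat 0-based positions of all active neurons."""
        grids = np.meshgrid(*[np.asarray(ax) - 1 for ax in self.axes], indexing="ij")
        return np.ravel_multi_index([g.ravel() for g in grids], self.grid.shape)


def make_bump(center, k: int, grid: PopulationGrid) -> BumpActivation:
    """Bump of width ``k`` centered at neuron ``center``."""
    c = grid.validate_index(center)
    axes = tuple(tuple(int(v) for v in interval_k(int(a), k, grid)) for a in c)
    return BumpActivation(center=tuple(int(a) for a in c), width=k, axes=axes, grid=grid)


def encode_value(x, grid: PopulationGrid) -> np.ndarray:
    """Center neuron for a continuous value ``x in [0,1]^d``.

    Picks per axis the index minimizing ``|i/n - x_j|`` (round half up),
    clamped to ``1..n``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != (grid.d,):
        raise DomainError(f"value of shape {x.shape} does not match d={grid.d}")
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise DomainError(f"value {x} outside [0,1]^{grid.d}")
    i = np.floor(x * grid.n + 0.5).astype(np.int64)
    return np.clip(i, 1, grid.n)


def decode_center(i, grid: PopulationGrid) -> np.ndarray:
    """Preferred value ``(i_1/n, ..., i_d/n)`` of neuron ``i``."""
    i = grid.validate_index(i)
    return i.astype(float) / grid.n
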