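"""Ordered cell partitions of a log10-intensity interval.

All densities, transfer matrices and piecewise-linear maps in this package
live on a :class:`Partition`: an ordered set of cell edges over a log10
fluorescence-intensity domain ``[lo, hi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ValidationError

__all__ = ["Partition", "DEFAULT_LO", "DEFAULT_HI", "DEFAULT_N_CELLS"]

#: Default domain in log10 units: raw intensities spanning 1 to 10^4.
DEFAULT_LO = 0.0
DEFAULT_HI = 4.0
DEFAULT_N_CELLS = 16


@dataclass(frozen=True)
class Partition:
    """An ordered partition of ``[lo, hi)`` into ``n_cells`` cells.

    Parameters
    ----------
    edges : ndarray of shape (n_cells + 1,)
        Strictly increasing cell boundaries; ``edges[0]`` is the domain
        lower bound and ``edges[-1]`` the (excluded) upper bound.
    """

    edges: np.ndarray = field(repr=False)

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or edges.size < 3:
            raise ValidationError("partition needs at least 2 cells (3 edges)")
        if not np.all(np.isfinite(edges)):
            raise ValidationError("partition edges must be finite")
        if not np.all(np.diff(edges) > 0):
            raise ValidationError("partition edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)
        edges.setflags(write=False)

    @classmethod
    def uniform(
        cls,
        lo: float = DEFAULT_LO,
        hi: float = DEFAULT_HI,
        n_cells: int = DEFAULT_N_CELLS,
    ) -> "Partition":
        """Uniform partition of ``[lo, hi)`` into ``n_cells`` equal cells."""
        if not hi > lo:
            raise ValidationError(f"need hi > lo, got lo={lo}, hi={hi}")
        if n_cells < 2:
            raise ValidationError(f"need n_cells >= 2, got {n_cells}")
        return cls(np.linspace(lo, hi, n_cells + 1))

    @property
    def lo(self) -> float:
        return float(self.edges[0])

    @property
    def hi(self) -> float:
        return float(self.edges[-1])

    @property
    def n_cells(self) -> int:
        return self.edges.size - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def locate(self, x) -> np.ndarray:
        """Cell index of each point of ``x`` (half-open cells ``[e_i, e_{i+1})``).

        Raises
        ------
        DomainError
            If any point lies outside ``[lo, hi)``.
        """
        x = np.asarray(x, dtype=float)
        if np.any(x < self.lo) or np.any(x >= self.hi):
            bad = x[(x < self.lo) | (x >= self.hi)]
            raise DomainError(
                f"point(s) outside domain [{self.lo}, {self.hi}): {bad[:5]}"
            )
        return np.minimum(
            np.searchsorted(self.edges, x, side="right") - 1, self.n_cells - 1
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.edges.shape == other.edges.shape and bool(
            np.array_equal(self.edges, other.edges)
        )

    def __hash__(self):
        return hash(self.edges.tobytes())

    def __repr__(self) -> str:
        return f"Partition(lo={self.lo}, hi={self.hi}, n_cells={self.n_cells})"
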