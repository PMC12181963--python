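"""Piecewise-linear maps and their induced transfer (Frobenius-Perron) matrices.

A :class:`PiecewiseLinearMap` is an ordered set of affine branches covering
a half-open domain ``[lo, hi)``.  Restricted to piecewise-constant densities
on a partition, its transfer operator is a row-stochastic matrix whose
entry ``Q[i, j]`` is the fraction of probability mass in cell ``i`` moved
to cell ``j`` in one step.  Both directions are computed exactly from the
branch geometry (Lebesgue measure of preimages), never by sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .density import Density
from .errors import (
    ConvergenceError,
    DomainError,
    InvalidMapError,
    InvalidMatrixError,
    PartitionMismatchError,
    ValidationError,
)
from .partition import Partition

__all__ = [
    "MapBranch",
    "PiecewiseLinearMap",
    "TransferMatrix",
    "apply_map",
    "transfer_matrix_of_map",
    "evolve_density",
    "invariant_density",
    "save_map_json",
    "load_map_json",
]

IMAGE_TOL = 1e-9
ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class MapBranch:
    """One affine branch ``x -> slope * x + intercept`` on ``[x_lo, x_hi)``."""

    x_lo: float
    x_hi: float
    slope: float
    intercept: float

    def __post_init__(self):
        if not self.x_lo < self.x_hi:
            raise InvalidMapError(
                f"branch domain [{self.x_lo}, {self.x_hi}) is empty"
            )
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise InvalidMapError("branch slope and intercept must be finite")

    def image(self, x: float) -> float:
        return self.slope * x + self.intercept

    def image_interval(self) -> tuple[float, float]:
        """Closure of the branch image, as an ordered (lo, hi) pair."""
        a, b = self.image(self.x_lo), self.image(self.x_hi)
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PiecewiseLinearMap:
    """The one-step expression map: ordered affine branches over a partition.

    Branch domains tile ``[lo, hi)`` exactly (no gaps, no overlaps);
    discontinuities at branch boundaries are permitted and expected.
    Branch images must stay inside the closed domain within ``1e-9``;
    evaluation clips them to the domain afterwards.
    """

    partition: Partition
    branches: tuple[MapBranch, ...]

    def __post_init__(self):
        branches = tuple(self.branches)
        if not branches:
            raise InvalidMapError("a map needs at least one branch")
        branches = tuple(sorted(branches, key=lambda b: b.x_lo))
        lo, hi = self.partition.lo, self.partition.hi
        if abs(branches[0].x_lo - lo) > 0 or abs(branches[-1].x_hi - hi) > 0:
            raise InvalidMapError(
                f"branches must cover [{lo}, {hi}) exactly; got "
                f"[{branches[0].x_lo}, {branches[-1].x_hi})"
            )
        for left, right in zip(branches, branches[1:]):
            if left.x_hi != right.x_lo:
                raise InvalidMapError(
                    f"gap or overlap between branches at {left.x_hi} vs {right.x_lo}"
                )
        for b in branches:
            img_lo, img_hi = b.image_interval()
            if img_lo < lo - IMAGE_TOL or img_hi > hi + IMAGE_TOL:
                raise InvalidMapError(
                    f"branch on [{b.x_lo}, {b.x_hi}) maps outside the domain: "
                    f"image [{img_lo}, {img_hi}] vs [{lo}, {hi}]"
                )
        object.__setattr__(self, "branches", branches)

    @property
    def breakpoints(self) -> np.ndarray:
        """Lower endpoints of all branch domains, in order."""
        return np.array([b.x_lo for b in self.branches])

    def branch_index(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.partition.lo, self.partition.hi
        if np.any(x < lo) or np.any(x >= hi):
            raise DomainError(f"point(s) outside map domain [{lo}, {hi})")
        return np.searchsorted(self.breakpoints, x, side="right") - 1

    def __call__(self, x):
        return apply_map(self, x)


def apply_map(pw_map: PiecewiseLinearMap, x):
    """Evaluate the map at scalar or array ``x`` in ``[lo, hi)``.

    Images are clipped into the closed domain (branch validation already
    guarantees they cannot exceed it by more than ``1e-9``).
    """
    scalar = np.isscalar(x)
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    idx = pw_map.branch_index(x_arr)
    slopes = np.array([b.slope for b in pw_map.branches])
    intercepts = np.array([b.intercept for b in pw_map.branches])
    y = slopes[idx] * x_arr + intercepts[idx]
    y = np.clip(y, pw_map.partition.lo, pw_map.partition.hi)
    return float(y[0]) if scalar else y


def apply_map_in_domain(pw_map: PiecewiseLinearMap, x: np.ndarray) -> np.ndarray:
    """Like :func:`apply_map` but nudges exact-``hi`` images just below ``hi``.

    Used by iterated (ensemble) evaluation, where outputs must remain
    inside the half-open domain to be valid inputs for the next step.
    """
    y = apply_map(pw_map, np.asarray(x, dtype=float))
    hi = pw_map.partition.hi
    hi_in = np.nextafter(hi, pw_map.partition.lo)
    return np.minimum(y, hi_in)


@dataclass(frozen=True)
class TransferMatrix:
    """Row-stochastic mass-transition matrix between partition cells."""

    partition: Partition
    Q: np.ndarray = field(repr=False)

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        n = self.partition.n_cells
        if Q.shape != (n, n):
            raise InvalidMatrixError(f"expected a {n}x{n} matrix, got {Q.shape}")
        if np.any(Q < -1e-12) or np.any(Q > 1 + 1e-12):
            raise InvalidMatrixError("entries must lie in [0, 1]")
        row_sums = Q.sum(axis=1)
        if np.any(np.abs(row_sums - 1) > ROW_SUM_TOL):
            worst = float(np.max(np.abs(row_sums - 1)))
            raise InvalidMatrixError(
                f"rows must sum to 1 within {ROW_SUM_TOL}; worst deviation {worst:g}"
            )
        Q = np.clip(Q, 0.0, 1.0)
        object.__setattr__(self, "Q", Q)
        Q.setflags(write=False)

    @property
    def n_cells(self) -> int:
        return self.partition.n_cells


def transfer_matrix_of_map(
    pw_map: PiecewiseLinearMap, partition: Partition | None = None
) -> TransferMatrix:
    """Exact transfer matrix of a piecewise-linear map on its partition.

    ``Q[i, j]`` is the Lebesgue measure of ``{x in cell i : S(x) in cell j}``
    divided by the width of cell ``i``, computed branch by branch: the
    branch domain is intersected with cell ``i``, pushed through the affine
    branch, and the image length apportioned over target cells.  Zero-width
    intersections contribute exactly zero.
    """
    if partition is None:
        partition = pw_map.partition
    if partition != pw_map.partition:
        raise PartitionMismatchError("map and partition disagree")
    edges = partition.edges
    lo, hi = partition.lo, partition.hi
    n = partition.n_cells
    Q = np.zeros((n, n))
    for br in pw_map.branches:
        img_lo, img_hi = br.image_interval()
        if img_lo < lo - IMAGE_TOL or img_hi > hi + IMAGE_TOL:
            raise InvalidMapError("branch image escapes the domain")
        i0 = int(np.searchsorted(edges, br.x_lo, side="right") - 1)
        i1 = int(np.searchsorted(edges, br.x_hi, side="left"))
        for i in range(max(i0, 0), min(i1, n)):
            a = max(br.x_lo, edges[i])
            b = min(br.x_hi, edges[i + 1])
            if b <= a:
                continue
            if br.slope == 0.0:
                y = min(max(br.intercept, lo), np.nextafter(hi, lo))
                j = int(np.searchsorted(edges, y, side="right") - 1)
                Q[i, min(j, n - 1)] += b - a
                continue
            ya, yb = br.image(a), br.image(b)
            y_lo, y_hi = (ya, yb) if ya <= yb else (yb, ya)
            y_lo, y_hi = max(y_lo, lo), min(y_hi, hi)
            j0 = max(int(np.searchsorted(edges, y_lo, side="right") - 1), 0)
            j1 = min(int(np.searchsorted(edges, y_hi, side="left")), n)
            for j in range(j0, j1):
                seg = min(y_hi, edges[j + 1]) - max(y_lo, edges[j])
                if seg > 0:
                    Q[i, j] += seg / abs(br.slope)
    widths = partition.widths
    Q /= widths[:, None]
    row_sums = Q.sum(axis=1)
    if np.any(np.abs(row_sums - 1) > ROW_SUM_TOL):
        raise InvalidMapError(
            "branch geometry does not conserve mass (row sums "
            f"{row_sums.min():.3g}..{row_sums.max():.3g})"
        )
    return TransferMatrix(partition, Q / row_sums[:, None])


def evolve_density(tm: TransferMatrix, f: Density) -> Density:
    """One forward step of the transfer operator on a density."""
    if tm.partition != f.partition:
        raise PartitionMismatchError("transfer matrix and density partitions differ")
    masses_next = tm.Q.T @ f.masses
    return Density.from_masses(tm.partition, masses_next)


def invariant_density(
    tm: TransferMatrix,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    start: Density | None = None,
) -> Density:
    """Invariant density of a transfer matrix by power iteration.

    Starts from the uniform density (or ``start``) and iterates until the
    L1 change per step falls below ``tol``; power iteration (rather than a
    general eigensolver) guarantees a non-negative, normalized result.
    Periodic matrices (e.g. permutations) fail to converge from generic
    starts and raise with the final residual attached.
    """
    if not tol > 0:
        raise ValidationError("tol must be positive")
    if start is not None and start.partition != tm.partition:
        raise PartitionMismatchError("start density partition differs")
    widths = tm.partition.widths
    if start is None:
        m = widths / widths.sum()  # uniform density's mass vector
    else:
        m = start.masses / start.masses.sum()
    QT = tm.Q.T
    residual = np.inf
    for _ in range(max_iter):
        m_next = QT @ m
        m_next /= m_next.sum()
        residual = float(np.abs(m_next - m).sum())
        m = m_next
        if residual <= tol:
            return Density.from_masses(tm.partition, m)
    raise ConvergenceError(
        f"power iteration did not reach tol={tol} in {max_iter} steps "
        f"(final L1 residual {residual:.3g})",
        residual=residual,
    )


# ---------------------------------------------------------------------------
# JSON serialization


def save_map_json(pw_map: PiecewiseLinearMap, path) -> None:
    payload = {
        "domain": {"lo": pw_map.partition.lo, "hi": pw_map.partition.hi},
        "partition_edges": [float(e) for e in pw_map.partition.edges],
        "branches": [
            {
                "x_lo": b.x_lo,
                "x_hi": b.x_hi,
                "slope": b.slope,
                "intercept": b.intercept,
            }
            for b in pw_map.branches
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_map_json(path) -> PiecewiseLinearMap:
    """Read a map JSON, validating every structural invariant."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such map JSON: {path}")
    payload = json.loads(path.read_text())
    try:
        edges = np.asarray(payload["partition_edges"], dtype=float)
        domain = payload["domain"]
        branch_specs = payload["branches"]
    except (KeyError, TypeError) as exc:
        raise InvalidMapError(f"malformed map JSON {path.name}: {exc}") from exc
    partition = Partition(edges)
    if partition.lo != domain["lo"] or partition.hi != domain["hi"]:
        raise InvalidMapError("domain does not match partition edges")
    branches = tuple(
        MapBranch(
            x_lo=float(b["x_lo"]),
            x_hi=float(b["x_hi"]),
            slope=float(b["slope"]),
            intercept=float(b["intercept"]),
        )
        for b in branch_specs
    )
    return PiecewiseLinearMap(partition=partition, branches=branches)
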