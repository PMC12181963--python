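"""Dynamical analysis of fitted piecewise-linear maps.

Equilibria are the intersections of the map with the diagonal ``y = x``;
because every branch is affine they are computed in closed form per branch
(never by generic root-finding, which would stumble on the discontinuities
at branch boundaries).  The Lyapunov exponent is the expected log absolute
slope under a reference density; positive values indicate expanding-on-
average, i.e. chaotic, dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .density import Density
from .errors import ConvergenceError, DivergenceError, ValidationError
from .transfer import (
    MapBranch,
    PiecewiseLinearMap,
    invariant_density,
    transfer_matrix_of_map,
)

__all__ = [
    "FixedPoint",
    "FixedPointSet",
    "BifurcationDiagram",
    "find_fixed_points",
    "lyapunov_exponent",
    "bifurcation_scan",
    "make_map_family",
]

#: |S(x*) - x*| tolerance every reported fixed point must satisfy.
FIXED_POINT_TOL = 1e-9
#: slope == 1 / intercept == 0 degeneracy tolerance (exact arithmetic cases).
DEGENERATE_TOL = 0.0


@dataclass(frozen=True)
class FixedPoint:
    """An isolated equilibrium ``x* = S(x*)`` on one branch."""

    x_star: float
    branch_index: int
    slope: float

    @property
    def stable(self) -> bool:
        """Strict linear stability: ``|slope| < 1``."""
        return abs(self.slope) < 1.0

    @property
    def marginal(self) -> bool:
        return abs(self.slope) == 1.0


@dataclass(frozen=True)
class FixedPointSet:
    """Closed-form equilibria of a map, sorted by location.

    ``degenerate_branches`` lists indices of identity branches
    (slope 1, intercept 0), each an entire continuum of fixed points;
    they contribute no isolated :class:`FixedPoint`.
    """

    points: tuple[FixedPoint, ...]
    degenerate_branches: tuple[int, ...] = ()

    def __iter__(self) -> Iterator[FixedPoint]:
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, idx):
        return self.points[idx]

    @property
    def locations(self) -> np.ndarray:
        return np.array([p.x_star for p in self.points])


def find_fixed_points(pw_map: PiecewiseLinearMap) -> FixedPointSet:
    """Solve ``S(x) = x`` exactly, branch by branch.

    For each branch with slope != 1 the unique candidate is
    ``intercept / (1 - slope)``, kept iff it lies in the branch's half-open
    domain.  Slope-1 branches either are identity pieces (degenerate
    continua) or have no fixed point at all.
    """
    points: list[FixedPoint] = []
    degenerate: list[int] = []
    for k, br in enumerate(pw_map.branches):
        if br.slope == 1.0:
            if abs(br.intercept) <= DEGENERATE_TOL:
                degenerate.append(k)
            continue
        x_star = br.intercept / (1.0 - br.slope)
        if br.x_lo <= x_star < br.x_hi:
            assert abs(br.image(x_star) - x_star) <= FIXED_POINT_TOL
            points.append(
                FixedPoint(x_star=float(x_star), branch_index=k, slope=br.slope)
            )
    points.sort(key=lambda p: p.x_star)
    return FixedPointSet(points=tuple(points), degenerate_branches=tuple(degenerate))


def lyapunov_exponent(pw_map: PiecewiseLinearMap, f: Density) -> float:
    """Expected log absolute slope of the map under the density ``f``.

    Computed cell-exactly: for every branch/cell overlap the contribution
    is ``height * overlap_width * ln|slope|``.  A zero-slope branch under
    positive density mass makes the integral diverge to -inf and raises.
    """
    if f.partition != pw_map.partition:
        raise ValidationError("density must live on the map's partition")
    edges = f.partition.edges
    total = 0.0
    for br in pw_map.branches:
        i0 = int(np.searchsorted(edges, br.x_lo, side="right") - 1)
        i1 = int(np.searchsorted(edges, br.x_hi, side="left"))
        for i in range(max(i0, 0), min(i1, f.partition.n_cells)):
            overlap = min(br.x_hi, edges[i + 1]) - max(br.x_lo, edges[i])
            if overlap <= 0:
                continue
            weight = f.values[i] * overlap
            if weight == 0:
                continue
            if br.slope == 0:
                raise DivergenceError(
                    f"zero-slope branch on [{br.x_lo}, {br.x_hi}) carries "
                    "positive density mass; log-derivative diverges"
                )
            total += weight * np.log(abs(br.slope))
    return float(total)


# ---------------------------------------------------------------------------
# one-parameter families and bifurcation scans

_FAMILIES = ("pull_to_identity", "additive_shift")


def _pull_to_identity(pw_map: PiecewiseLinearMap, beta: float) -> PiecewiseLinearMap:
    """Homotopy toward the identity: ``S_b(x) = (1 - b) S(x) + b x``."""
    if not 0.0 <= beta <= 1.0:
        raise ValidationError("pull_to_identity requires beta in [0, 1]")
    branches = tuple(
        MapBranch(
            x_lo=b.x_lo,
            x_hi=b.x_hi,
            slope=(1.0 - beta) * b.slope + beta,
            intercept=(1.0 - beta) * b.intercept,
        )
        for b in pw_map.branches
    )
    return PiecewiseLinearMap(partition=pw_map.partition, branches=branches)


def _additive_shift(pw_map: PiecewiseLinearMap, beta: float) -> PiecewiseLinearMap:
    """Shift every image by ``beta``, clipping at the domain boundaries.

    Where the shifted image leaves the domain the branch is split and the
    escaping part replaced by a saturated (zero-slope) piece pinned at the
    boundary, keeping the map piecewise-linear.
    """
    lo, hi = pw_map.partition.lo, pw_map.partition.hi
    out: list[MapBranch] = []
    for b in pw_map.branches:
        slope, icpt = b.slope, b.intercept + beta
        if slope == 0.0:
            out.append(
                MapBranch(b.x_lo, b.x_hi, 0.0, min(max(icpt, lo), hi))
            )
            continue
        pieces: list[tuple[float, float]] = [(b.x_lo, b.x_hi)]
        # split at the preimages of both boundaries that fall inside the domain
        cuts = sorted(
            x
            for x in ((lo - icpt) / slope, (hi - icpt) / slope)
            if b.x_lo < x < b.x_hi
        )
        xs = [b.x_lo, *cuts, b.x_hi]
        for x0, x1 in zip(xs, xs[1:]):
            mid = 0.5 * (x0 + x1)
            y = slope * mid + icpt
            if y < lo:
                out.append(MapBranch(x0, x1, 0.0, lo))
            elif y > hi:
                out.append(MapBranch(x0, x1, 0.0, hi))
            else:
                out.append(MapBranch(x0, x1, slope, icpt))
    return PiecewiseLinearMap(partition=pw_map.partition, branches=tuple(out))


def make_map_family(
    pw_map: PiecewiseLinearMap, family: str
) -> Callable[[float], PiecewiseLinearMap]:
    if family == "pull_to_identity":
        return lambda beta: _pull_to_identity(pw_map, beta)
    if family == "additive_shift":
        return lambda beta: _additive_shift(pw_map, beta)
    raise ValidationError(
        f"unknown map family {family!r}; choose from {_FAMILIES}"
    )


@dataclass(frozen=True)
class BifurcationDiagram:
    """Per-parameter fixed points and invariant densities along a scan.

    ``invariant_densities[k]`` is ``None`` where power iteration failed to
    converge for that parameter value.
    """

    param_values: tuple[float, ...]
    fixed_points: tuple[FixedPointSet, ...]
    invariant_densities: tuple[Density | None, ...]

    def __post_init__(self):
        if not (
            len(self.param_values)
            == len(self.fixed_points)
            == len(self.invariant_densities)
        ):
            raise ValidationError("diagram fields must have one entry per parameter")


def bifurcation_scan(
    pw_map: PiecewiseLinearMap,
    family: str,
    param_values: Sequence[float],
    invariant_tol: float = 1e-10,
    invariant_max_iter: int = 50_000,
) -> BifurcationDiagram:
    """Scan a one-parameter deformation of the map.

    For every parameter value the deformed map's fixed points are computed
    in closed form, and the invariant density of its transfer matrix is
    recorded when power iteration converges.  Both built-in families are
    declared choices (the original control parameter behind such scans is
    problem-specific); arbitrary user families can be scanned by calling
    this with maps pre-built via :func:`make_map_family`.
    """
    param_values = [float(v) for v in param_values]
    if not param_values:
        raise ValidationError("param_values must be non-empty")
    if sorted(param_values) != param_values:
        raise ValidationError("param_values must be ascending")
    builder = make_map_family(pw_map, family)
    fps: list[FixedPointSet] = []
    densities: list[Density | None] = []
    for beta in param_values:
        deformed = builder(beta)
        fps.append(find_fixed_points(deformed))
        try:
            tm = transfer_matrix_of_map(deformed)
            densities.append(
                invariant_density(tm, tol=invariant_tol, max_iter=invariant_max_iter)
            )
        except ConvergenceError:
            densities.append(None)
    return BifurcationDiagram(
        param_values=tuple(param_values),
        fixed_points=tuple(fps),
        invariant_densities=tuple(densities),
    )
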