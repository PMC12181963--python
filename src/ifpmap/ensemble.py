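"""Ensemble (Monte-Carlo) iteration of a map over populations of cells.

The deterministic step sends every cell's log-intensity through the map;
the stochastic variant adds i.i.d. Gaussian perturbations to the image,
with reflecting (default) or clipping boundary handling.  Iterating over
ensembles sampled from a density gives a Monte-Carlo estimator of the
transfer-operator action, which is the module's central correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import Density, DensitySeries, density_from_log_events
from .errors import BoundaryError, ValidationError
from .partition import Partition
from .transfer import PiecewiseLinearMap, apply_map_in_domain

__all__ = [
    "Ensemble",
    "NoiseModel",
    "NO_NOISE",
    "sample_from_density",
    "step_ensemble",
    "predict_density_series",
]

#: Floor on the per-density sample count for meaningful histograms.
MIN_SAMPLES = 1000
MAX_REFLECTIONS = 10


@dataclass(frozen=True)
class Ensemble:
    """Per-cell log10 intensities of one population at one day."""

    values: np.ndarray = field(repr=False)
    day: int = 0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", values)
        values.setflags(write=False)

    @property
    def n(self) -> int:
        return self.values.size

    def to_density(self, partition: Partition) -> Density:
        return density_from_log_events(self.values, partition)


@dataclass(frozen=True)
class NoiseModel:
    """Additive perturbation applied after the map step.

    ``family`` is ``"none"`` or ``"gaussian"``; ``sigma`` is the standard
    deviation in log10-intensity units; ``boundary`` says how out-of-domain
    images are brought back (``"reflect"`` default; ``"clip"`` creates
    boundary atoms and is mainly useful for diagnostics).
    """

    family: str = "none"
    sigma: float = 0.0
    boundary: str = "reflect"

    def __post_init__(self):
        if self.family not in ("none", "gaussian"):
            raise ValidationError(f"unknown noise family {self.family!r}")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.family == "none" and self.sigma != 0:
            raise ValidationError("sigma must be 0 when family is 'none'")
        if self.boundary not in ("reflect", "clip"):
            raise ValidationError(f"unknown boundary policy {self.boundary!r}")


NO_NOISE = NoiseModel()


def sample_from_density(f: Density, n: int, seed) -> Ensemble:
    """Draw ``n`` cells from a piecewise-constant density.

    Cells are chosen by mass and positions uniformly within the chosen
    cell; identical seeds give bit-identical ensembles.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        return Ensemble(values=np.empty(0), day=0)
    part = f.partition
    cells = rng.choice(part.n_cells, size=n, p=f.masses / f.masses.sum())
    u = rng.random(n)
    values = part.edges[cells] + u * part.widths[cells]
    return Ensemble(values=values, day=0)


def _enforce_boundary(
    values: np.ndarray, partition: Partition, policy: str
) -> np.ndarray:
    lo, hi = partition.lo, partition.hi
    hi_in = np.nextafter(hi, lo)
    if policy == "clip":
        return np.clip(values, lo, hi_in)
    out = values.copy()
    for _ in range(MAX_REFLECTIONS):
        below, above = out < lo, out >= hi
        if not (below.any() or above.any()):
            return out
        out[below] = 2 * lo - out[below]
        out[above] = 2 * hi - out[above]
    if np.any((out < lo) | (out >= hi)):
        raise BoundaryError(
            f"values still out of [{lo}, {hi}) after {MAX_REFLECTIONS} "
            "reflection passes; noise scale is pathological for this domain"
        )
    return out


def step_ensemble(
    pw_map: PiecewiseLinearMap,
    ensemble: Ensemble,
    noise: NoiseModel = NO_NOISE,
    seed=None,
) -> Ensemble:
    """Advance every cell one day: map image plus optional additive noise."""
    y = apply_map_in_domain(pw_map, ensemble.values)
    if noise.family == "gaussian" and noise.sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise.sigma, size=y.size)
        y = _enforce_boundary(y, pw_map.partition, noise.boundary)
    return Ensemble(values=y, day=ensemble.day + 1)


def predict_density_series(
    pw_map: PiecewiseLinearMap,
    f0: Density,
    days: int,
    n: int = 100_000,
    noise: NoiseModel = NO_NOISE,
    seed=0,
    fraction_label: str = "predicted",
    carry_ensemble: bool = False,
) -> DensitySeries:
    """Predict a density series by iterated ensemble simulation.

    By default each day re-samples ``n`` initial conditions from the
    previous day's *density*, mirroring the prediction-from-previous-PDF
    procedure; ``carry_ensemble=True`` instead samples once and carries the
    raw population forward (lower variance, same limit).  Randomness is
    split per day from the master seed, so day ``k`` is reproducible.
    """
    if days < 1:
        raise ValidationError("days must be >= 1")
    if n < MIN_SAMPLES:
        raise ValidationError(f"n must be >= {MIN_SAMPLES} for a meaningful density")
    if f0.partition != pw_map.partition:
        raise ValidationError("initial density must live on the map's partition")
    partition = pw_map.partition
    master = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    day_seeds = master.spawn(days)
    densities: list[Density] = [f0]
    current = f0
    ensemble: Ensemble | None = None
    for k in range(days):
        sample_seed, step_seed = day_seeds[k].spawn(2)
        if carry_ensemble and ensemble is not None:
            stepped = step_ensemble(pw_map, ensemble, noise, seed=step_seed)
        else:
            drawn = sample_from_density(current, n, seed=sample_seed)
            stepped = step_ensemble(pw_map, drawn, noise, seed=step_seed)
        current = stepped.to_density(partition)
        densities.append(current)
        ensemble = stepped
    return DensitySeries(
        fraction_label=fraction_label,
        times=tuple(range(days + 1)),
        densities=tuple(densities),
    )
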