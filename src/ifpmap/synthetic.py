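"""Ground-truth maps and a synthetic cell-sorting experiment generator.

No public dataset accompanies the sorting experiment this emulates, so the
package ships its own: a parental population is burned in to the ground-
truth map's long-run distribution, split by intensity gates into sorted
fractions ("negative" through "high"), and every fraction is then advanced
daily, recording its density each day.  The resulting bundle exercises the
full inference pipeline end-to-end with a known answer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .density import Density, DensitySeries, density_from_log_events, l1_distance
from .ensemble import Ensemble, NoiseModel, NO_NOISE, sample_from_density, step_ensemble
from .errors import (
    EmptyGateError,
    PartitionMismatchError,
    ValidationError,
)
from .dynamics import find_fixed_points
from .inference import InferenceResult, construct_semi_markov_map
from .partition import Partition
from .transfer import (
    MapBranch,
    PiecewiseLinearMap,
    TransferMatrix,
    invariant_density,
)

__all__ = [
    "SortingGate",
    "ExperimentBundle",
    "default_gates",
    "make_ground_truth_map",
    "simulate_sorting_experiment",
    "recovery_report",
]

log = logging.getLogger(__name__)

DEFAULT_BURN_IN_STEPS = 50
#: Additive measurement noise on the log scale for optional event tables
#: (log-normal multiplicative on raw intensity); separate from dynamical noise.
DEFAULT_MEASUREMENT_SIGMA = 0.05
DEFAULT_GATE_LABELS = ("negative", "low", "medium", "high")


@dataclass(frozen=True)
class SortingGate:
    """A half-open sorting interval ``[lo, hi)`` on the log10 scale."""

    label: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValidationError(f"gate {self.label!r} has lo >= hi")

    def contains(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values)
        return (values >= self.lo) & (values < self.hi)


def default_gates(partition: Partition) -> list[SortingGate]:
    """Four equal-width gates spanning the domain, negative through high."""
    bounds = np.linspace(partition.lo, partition.hi, 5)
    return [
        SortingGate(label, float(a), float(b))
        for label, a, b in zip(DEFAULT_GATE_LABELS, bounds, bounds[1:])
    ]


@dataclass(frozen=True)
class ExperimentBundle:
    """Everything one simulated sorting experiment produced."""

    truth_map: PiecewiseLinearMap
    truth_sigma: float
    gates: tuple[SortingGate, ...]
    series: tuple[DensitySeries, ...]
    parental_density: Density
    event_tables: dict | None = None

    @property
    def partition(self) -> Partition:
        return self.truth_map.partition


def make_ground_truth_map(
    kind: str,
    partition: Partition | None = None,
    seed=0,
    peak: float = 0.5,
) -> PiecewiseLinearMap:
    """Build a ground-truth map with known dynamics.

    ``tent`` and ``skew_tent`` (peak position ``peak``, relative to the
    domain) are canonical chaotic maps with known invariant measures;
    ``random_semi_markov`` draws a Dirichlet(1, ..., 1)-row transition
    matrix and realizes it as a semi-Markov map, giving an endless supply
    of seeded test problems.
    """
    if partition is None:
        partition = Partition.uniform()
    lo, hi = partition.lo, partition.hi
    span = hi - lo
    if kind == "tent":
        peak = 0.5
        kind = "skew_tent"
    if kind == "skew_tent":
        if not 0.0 < peak < 1.0:
            raise ValidationError("skew-tent peak must lie strictly inside (0, 1)")
        mid = lo + peak * span
        up = MapBranch(lo, mid, 1.0 / peak, lo * (1.0 - 1.0 / peak))
        down_slope = -1.0 / (1.0 - peak)
        down = MapBranch(mid, hi, down_slope, hi - down_slope * mid)
        return PiecewiseLinearMap(partition=partition, branches=(up, down))
    if kind == "random_semi_markov":
        rng = np.random.default_rng(seed)
        n = partition.n_cells
        if n < 2:
            raise ValidationError("random_semi_markov needs n_cells >= 2")
        Q = rng.dirichlet(np.ones(n), size=n)
        return construct_semi_markov_map(TransferMatrix(partition, Q))
    raise ValidationError(
        f"unknown ground-truth map kind {kind!r}; "
        "choose tent, skew_tent or random_semi_markov"
    )


def simulate_sorting_experiment(
    pw_map: PiecewiseLinearMap,
    gates: Sequence[SortingGate] | None = None,
    n_cells: int = 20_000,
    days: int = 5,
    noise: NoiseModel = NO_NOISE,
    seed=0,
    burn_in_steps: int = DEFAULT_BURN_IN_STEPS,
    include_event_tables: bool = False,
    measurement_sigma: float = DEFAULT_MEASUREMENT_SIGMA,
) -> ExperimentBundle:
    """Simulate sorting a burned-in population into gated fractions.

    A parental ensemble of ``n_cells`` starts uniform and runs
    ``burn_in_steps`` map steps to reach the long-run distribution (the
    generative model for the parental population is taken to be the truth
    map's own attractor — self-consistency, since nothing else defines it).
    Each gate selects its fraction; the fraction is re-sampled up to
    ``n_cells`` from its renormalized density (a sorted subculture is
    expanded before daily assessment) and advanced ``days`` steps, with a
    density recorded for day 0 through ``days``.
    """
    if days < 2:
        raise ValidationError("days must be >= 2")
    if n_cells < 1000:
        raise ValidationError("n_cells must be >= 1000")
    partition = pw_map.partition
    if gates is None:
        gates = default_gates(partition)
    if not gates:
        raise ValidationError("need at least one sorting gate")
    for gate in gates:
        if gate.lo < partition.lo or gate.hi > partition.hi:
            raise ValidationError(f"gate {gate.label!r} exceeds the domain")

    master = np.random.SeedSequence(seed)
    burn_seed, *gate_seeds = master.spawn(1 + len(gates))

    # parental population: burn in from uniform under the same dynamics
    parental = sample_from_density(
        Density.uniform(partition), n_cells, seed=burn_seed.spawn(1)[0]
    )
    burn_step_seeds = burn_seed.spawn(burn_in_steps)
    for k in range(burn_in_steps):
        parental = step_ensemble(pw_map, parental, noise, seed=burn_step_seeds[k])
    parental_density = parental.to_density(partition)

    series: list[DensitySeries] = []
    event_tables: dict[str, dict[int, np.ndarray]] = {}
    for gate, gate_seed in zip(gates, gate_seeds):
        inside = parental.values[gate.contains(parental.values)]
        if inside.size == 0:
            raise EmptyGateError(
                f"gate {gate.label!r} [{gate.lo}, {gate.hi}) captured no cells"
            )
        sample_seed, meas_seed, *day_seeds = gate_seed.spawn(2 + days)
        day0_density = density_from_log_events(inside, partition)
        population = sample_from_density(day0_density, n_cells, seed=sample_seed)
        densities = [population.to_density(partition)]
        raw_days = {0: population.values.copy()}
        for day in range(1, days + 1):
            population = step_ensemble(
                pw_map, population, noise, seed=day_seeds[day - 1]
            )
            densities.append(population.to_density(partition))
            raw_days[day] = population.values.copy()
        series.append(
            DensitySeries(
                fraction_label=gate.label,
                times=tuple(range(days + 1)),
                densities=tuple(densities),
            )
        )
        if include_event_tables:
            rng = np.random.default_rng(meas_seed)
            event_tables[gate.label] = {
                day: 10.0
                ** (vals + rng.normal(0.0, measurement_sigma, size=vals.size))
                for day, vals in raw_days.items()
            }

    return ExperimentBundle(
        truth_map=pw_map,
        truth_sigma=noise.sigma,
        gates=tuple(gates),
        series=tuple(series),
        parental_density=parental_density,
        event_tables=event_tables if include_event_tables else None,
    )


def recovery_report(bundle: ExperimentBundle, result: InferenceResult) -> dict:
    """Score an inference result against the bundle's ground truth.

    Reports entrywise-max and Frobenius error of the estimated transition
    matrix, the L1 distance between invariant densities, matching of fixed
    points within 0.05 log-units, and the noise-scale error when both
    sides carry one.
    """
    if bundle.partition != result.Q_hat.partition:
        raise PartitionMismatchError("bundle and result partitions differ")
    from .transfer import transfer_matrix_of_map  # local: avoid cycle at import

    Q_true = transfer_matrix_of_map(bundle.truth_map).Q
    Q_hat = result.Q_hat.Q
    diff = Q_hat - Q_true
    inv_true = invariant_density(transfer_matrix_of_map(bundle.truth_map))
    inv_hat = invariant_density(result.Q_hat)
    fps_true = find_fixed_points(bundle.truth_map).locations
    fps_hat = find_fixed_points(result.map).locations
    matched = 0
    for x in fps_true:
        if fps_hat.size and np.min(np.abs(fps_hat - x)) <= 0.05:
            matched += 1
    report = {
        "q_max_error": float(np.max(np.abs(diff))),
        "q_frobenius_error": float(np.linalg.norm(diff)),
        "invariant_l1_error": float(l1_distance(inv_hat, inv_true)),
        "n_fixed_points_truth": int(fps_true.size),
        "n_fixed_points_fit": int(fps_hat.size),
        "n_fixed_points_matched": matched,
        "residual": result.residual,
        "n_pairs": result.n_pairs,
    }
    if result.sigma_hat is not None:
        report["sigma_hat"] = result.sigma_hat
        report["sigma_error"] = float(abs(result.sigma_hat - bundle.truth_sigma))
    return report
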