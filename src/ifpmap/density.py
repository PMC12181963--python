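"""Per-cell intensity ingestion and piecewise-constant density estimation.

This module turns tables of raw flow-cytometry events into probability
density functions on a shared :class:`~ifpmap.partition.Partition`, and
manages dated series of such densities per sorted fraction.

Densities are piecewise-constant (histogram) by design: that is the natural
representation on which the transfer operator acts, and it avoids the extra
bandwidth parameter a KDE would introduce.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    GapError,
    ParseError,
    PartitionMismatchError,
    SchemaError,
    ValidationError,
)
from .partition import Partition

__all__ = [
    "IntensitySample",
    "Density",
    "DensitySeries",
    "load_intensity_table",
    "load_intensity_fcs",
    "log10_transform",
    "estimate_density",
    "density_from_log_events",
    "l1_distance",
    "write_density_series_csv",
    "read_density_series_csv",
]

log = logging.getLogger(__name__)

MASS_TOL = 1e-9


@dataclass(frozen=True)
class IntensitySample:
    """A vector of per-event intensities plus bookkeeping counts.

    ``values`` are raw (linear-scale) fluorescence intensities until
    :func:`log10_transform` is applied, after which they are log10
    intensities.  ``n_dropped`` counts events removed by the transform
    policy.
    """

    values: np.ndarray = field(repr=False)
    n_dropped: int = 0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", values)
        values.setflags(write=False)
        if self.n_dropped < 0:
            raise ValidationError("n_dropped must be >= 0")

    @property
    def n_events(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class Density:
    """Piecewise-constant probability density on a partition.

    ``values[i]`` is the density height on cell ``i`` in probability per
    log10-intensity unit; heights are non-negative and integrate to one.
    """

    partition: Partition
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float).ravel()
        if values.size != self.partition.n_cells:
            raise ValidationError(
                f"expected {self.partition.n_cells} heights, got {values.size}"
            )
        if np.any(values < 0):
            raise ValidationError("density heights must be non-negative")
        total = float(values @ self.partition.widths)
        if abs(total - 1.0) > MASS_TOL:
            raise ValidationError(f"density integrates to {total}, not 1")
        object.__setattr__(self, "values", values)
        values.setflags(write=False)

    @classmethod
    def uniform(cls, partition: Partition) -> "Density":
        span = partition.hi - partition.lo
        return cls(partition, np.full(partition.n_cells, 1.0 / span))

    @classmethod
    def from_masses(cls, partition: Partition, masses: np.ndarray) -> "Density":
        """Build from per-cell probability masses (normalized internally)."""
        masses = np.asarray(masses, dtype=float)
        total = masses.sum()
        if total <= 0:
            raise EmptyInputError("total mass must be positive")
        return cls(partition, masses / total / partition.widths)

    @property
    def masses(self) -> np.ndarray:
        """Per-cell probability mass (heights times cell widths)."""
        return self.values * self.partition.widths


@dataclass(frozen=True)
class DensitySeries:
    """A dated sequence of densities for one sorted fraction.

    Day indices are integers (measurements spaced 24 h apart); all
    densities share one partition.
    """

    fraction_label: str
    times: tuple[int, ...]
    densities: tuple[Density, ...]

    def __post_init__(self):
        times = tuple(int(t) for t in self.times)
        densities = tuple(self.densities)
        if len(times) != len(densities):
            raise ValidationError("times and densities must have equal length")
        if len(times) == 0:
            raise EmptyInputError("a density series cannot be empty")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("day indices must be strictly increasing")
        part = densities[0].partition
        if any(d.partition != part for d in densities[1:]):
            raise PartitionMismatchError(
                "all densities in a series must share one partition"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "densities", densities)

    @property
    def partition(self) -> Partition:
        return self.densities[0].partition

    def __len__(self) -> int:
        return len(self.times)

    def consecutive_pairs(self) -> list[tuple[Density, Density]]:
        """All (day k, day k+1) density pairs.

        Raises
        ------
        GapError
            If any two successive measurements are more than one day apart
            (no interpolation is performed).
        """
        pairs = []
        for t0, t1, d0, d1 in zip(
            self.times, self.times[1:], self.densities, self.densities[1:]
        ):
            if t1 - t0 != 1:
                raise GapError(
                    f"fraction {self.fraction_label!r}: days {t0} and {t1} "
                    "are not consecutive"
                )
            pairs.append((d0, d1))
        return pairs


# ---------------------------------------------------------------------------
# ingestion


def load_intensity_table(path, column: str) -> IntensitySample:
    """Read one channel of per-event intensities from a CSV/TSV table.

    The file must have a header row naming ``column``; delimiter is
    sniffed from the extension (``.tsv``/``.tab`` -> tab, else comma).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such event table: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep)
    if column not in frame.columns:
        raise SchemaError(
            f"column {column!r} not found in {path.name}; "
            f"available: {list(frame.columns)}"
        )
    raw = pd.to_numeric(frame[column], errors="coerce")
    bad = raw.isna() & frame[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {frame[column].iloc[row]!r} in column "
            f"{column!r} at data row {row} of {path.name}"
        )
    values = raw.to_numpy(dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EmptyInputError(f"no parseable events in column {column!r} of {path.name}")
    return IntensitySample(values=values, n_dropped=0)


def load_intensity_fcs(path, channel: str) -> IntensitySample:
    """Optional FCS adapter: read one channel by its short name.

    Requires ``fcsparser`` (not a hard dependency); plain-text tables via
    :func:`load_intensity_table` are the supported default.
    """
    try:
        import fcsparser  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "FCS support requires the optional 'fcsparser' package"
        ) from exc
    _, frame = fcsparser.parse(str(path))  # pragma: no cover
    if channel not in frame.columns:  # pragma: no cover
        raise SchemaError(f"channel {channel!r} not in FCS file {path}")
    return IntensitySample(values=frame[channel].to_numpy(dtype=float))  # pragma: no cover


def log10_transform(
    sample: IntensitySample, policy: str = "drop", floor: float | None = None
) -> IntensitySample:
    """Convert raw intensities to log10 scale.

    Non-positive events (cytometers can report non-positive compensated
    values) are handled per ``policy``: ``"drop"`` removes them and counts
    them in ``n_dropped``; ``"clamp"`` raises them to ``floor`` (> 0)
    before taking the log.
    """
    values = sample.values
    if policy == "drop":
        keep = values > 0
        dropped = int(np.sum(~keep))
        if dropped and keep.sum() == 0:
            raise EmptyInputError("all events are non-positive; nothing to log")
        if dropped:
            log.info("log10_transform dropped %d non-positive events", dropped)
        return IntensitySample(
            values=np.log10(values[keep]), n_dropped=sample.n_dropped + dropped
        )
    if policy == "clamp":
        if floor is None or not floor > 0:
            raise ValidationError("clamp policy requires a positive floor")
        return IntensitySample(
            values=np.log10(np.maximum(values, floor)), n_dropped=sample.n_dropped
        )
    raise ValidationError(f"unknown log-transform policy {policy!r}")


# ---------------------------------------------------------------------------
# density estimation


def density_from_log_events(values: np.ndarray, partition: Partition) -> Density:
    """Histogram in-domain log10 events into a normalized density.

    All ``values`` must already lie in ``[lo, hi)``; see
    :func:`estimate_density` for out-of-range policies.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyInputError("cannot estimate a density from zero events")
    counts, _ = np.histogram(values, bins=partition.edges)
    return Density.from_masses(partition, counts.astype(float))


def estimate_density(
    sample: IntensitySample,
    partition: Partition,
    policy_out_of_range: str = "drop",
) -> Density:
    """Estimate a piecewise-constant density from log10-scale events.

    ``policy_out_of_range`` handles events outside ``[lo, hi)``:
    ``"drop"`` discards them (with a logged count), ``"clip"`` moves them
    to the nearest in-domain cell.
    """
    values = sample.values
    if policy_out_of_range == "drop":
        keep = (values >= partition.lo) & (values < partition.hi)
        n_out = int(np.sum(~keep))
        if n_out:
            log.info("estimate_density dropped %d out-of-range events", n_out)
        values = values[keep]
    elif policy_out_of_range == "clip":
        hi_in = np.nextafter(partition.hi, partition.lo)
        values = np.clip(values, partition.lo, hi_in)
    else:
        raise ValidationError(
            f"unknown out-of-range policy {policy_out_of_range!r}"
        )
    if values.size == 0:
        raise EmptyInputError("no in-range events to estimate a density from")
    return density_from_log_events(values, partition)


def l1_distance(a: Density, b: Density) -> float:
    """Integral of ``|a - b|`` over the domain (in [0, 2] for densities)."""
    if a.partition != b.partition:
        raise PartitionMismatchError("densities live on different partitions")
    return float(np.abs(a.values - b.values) @ a.partition.widths)


# ---------------------------------------------------------------------------
# series round-trip (long-format CSV)


def write_density_series_csv(series: Iterable[DensitySeries], path) -> None:
    """Write density series to a long-format CSV.

    Columns: ``fraction, day, cell_index, height``.  Heights are written
    with shortest round-trip ``repr`` so the reader reproduces them
    bit-exactly.
    """
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["fraction", "day", "cell_index", "height"])
        for s in series:
            for day, dens in zip(s.times, s.densities):
                for idx, h in enumerate(dens.values):
                    writer.writerow([s.fraction_label, day, idx, repr(float(h))])


def read_density_series_csv(path, partition: Partition) -> list[DensitySeries]:
    """Read the long-format CSV written by :func:`write_density_series_csv`.

    The partition is not stored in the CSV and must be supplied (it is
    recorded in the map JSON / run config).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such density CSV: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"fraction", "day", "cell_index", "height"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"density CSV missing columns: {sorted(missing)}")
    if len(frame) == 0:
        raise EmptyInputError(f"density CSV {path.name} holds no rows")
    out: list[DensitySeries] = []
    for label, group in frame.groupby("fraction", sort=False):
        times: list[int] = []
        densities: list[Density] = []
        for day, day_group in group.groupby("day", sort=True):
            heights = np.zeros(partition.n_cells)
            idx = day_group["cell_index"].to_numpy(dtype=int)
            if np.any(idx < 0) or np.any(idx >= partition.n_cells):
                raise SchemaError(
                    f"cell_index out of range for a {partition.n_cells}-cell partition"
                )
            heights[idx] = day_group["height"].to_numpy(dtype=float)
            times.append(int(day))
            densities.append(Density(partition, heights))
        out.append(
            DensitySeries(
                fraction_label=str(label),
                times=tuple(times),
                densities=tuple(densities),
            )
        )
    return out
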