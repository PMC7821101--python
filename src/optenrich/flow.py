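"""FACS gating and sorting simulation.

Events are rows of a DataFrame (one per cell) with intensity columns
(mcherry, mifp, gfp, bfp, fsc, ...).  A :class:`GateSet` assigns every
event to exactly one sort population or ``unsorted``.  Gates are simple
1-D thresholds on (log-)intensity, calibrated data-driven: the
mCherry-positive gate sits at the 99.9th percentile of an unactivated
reference population and multi-level boundaries at log-space midpoints
between the expected intensities of the photoactivation exposure classes
— the in-silico analog of predefining sorting gates with samples
photoactivated for different durations.

Sorting losses are modeled as independent Bernoulli recovery per gated
cell (default 0.8), and sequencing is a multinomial draw over the sorted
cells' sgRNA composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from optenrich.activation import ActivationResponse

EVENT_CHANNELS = ("mcherry", "mifp", "gfp", "bfp", "fsc")


class NoPositivesError(ValueError):
    """Raised when precision is requested but no positives were called."""


@dataclass
class FlowEvent:
    cell_id: int
    intensities: dict[str, float]
    recovered: bool = True


def events_frame(events: Iterable[FlowEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        row = {"cell_id": e.cell_id, "recovered": e.recovered}
        row.update(e.intensities)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RangeGate:
    """Keep events with channel value in (lo, hi]."""

    channel: str
    lo: float = -math.inf
    hi: float = math.inf


@dataclass(frozen=True)
class TopFractionGate:
    """Keep the top round(fraction * n) events ranked by channel value."""

    channel: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")


@dataclass
class GateSet:
    """Ordered, named sort-population gates; first match wins."""

    populations: dict[str, RangeGate | TopFractionGate] = dc_field(default_factory=dict)

    @classmethod
    def from_activation_classes(
        cls,
        unactivated_mcherry: Sequence[float],
        class_exposures: Mapping[str, float],
        response: ActivationResponse = ActivationResponse(),
    ) -> "GateSet":
        """Data-driven mCherry gates for photoactivation exposure classes.

        ``class_exposures`` maps population name -> exposure_ms in
        increasing exposure order.  The lowest boundary is the 99.9th
        percentile of the unactivated reference; boundaries between
        classes are midpoints between expected log-intensities.
        """
        ref = np.asarray(unactivated_mcherry, dtype=float)
        if ref.size == 0:
            raise ValueError("unactivated reference must be non-empty")
        base = float(np.quantile(ref, 0.999))
        names = list(class_exposures)
        exps = np.array([class_exposures[n] for n in names], dtype=float)
        if not np.all(np.diff(exps) > 0):
            raise ValueError("class exposures must be strictly increasing")
        centers = np.log(response.expected_intensity(exps))
        bounds = [base]
        for lo, hi in zip(centers[:-1], centers[1:]):
            bounds.append(math.exp((lo + hi) / 2.0))
        bounds.append(math.inf)
        pops = {
            name: RangeGate("mcherry", lo=bounds[i], hi=bounds[i + 1])
            for i, name in enumerate(names)
        }
        return cls(populations=pops)

    @classmethod
    def top_fraction(cls, channel: str, fraction: float,
                     name: str | None = None) -> "GateSet":
        name = name or f"high_{channel}"
        return cls(populations={name: TopFractionGate(channel, fraction)})


def gate_events(events: pd.DataFrame, gates: GateSet) -> pd.Series:
    """Assign every event to exactly one population or ``unsorted``."""
    n = len(events)
    assignment = pd.Series(["unsorted"] * n, index=events.index, name="population")
    unassigned = np.ones(n, dtype=bool)
    for name, gate in gates.populations.items():
        if gate.channel not in events.columns:
            raise KeyError(f"events lack channel {gate.channel!r}")
        values = events[gate.channel].to_numpy(dtype=float)
        if isinstance(gate, RangeGate):
            match = (values > gate.lo) & (values <= gate.hi)
        else:
            k = int(round(gate.fraction * n))
            match = np.zeros(n, dtype=bool)
            if k > 0:
                # stable ranking: ties broken by event order
                order = np.argsort(-values, kind="stable")
                match[order[:k]] = True
        take = match & unassigned
        assignment.iloc[np.flatnonzero(take)] = name
        unassigned &= ~take
    return assignment


def apply_recovery(
    population_ids: Sequence[int], recovery: float = 0.8, seed: int = 0
) -> list[int]:
    """Independent Bernoulli recovery of each sorted cell."""
    if not 0.0 <= recovery <= 1.0:
        raise ValueError("recovery must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 37]))
    ids = np.asarray(list(population_ids))
    keep = rng.random(len(ids)) < recovery
    return [int(x) for x in ids[keep]]


def precision(called_ids: Sequence[int], truth: Mapping[int, bool]) -> float:
    """Fraction of called (photoactivated, mCherry-positive) cells that are
    true positives: TP / (TP + FP).

    Raises :class:`NoPositivesError` when nothing was called positive and
    KeyError when a called cell has no truth entry.
    """
    called = list(called_ids)
    if len(called) == 0:
        raise NoPositivesError("no positives called; precision undefined")
    tp = 0
    for cid in called:
        if cid not in truth:
            raise KeyError(f"no truth entry for cell {cid}")
        tp += bool(truth[cid])
    return tp / len(called)


def sort_to_counts(
    sorted_sgrnas: Sequence[str],
    library_sgrnas: Sequence[str],
    depth: int = 1_000_000,
    seed: int = 0,
) -> pd.Series:
    """Sequencing counts for one sorted population.

    Reads are a multinomial draw of size ``depth`` over the sorted cells'
    sgRNA composition; the returned column is indexed by the full library
    and sums exactly to ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    cells = pd.Series(list(sorted_sgrnas))
    if len(cells) == 0:
        raise ValueError("empty sorted population")
    index = pd.Index(library_sgrnas, name="sgrna_id")
    comp = cells.value_counts().reindex(index, fill_value=0).to_numpy(dtype=float)
    if comp.sum() == 0:
        raise ValueError("sorted sgRNAs not present in library")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    counts = rng.multinomial(int(depth), comp / comp.sum())
    return pd.Series(counts, index=index, dtype=np.int64)
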