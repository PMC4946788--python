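"""Spike-train containers, text readers/writers and time binning.

Parallel spike data is represented as a :class:`SpikeTrainSet`: ``N`` ascending
per-neuron spike-time arrays on a common observation window ``[t_start,
t_stop)``.  Binning discretizes the window into ``B`` adjacent bins of equal
width; a neuron is *active* in a bin if it emits at least one spike there
(binary clipping), so that the per-bin neuron sets have well-defined
intersections.

Two plain-text dialects are supported:

* ``two-column``: one line ``<time_seconds> <neuron_id>`` per spike, ``#``
  comments allowed;
* ``rows``: line ``k`` holds the whitespace-separated spike times of neuron
  ``k`` (an empty line is a silent neuron).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpikeTrainSet",
    "BinConfig",
    "BinnedSpikes",
    "read_spikes",
    "write_spikes",
    "bin_spike_trains",
]

logger = logging.getLogger(__name__)


@dataclass
class SpikeTrainSet:
    """``N`` parallel spike trains observed on ``[t_start, t_stop)``.

    Parameters
    ----------
    trains
        One ascending float array of spike times (seconds) per neuron.
    t_start, t_stop
        Observation window; every spike must satisfy
        ``t_start <= t < t_stop``.
    neuron_ids
        Integer labels, default ``0..N-1``.
    """

    trains: list
    t_start: float = 0.0
    t_stop: float = 1.0
    neuron_ids: list = field(default=None)

    def __post_init__(self):
        if len(self.trains) < 1:
            raise ValueError("need at least one spike train")
        if not self.t_stop > self.t_start:
            raise ValueError("t_stop must exceed t_start")
        self.trains = [np.asarray(t, dtype=float).ravel() for t in self.trains]
        for k, t in enumerate(self.trains):
            if t.size and np.any(np.diff(t) < 0):
                self.trains[k] = np.sort(t)
            t = self.trains[k]
            if t.size and (t[0] < self.t_start or t[-1] >= self.t_stop):
                bad = t[(t < self.t_start) | (t >= self.t_stop)]
                raise ValueError(
                    f"neuron {k}: {bad.size} spikes outside "
                    f"[{self.t_start}, {self.t_stop}): {bad[:5]}"
                )
        if self.neuron_ids is None:
            self.neuron_ids = list(range(len(self.trains)))
        elif len(self.neuron_ids) != len(self.trains):
            raise ValueError("neuron_ids length mismatch")

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))

    def rates(self) -> np.ndarray:
        """Mean firing rate of each neuron in Hz."""
        return np.array([t.size / self.duration for t in self.trains])


@dataclass(frozen=True)
class BinConfig:
    """Discretization of ``[t_start, t_start + n_bins*bin_width)``.

    Bin ``i`` covers the half-open interval
    ``[t_start + i*bin_width, t_start + (i+1)*bin_width)``.
    """

    bin_width: float
    n_bins: int
    t_start: float = 0.0

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.n_bins < 1:
            raise ValueError("need at least one bin")

    @classmethod
    def from_interval(cls, t_start: float, t_stop: float, bin_width: float) -> "BinConfig":
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if bin_width > t_stop - t_start:
            raise ValueError("bin_width exceeds the observation window")
        n_bins = int(math.floor((t_stop - t_start) / bin_width + 1e-9))
        remainder = (t_stop - t_start) - n_bins * bin_width
        if remainder > 1e-9 * max(1.0, bin_width):
            logger.warning(
                "observation window not divisible by bin width; "
                "discarding trailing %.3g s", remainder,
            )
        return cls(bin_width=bin_width, n_bins=n_bins, t_start=t_start)

    @property
    def t_stop(self) -> float:
        return self.t_start + self.n_bins * self.bin_width

    def centers(self) -> np.ndarray:
        return self.t_start + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def edges(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_bins + 1) * self.bin_width

    def bin_of(self, times: np.ndarray) -> np.ndarray:
        """Bin index of each time under the half-open convention (-1 = outside)."""
        idx = np.floor((np.asarray(times, float) - self.t_start) / self.bin_width).astype(int)
        idx[(idx < 0) | (idx >= self.n_bins)] = -1
        return idx


@dataclass
class BinnedSpikes:
    """Boolean neuron-by-bin occupancy table.

    ``occupancy[k, i]`` is True iff neuron ``k`` spikes at least once in bin
    ``i``; a neuron spiking several times in one bin counts once.
    """

    occupancy: np.ndarray
    config: BinConfig

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 2:
            raise ValueError("occupancy must be 2-D (neurons x bins)")
        if self.occupancy.shape[1] != self.config.n_bins:
            raise ValueError("occupancy column count differs from n_bins")

    @property
    def n_neurons(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_bins(self) -> int:
        return self.occupancy.shape[1]

    @property
    def population_histogram(self) -> np.ndarray:
        """Number of active neurons per bin, ``|S_i|``."""
        return self.occupancy.sum(axis=0).astype(int)

    def bin_set(self, i: int) -> frozenset:
        """Set ``S_i`` of neuron indices active in bin ``i``."""
        return frozenset(np.flatnonzero(self.occupancy[:, i]).tolist())

    def bin_sets(self) -> list:
        return [self.bin_set(i) for i in range(self.n_bins)]


def bin_spike_trains(spikes: SpikeTrainSet, bin_width: float) -> BinnedSpikes:
    """Discretize a spike-train set into binary occupancy on equal bins.

    The trailing remainder of the window (if the duration is not an integer
    multiple of ``bin_width``) is discarded with a warning.
    """
    config = BinConfig.from_interval(spikes.t_start, spikes.t_stop, bin_width)
    occ = np.zeros((spikes.n_neurons, config.n_bins), dtype=bool)
    for k, train in enumerate(spikes.trains):
        idx = config.bin_of(train)
        occ[k, idx[idx >= 0]] = True
    return BinnedSpikes(occupancy=occ, config=config)


def read_spikes(
    path,
    dialect: str = "two-column",
    t_start: float = 0.0,
    t_stop: float = 1.0,
    n_neurons: int | None = None,
) -> SpikeTrainSet:
    """Read parallel spike trains from a plain-text file.

    Parameters
    ----------
    dialect
        ``"two-column"`` (``time id`` per line) or ``"rows"`` (line ``k`` =
        spike times of neuron ``k``).
    n_neurons
        Declared neuron count; silent neurons are retained as empty trains.
        Required for the two-column dialect if trailing neurons are silent.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "two-column":
        spikes_by_id: dict[int, list] = {}
        max_id = -1
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'time neuron_id', got {line!r}")
            try:
                t = float(parts[0])
                k = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable line {line!r}") from exc
            if not math.isfinite(t):
                raise ValueError(f"{path}:{lineno}: non-finite spike time")
            spikes_by_id.setdefault(k, []).append(t)
            max_id = max(max_id, k)
        n = n_neurons if n_neurons is not None else max_id + 1
        n = max(n, 1)
        trains = [np.sort(np.asarray(spikes_by_id.get(k, []), float)) for k in range(n)]
    elif dialect == "rows":
        lines = text.splitlines()
        trains = []
        for lineno, line in enumerate(lines, start=1):
            line = line.split("#", 1)[0]
            try:
                vals = np.asarray([float(v) for v in line.split()], float)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable spike time") from exc
            if vals.size and not np.all(np.isfinite(vals)):
                raise ValueError(f"{path}:{lineno}: non-finite spike time")
            trains.append(np.sort(vals))
        if n_neurons is not None:
            while len(trains) < n_neurons:
                trains.append(np.array([]))
        if not trains:
            trains = [np.array([])]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    bad = [
        (k, t[(t < t_start) | (t >= t_stop)])
        for k, t in enumerate(trains)
        if t.size and (t[0] < t_start or t[-1] >= t_stop)
    ]
    bad = [(k, b) for k, b in bad if b.size]
    if bad:
        desc = "; ".join(f"neuron {k}: {b[:3]}" for k, b in bad[:5])
        raise ValueError(f"spikes outside [{t_start}, {t_stop}): {desc}")
    return SpikeTrainSet(trains=trains, t_start=t_start, t_stop=t_stop)


def write_spikes(spikes: SpikeTrainSet, path, dialect: str = "two-column") -> None:
    """Write a spike-train set in one of the supported text dialects."""
    path = Path(path)
    lines = []
    if dialect == "two-column":
        events = [
            (t, k) for k, train in enumerate(spikes.trains) for t in train
        ]
        events.sort()
        lines = [f"{t:.9g} {k}" for t, k in events]
    elif dialect == "rows":
        lines = [" ".join(f"{t:.9g}" for t in train) for train in spikes.trains]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def write_matrix(matrix: np.ndarray, path, kind: str, bin_width: float) -> None:
    """Export a bin-by-bin matrix as tab-delimited text with a header line."""
    header = f"kind={kind} bin_width={bin_width:g}"
    np.savetxt(path, np.asarray(matrix), fmt="%.10g", delimiter="\t", header=header)


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")
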