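"""Data model and file I/O for fluorescence traces and spike-call tables.

The canonical exchange format is a long (tidy) CSV with one row per frame
per cell per channel::

    time_s,plant_id,cell_id,channel,intensity,position_um

``channel`` is ``nuclear`` or ``cytosolic``; ``position_um`` (axial distance
of the cell from the root tip, micrometres) is optional and may be blank.
Wide per-cell layouts are deliberately not supported: keeping the channel as
an explicit column avoids ambiguity when a cell is recorded in both the
nuclear and the cytosolic channel of a dual-localised sensor.

Time is carried explicitly in seconds because acquisition alternates between
2 s and 3 s frame intervals across recordings.  Frame indices are internal
only.  Non-uniform sampling (beyond a relative tolerance) is rejected rather
than resampled, because resampling would silently change finite-difference
gradient estimates downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from caspike.spike_core import SpikeCall

CHANNELS = ("nuclear", "cytosolic")

#: Column order of the trace CSV dialect ``long_csv``.
TRACE_COLUMNS = ("time_s", "plant_id", "cell_id", "channel", "intensity")

#: Column order of the spike-call CSV.
SPIKE_CALL_COLUMNS = (
    "plant_id",
    "cell_id",
    "channel",
    "t_on_s",
    "t_peak_s",
    "t_off_s",
    "rise_s",
    "fall_s",
    "duration_s",
    "amplitude_dff",
    "censored",
)


class TraceFormatError(ValueError):
    """A trace file does not conform to the expected CSV schema."""


class TraceValidationError(ValueError):
    """Trace contents violate a model invariant (ordering, uniqueness...)."""


@dataclass(frozen=True)
class FluorescenceTrace:
    """One cell/channel raw fluorescence series on a uniform sampling grid.

    Parameters
    ----------
    plant_id, cell_id
        Free-text labels identifying the plant and the cell within it.
    channel
        ``"nuclear"`` or ``"cytosolic"``.
    times
        Seconds from the start of the recording, strictly increasing.
    intensities
        Raw fluorescence in arbitrary units, non-negative, same length as
        ``times``.
    frame_interval
        Nominal sampling interval in seconds (> 0).
    position_um
        Optional axial distance of the cell from the root tip, micrometres.
    """

    plant_id: str
    cell_id: str
    channel: str
    times: np.ndarray
    intensities: np.ndarray
    frame_interval: float
    position_um: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        intensities = np.asarray(self.intensities, dtype=np.float64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        if self.channel not in CHANNELS:
            raise TraceValidationError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}"
            )
        if times.ndim != 1 or intensities.ndim != 1:
            raise TraceValidationError("times and intensities must be 1-D")
        if times.size != intensities.size:
            raise TraceValidationError(
                f"times ({times.size}) and intensities ({intensities.size}) "
                "differ in length"
            )
        if times.size == 0:
            raise TraceValidationError("empty trace")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise TraceValidationError(
                f"times not strictly increasing for {self.key}"
            )
        if np.any(intensities < 0):
            raise TraceValidationError(f"negative intensity in {self.key}")
        if not self.frame_interval > 0:
            raise TraceValidationError("frame_interval must be > 0")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.plant_id, self.cell_id, self.channel)

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class SamplingReport:
    """Report of :func:`validate_sampling`; empty ``flagged`` means pass."""

    flagged: tuple[int, ...]
    warning: str | None = None

    @property
    def passed(self) -> bool:
        return not self.flagged


def validate_sampling(
    trace: FluorescenceTrace, rel_tol: float = 0.01
) -> SamplingReport:
    """Check that successive time steps match the nominal frame interval.

    Returns a report listing the indices ``i`` for which the step
    ``times[i+1] - times[i]`` deviates from ``frame_interval`` by more than
    ``rel_tol`` (relative).  A single-frame trace passes with a warning,
    because uniformity is vacuous there.
    """
    if trace.n_frames < 2:
        return SamplingReport(flagged=(), warning="single-frame trace; sampling uniformity not checkable")
    steps = np.diff(trace.times)
    bad = np.abs(steps - trace.frame_interval) > rel_tol * trace.frame_interval
    return SamplingReport(flagged=tuple(int(i) for i in np.nonzero(bad)[0]))


@dataclass(frozen=True)
class TraceCollection:
    """A set of traces keyed by ``(plant_id, cell_id, channel)``."""

    traces: Mapping[tuple[str, str, str], FluorescenceTrace]
    recording_duration_s: float

    def __post_init__(self) -> None:
        for key, trace in self.traces.items():
            if key != trace.key:
                raise TraceValidationError(f"key {key} does not match trace {trace.key}")
        if self.traces:
            max_t = max(float(t.times[-1]) for t in self.traces.values())
            if self.recording_duration_s < max_t:
                raise TraceValidationError(
                    "recording_duration_s shorter than the longest trace"
                )

    @classmethod
    def from_traces(cls, traces: Iterator[FluorescenceTrace] | list[FluorescenceTrace]) -> "TraceCollection":
        mapping: dict[tuple[str, str, str], FluorescenceTrace] = {}
        for trace in traces:
            if trace.key in mapping:
                raise TraceValidationError(f"duplicate trace key {trace.key}")
            mapping[trace.key] = trace
        duration = max((float(t.times[-1]) for t in mapping.values()), default=0.0)
        return cls(traces=mapping, recording_duration_s=duration)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[FluorescenceTrace]:
        return iter(self.traces.values())

    def __getitem__(self, key: tuple[str, str, str]) -> FluorescenceTrace:
        return self.traces[key]

    def positions(self) -> dict[tuple[str, str], float]:
        """Map ``(plant_id, cell_id)`` to axial position where known."""
        out: dict[tuple[str, str], float] = {}
        for trace in self:
            if trace.position_um is not None:
                out[(trace.plant_id, trace.cell_id)] = float(trace.position_um)
        return out


@dataclass(frozen=True)
class SpikeRecord:
    """One spike call together with its originating trace key."""

    plant_id: str
    cell_id: str
    channel: str
    call: "SpikeCall"

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.plant_id, self.cell_id, self.channel)


@dataclass(frozen=True)
class SpikeCallTable:
    """A flat table of spike calls keyed by plant, cell and channel."""

    records: tuple[SpikeRecord, ...]

    @classmethod
    def from_records(cls, records) -> "SpikeCallTable":
        return cls(records=tuple(records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpikeRecord]:
        return iter(self.records)

    def filter(self, **criteria) -> "SpikeCallTable":
        """Subset by equality on ``plant_id``, ``cell_id`` or ``channel``."""
        kept = [
            r
            for r in self.records
            if all(getattr(r, name) == value for name, value in criteria.items())
        ]
        return SpikeCallTable(records=tuple(kept))

    def uncensored(self) -> "SpikeCallTable":
        return SpikeCallTable(
            records=tuple(r for r in self.records if not r.call.censored)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            c = rec.call
            rows.append(
                {
                    "plant_id": rec.plant_id,
                    "cell_id": rec.cell_id,
                    "channel": rec.channel,
                    "t_on_s": c.t_on,
                    "t_peak_s": c.t_peak,
                    "t_off_s": c.t_off,
                    "rise_s": c.rise_s,
                    "fall_s": c.fall_s,
                    "duration_s": c.duration_s,
                    "amplitude_dff": c.amplitude_dff,
                    "censored": c.censored,
                }
            )
        return pd.DataFrame(rows, columns=list(SPIKE_CALL_COLUMNS))


def read_traces(
    path: str | Path, dialect: str = "long_csv", rel_tol: float = 0.01
) -> TraceCollection:
    """Read a long-format trace CSV into a :class:`TraceCollection`.

    One :class:`FluorescenceTrace` is built per ``(plant, cell, channel)``
    group, sorted by time.  The nominal frame interval of each trace is
    inferred as the median of its successive time differences and the grid is
    then validated against that interval with relative tolerance ``rel_tol``.
    """
    if dialect != "long_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    frame = pd.read_csv(path)
    for column in TRACE_COLUMNS:
        if column not in frame.columns:
            raise TraceFormatError(f"missing required column {column!r} in {path}")
    has_position = "position_um" in frame.columns

    unknown = set(frame["channel"].unique()) - set(CHANNELS)
    if unknown:
        raise TraceValidationError(
            f"unknown channel label(s) {sorted(unknown)}; expected {CHANNELS}"
        )

    traces: list[FluorescenceTrace] = []
    for key, group in frame.groupby(["plant_id", "cell_id", "channel"], sort=True):
        group = group.sort_values("time_s")
        times = group["time_s"].to_numpy(dtype=np.float64)
        if np.any(np.diff(times) == 0):
            raise TraceValidationError(f"duplicated time point in group {key}")
        if np.any(np.diff(times) < 0):  # unreachable after sort; defensive
            raise TraceValidationError(f"non-monotone times in group {key}")
        if times.size < 2:
            raise TraceValidationError(
                f"group {key} has fewer than 2 frames; cannot infer frame interval"
            )
        interval = float(np.median(np.diff(times)))
        position: float | None = None
        if has_position:
            values = group["position_um"].dropna()
            if len(values):
                position = float(values.iloc[0])
        trace = FluorescenceTrace(
            plant_id=str(key[0]),
            cell_id=str(key[1]),
            channel=str(key[2]),
            times=times,
            intensities=group["intensity"].to_numpy(dtype=np.float64),
            frame_interval=interval,
            position_um=position,
        )
        report = validate_sampling(trace, rel_tol=rel_tol)
        if not report.passed:
            raise TraceValidationError(
                f"non-uniform sampling in group {key}: steps at indices "
                f"{list(report.flagged)} deviate from {interval} s by more than "
                f"{rel_tol:.1%}"
            )
        traces.append(trace)
    return TraceCollection.from_traces(traces)


def write_traces(collection: TraceCollection, path: str | Path) -> Path:
    """Write a collection to the long CSV dialect (inverse of read_traces)."""
    path = Path(path)
    rows = []
    for trace in collection:
        for t, f in zip(trace.times, trace.intensities):
            rows.append(
                {
                    "time_s": t,
                    "plant_id": trace.plant_id,
                    "cell_id": trace.cell_id,
                    "channel": trace.channel,
                    "intensity": f,
                    "position_um": trace.position_um,
                }
            )
    frame = pd.DataFrame(rows, columns=list(TRACE_COLUMNS) + ["position_um"])
    frame.to_csv(path, index=False)
    return path


def write_spike_calls(table: SpikeCallTable, path: str | Path) -> Path:
    """Write spike calls to CSV; reading the file back yields an equal table."""
    path = Path(path)
    table.to_frame().to_csv(path, index=False)
    return path


def read_spike_calls(path: str | Path) -> SpikeCallTable:
    """Read a spike-call CSV written by :func:`write_spike_calls`."""
    from caspike.spike_core import SpikeCall  # deferred: avoids import cycle

    path = Path(path)
    frame = pd.read_csv(path)
    for column in SPIKE_CALL_COLUMNS:
        if column not in frame.columns:
            raise TraceFormatError(f"missing required column {column!r} in {path}")
    records = []
    for row in frame.itertuples(index=False):
        call = SpikeCall(
            t_on=float(row.t_on_s),
            t_peak=float(row.t_peak_s),
            t_off=float(row.t_off_s),
            rise_s=float(row.rise_s),
            fall_s=float(row.fall_s),
            duration_s=float(row.duration_s),
            amplitude_dff=float(row.amplitude_dff),
            censored=bool(row.censored),
        )
        records.append(
            SpikeRecord(
                plant_id=str(row.plant_id),
                cell_id=str(row.cell_id),
                channel=str(row.channel),
                call=call,
            )
        )
    return SpikeCallTable.from_records(records)
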