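"""Per-plant and per-genotype aggregation of spike calls.

This module turns per-cell spike calls into the cohort statistics used to
compare genotypes: the fraction of plants showing at least one nuclear
spike ("responders"), the nuclear spike rate per plant-hour within a
reference meristem span (default 200 um from the root tip), the partition
of spikes between the meristem and elongation zones, arithmetic means and
standard deviations of rise/fall/duration, and the least-squares relation
between spike rate and primary-root growth rate.

Unless stated otherwise every statistic is computed over *accepted* nuclear
calls: uncensored calls from the nuclear channel.  Censored (edge-truncated)
spikes have unreliable shape and are excluded from shape means; hypothesis
testing on the resulting tables is out of scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from caspike.trace_model import SpikeCallTable

PLANT_META_COLUMNS = (
    "plant_id",
    "genotype",
    "imaging_duration_s",
    "boundary_um",
    "length_day3_cm",
    "length_day5_cm",
)


@dataclass(frozen=True)
class PlantSummary:
    """Spiking summary of a single plant."""

    plant_id: str
    genotype: str
    n_cells_observed: int
    n_spikes_in_span: int
    spikes_per_hour: float
    responder: bool
    meristem_count: int
    elongation_count: int


@dataclass(frozen=True)
class GrowthRecord:
    """Primary-root lengths at days 3 and 5 after germination, in cm."""

    plant_id: str
    length_day3_cm: float
    length_day5_cm: float

    def __post_init__(self) -> None:
        if self.length_day3_cm < 0 or self.length_day5_cm < 0:
            raise ValueError(f"negative root length for plant {self.plant_id}")

    @property
    def growth_rate_cm_per_day(self) -> float:
        return (self.length_day5_cm - self.length_day3_cm) / 2.0

    @property
    def suspect(self) -> bool:
        """Flag set when the root apparently shrank between measurements."""
        return self.length_day5_cm < self.length_day3_cm


@dataclass(frozen=True)
class ShapeStats:
    """Means and standard deviations of spike shape over uncensored calls.

    ``n == 0`` marks the empty result (all statistics NaN); ``n == 1`` gives
    zero dispersion, flagged by the caller if needed.
    """

    n: int
    mean_rise_s: float
    sd_rise_s: float
    mean_fall_s: float
    sd_fall_s: float
    mean_duration_s: float
    sd_duration_s: float


@dataclass(frozen=True)
class ZoneFractions:
    meristem_count: int
    elongation_count: int
    meristem_pct: float
    elongation_pct: float


@dataclass(frozen=True)
class GenotypeSummary:
    genotype: str
    n_plants: int
    responder_pct: float
    mean_spikes_per_hour: float
    sem_spikes_per_hour: float
    shape: ShapeStats
    zones: ZoneFractions | None


def _accepted_nuclear(calls: SpikeCallTable) -> SpikeCallTable:
    return calls.filter(channel="nuclear").uncensored()


def summarize_plant(
    calls: SpikeCallTable,
    plant_id: str,
    *,
    imaging_duration_s: float,
    positions: Mapping[str, float],
    span_um: float | None = 200.0,
    boundary_um: float | None = None,
    genotype: str = "",
    n_cells_observed: int | None = None,
    span_mode: str = "filter",
) -> PlantSummary:
    """Summarise one plant's accepted nuclear spike calls.

    ``positions`` maps ``cell_id`` to axial distance from the root tip (um).
    With ``span_mode="filter"`` (default) the spike count and rate include
    only cells within ``span_um`` of the tip, treating the span as a counting
    window; ``span_mode="rescale"`` counts every accepted call and rescales
    the rate by ``span_um`` over the observed positional extent instead.
    ``boundary_um`` (meristem/elongation boundary) enables the per-zone
    counts; a cell sitting exactly on the boundary counts as meristematic.
    """
    if imaging_duration_s <= 0:
        raise ValueError("imaging_duration_s must be > 0")
    if span_mode not in ("filter", "rescale"):
        raise ValueError("span_mode must be 'filter' or 'rescale'")
    accepted = _accepted_nuclear(calls.filter(plant_id=plant_id))
    hours = imaging_duration_s / 3600.0

    if span_um is not None or boundary_um is not None:
        missing = sorted({r.cell_id for r in accepted if r.cell_id not in positions})
        if missing:
            raise ValueError(
                f"plant {plant_id}: positional filtering requested but cells "
                f"{missing} have no position_um"
            )

    if span_um is None:
        n_in_span = len(accepted)
        rate = n_in_span / hours
    elif span_mode == "filter":
        n_in_span = sum(1 for r in accepted if positions[r.cell_id] <= span_um)
        rate = n_in_span / hours
    else:  # rescale
        n_in_span = len(accepted)
        extent = max(positions.values(), default=0.0)
        scale = span_um / extent if extent > span_um else 1.0
        rate = n_in_span * scale / hours

    meristem = elongation = 0
    if boundary_um is not None:
        for rec in accepted:
            if positions[rec.cell_id] <= boundary_um:
                meristem += 1
            else:
                elongation += 1
    return PlantSummary(
        plant_id=plant_id,
        genotype=genotype,
        n_cells_observed=n_cells_observed if n_cells_observed is not None else len(positions),
        n_spikes_in_span=n_in_span,
        spikes_per_hour=rate,
        responder=len(accepted) > 0,
        meristem_count=meristem,
        elongation_count=elongation,
    )


def responder_fraction(summaries: Sequence[PlantSummary]) -> float:
    """Percentage of plants with at least one accepted nuclear spike."""
    if not summaries:
        raise ValueError("responder_fraction of an empty cohort is undefined")
    return 100.0 * sum(s.responder for s in summaries) / len(summaries)


def partition_by_zone(
    calls: SpikeCallTable,
    positions: Mapping[tuple[str, str], float],
    boundary_um: float | Mapping[str, float],
) -> ZoneFractions:
    """Split accepted nuclear calls between meristem and elongation zones.

    ``positions`` maps ``(plant_id, cell_id)`` to axial position and
    ``boundary_um`` is a single boundary or a per-plant mapping.  A call at
    exactly the boundary is meristematic (inclusive rule, consistent with
    counting the last meristematic cell as part of the meristem).  The two
    percentages sum to 100 whenever at least one call exists.
    """
    accepted = _accepted_nuclear(calls)
    meristem = elongation = 0
    for rec in accepted:
        key = (rec.plant_id, rec.cell_id)
        if key not in positions:
            raise ValueError(f"call for cell {key} has no position_um")
        if isinstance(boundary_um, Mapping):
            if rec.plant_id not in boundary_um:
                raise ValueError(f"plant {rec.plant_id} has no meristem boundary")
            boundary = boundary_um[rec.plant_id]
        else:
            boundary = float(boundary_um)
        if positions[key] <= boundary:
            meristem += 1
        else:
            elongation += 1
    total = meristem + elongation
    if total == 0:
        return ZoneFractions(0, 0, float("nan"), float("nan"))
    return ZoneFractions(
        meristem_count=meristem,
        elongation_count=elongation,
        meristem_pct=100.0 * meristem / total,
        elongation_pct=100.0 * elongation / total,
    )


def shape_means(calls: SpikeCallTable) -> ShapeStats:
    """Arithmetic means/SDs of rise, fall and duration over uncensored calls.

    The mean duration equals the sum of the mean rise and fall computed over
    the same calls (linearity of the mean).  Returns an ``n == 0`` marker
    rather than raising when no uncensored call exists.
    """
    accepted = [r.call for r in calls.uncensored()]
    if not accepted:
        nan = float("nan")
        return ShapeStats(0, nan, nan, nan, nan, nan, nan)
    rise = np.array([c.rise_s for c in accepted])
    fall = np.array([c.fall_s for c in accepted])
    duration = np.array([c.duration_s for c in accepted])
    return ShapeStats(
        n=len(accepted),
        mean_rise_s=float(np.mean(rise)),
        sd_rise_s=float(np.std(rise, ddof=1)) if len(accepted) > 1 else 0.0,
        mean_fall_s=float(np.mean(fall)),
        sd_fall_s=float(np.std(fall, ddof=1)) if len(accepted) > 1 else 0.0,
        mean_duration_s=float(np.mean(duration)),
        sd_duration_s=float(np.std(duration, ddof=1)) if len(accepted) > 1 else 0.0,
    )


def correlate_growth_spiking(
    growth: Sequence[GrowthRecord], summaries: Sequence[PlantSummary]
) -> tuple[float, float]:
    """OLS line of growth rate (cm/day) against spike rate (per hour).

    All plants having both measurements enter the fit; no outlier removal.
    Returns ``(slope, intercept)``.
    """
    by_plant = {g.plant_id: g for g in growth}
    x, y = [], []
    for s in summaries:
        if s.plant_id in by_plant:
            x.append(s.spikes_per_hour)
            y.append(by_plant[s.plant_id].growth_rate_cm_per_day)
    if len(x) < 2:
        raise ValueError(f"need >= 2 matched plants for a line fit, got {len(x)}")
    x_arr = np.asarray(x)
    y_arr = np.asarray(y)
    if np.ptp(x_arr) == 0:
        raise ValueError("zero variance in spike rate; slope undefined")
    slope, intercept = np.polyfit(x_arr, y_arr, deg=1)
    return float(slope), float(intercept)


def summarize_genotype(
    genotype: str,
    summaries: Sequence[PlantSummary],
    calls: SpikeCallTable,
    zones: ZoneFractions | None = None,
) -> GenotypeSummary:
    """Aggregate plant summaries of one genotype for cross-genotype tables."""
    members = [s for s in summaries if s.genotype == genotype]
    if not members:
        raise ValueError(f"no plants with genotype {genotype!r}")
    rates = np.array([s.spikes_per_hour for s in members])
    sem = float(np.std(rates, ddof=1) / math.sqrt(len(rates))) if len(rates) > 1 else 0.0
    plant_ids = {s.plant_id for s in members}
    geno_calls = SpikeCallTable.from_records(
        [r for r in calls if r.plant_id in plant_ids and r.channel == "nuclear"]
    )
    return GenotypeSummary(
        genotype=genotype,
        n_plants=len(members),
        responder_pct=responder_fraction(members),
        mean_spikes_per_hour=float(np.mean(rates)),
        sem_spikes_per_hour=sem,
        shape=shape_means(geno_calls),
        zones=zones,
    )


def read_plant_metadata(path: str | Path) -> pd.DataFrame:
    """Read the plant metadata CSV (plant_id, genotype, imaging_duration_s,
    boundary_um, length_day3_cm, length_day5_cm)."""
    frame = pd.read_csv(path)
    missing = [c for c in ("plant_id", "imaging_duration_s") if c not in frame.columns]
    if missing:
        raise ValueError(f"plant metadata missing column(s) {missing}")
    frame["plant_id"] = frame["plant_id"].astype(str)
    return frame


def summaries_frame(summaries: Sequence[PlantSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plant_id": s.plant_id,
                "genotype": s.genotype,
                "n_cells_observed": s.n_cells_observed,
                "n_spikes_in_span": s.n_spikes_in_span,
                "spikes_per_hour": s.spikes_per_hour,
                "responder": s.responder,
                "meristem_count": s.meristem_count,
                "elongation_count": s.elongation_count,
            }
            for s in summaries
        ]
    )
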