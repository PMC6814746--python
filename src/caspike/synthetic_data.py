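"""Seeded simulator of fluorescence recordings with exact ground truth.

The generator emulates what confocal time-lapse recordings of root-tip
cells expressing a dual-localised calcium sensor look like to the analysis
pipeline: frames every 2-3 s over ~1.5 h, a slow polynomial baseline drift
(photobleaching/focus creep), additive sensor noise, and at most one
asymmetric Ca2+ transient per responding cell, with the nuclear channel
leading the cytosolic one.  Cohorts add plant-level structure: a responder
probability per plant, a Poisson number of spiking cells per responder
plant-hour, and an expected 80/20 split of spiking cells between the
meristem and elongation zones.

Raw fluorescence is built as::

    F(t) = f0 * (1 + drift(t) + sum_k kernel_k(t)) + noise(t)

with ``drift`` a polynomial in normalised time t/duration and each kernel
expressed in dF/F units.  The default *tent* kernel is piecewise linear
(0 -> amplitude over the rise, back to 0 over the fall), so its onset, peak
and end are analytically exact ground truth for boundary-recovery tests.
A double-exponential kernel is available for more realistic rounded shapes;
because its support is infinite, its ground-truth onset and offset are
defined as the crossings of 5% of the peak amplitude.

Everything is driven by ``numpy`` ``SeedSequence`` spawning, so a fixed
seed reproduces every output bitwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from caspike.cohort import PLANT_META_COLUMNS
from caspike.trace_model import FluorescenceTrace, TraceCollection, write_traces

GENOTYPE_PRESETS = ("wildtype", "low_frequency", "slow_kinetics", "custom")

TRUTH_COLUMNS = (
    "plant_id",
    "cell_id",
    "channel",
    "true_t_on",
    "true_t_peak",
    "true_t_off",
    "true_amplitude_dff",
    "position_um",
    "zone",
)


@dataclass(frozen=True)
class SpikeSpec:
    """Injected spike: onset (s), rise (s), fall (s), peak amplitude (dF/F)."""

    t_on: float
    rise_s: float
    fall_s: float
    amplitude_dff: float

    def __post_init__(self) -> None:
        if self.rise_s <= 0 or self.fall_s <= 0 or self.amplitude_dff <= 0:
            raise ValueError("rise, fall and amplitude must be > 0")

    @property
    def t_peak(self) -> float:
        return self.t_on + self.rise_s

    @property
    def t_off(self) -> float:
        return self.t_on + self.rise_s + self.fall_s


@dataclass(frozen=True)
class SpikeGroundTruth:
    """Simulator-emitted true spike parameters, the oracle for recovery tests."""

    plant_id: str
    cell_id: str
    channel: str
    true_t_on: float
    true_t_peak: float
    true_t_off: float
    true_amplitude_dff: float
    position_um: float | None = None
    zone: str | None = None

    def __post_init__(self) -> None:
        if not (self.true_t_on < self.true_t_peak < self.true_t_off):
            raise ValueError("ground-truth boundaries must be strictly ordered")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated recordings.

    Defaults encode the recording statistics of the emulated experiments:
    2 s frames over 5400 s (1.5 h); wild-type kinetics with mean rise
    15.4 s and mean fall 24.1 s; peak amplitude 0.5 dF/F with additive
    noise at one fifth of the peak (SNR 5 in dF/F units); the cytosolic
    channel lagging the nucleus by two frames; about five spiking cells per
    responder plant-hour; and 80% of spiking cells in the meristem.  The
    dispersions of the kinetic parameters and the mutant presets encode
    plausible magnitudes/directions only (frequency reduced; kinetics
    slowed) and are not measured quantities.
    """

    seed: int = 0
    frame_interval_s: float = 2.0
    duration_s: float = 5400.0
    f0_level: float = 100.0
    drift_coeffs: tuple[float, ...] = (0.0, -0.06, 0.025, -0.015)
    noise_sigma: float = 10.0
    noise_model: str = "gaussian"  # "gaussian" | "poisson"
    kernel: str = "tent"  # "tent" | "double_exponential"
    rise_mean_s: float = 15.4
    rise_sd_s: float = 4.0
    fall_mean_s: float = 24.1
    fall_sd_s: float = 6.0
    amplitude_dff: float = 0.5
    cyto_amplitude_scale: float = 0.8
    nuclear_cyto_lag_s: float = 4.0
    n_plants: int = 20
    cells_per_plant: int = 20
    responder_prob: float = 0.6
    spikes_per_responder_rate: float = 5.0  # spiking cells per responder hour
    meristem_fraction: float = 0.8
    boundary_um: float = 200.0
    elongation_extent_um: float = 300.0
    genotype_preset: str = "wildtype"

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0 or self.duration_s <= 0 or self.f0_level <= 0:
            raise ValueError("frame interval, duration and f0_level must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for p in (self.responder_prob, self.meristem_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.nuclear_cyto_lag_s < 0:
            raise ValueError("nuclear_cyto_lag_s must be >= 0 (nucleus leads)")
        if self.kernel not in ("tent", "double_exponential"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.genotype_preset not in GENOTYPE_PRESETS:
            raise ValueError(f"unknown genotype preset {self.genotype_preset!r}")

    @classmethod
    def preset(cls, genotype: str, **overrides) -> "SimulationConfig":
        """Build a config from a named genotype preset.

        ``low_frequency`` models an overexpressor-like phenotype (fewer
        responding plants, fewer spiking cells per hour); ``slow_kinetics``
        a knockdown-like phenotype (longer rise and fall).  The multipliers
        are illustrative, not measured.
        """
        base: dict = {"genotype_preset": genotype}
        if genotype == "wildtype":
            pass
        elif genotype == "low_frequency":
            base.update(responder_prob=0.25, spikes_per_responder_rate=2.0)
        elif genotype == "slow_kinetics":
            base.update(
                rise_mean_s=15.4 * 1.6,
                fall_mean_s=24.1 * 1.6,
                rise_sd_s=4.0 * 1.6,
                fall_sd_s=6.0 * 1.6,
            )
        elif genotype == "custom":
            pass
        else:  # pragma: no cover - guarded by __post_init__
            raise ValueError(genotype)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class CohortSimulation:
    """Output bundle of :func:`simulate_cohort`."""

    collection: TraceCollection
    truth: pd.DataFrame
    plants: pd.DataFrame

    def truth_records(self) -> list[SpikeGroundTruth]:
        out = []
        for row in self.truth.itertuples(index=False):
            out.append(
                SpikeGroundTruth(
                    plant_id=str(row.plant_id),
                    cell_id=str(row.cell_id),
                    channel=str(row.channel),
                    true_t_on=float(row.true_t_on),
                    true_t_peak=float(row.true_t_peak),
                    true_t_off=float(row.true_t_off),
                    true_amplitude_dff=float(row.true_amplitude_dff),
                    position_um=float(row.position_um),
                    zone=str(row.zone),
                )
            )
        return out


def _time_grid(config: SimulationConfig) -> np.ndarray:
    n = int(np.floor(config.duration_s / config.frame_interval_s)) + 1
    return np.arange(n, dtype=np.float64) * config.frame_interval_s


def _tent(times: np.ndarray, spike: SpikeSpec) -> np.ndarray:
    up = np.clip((times - spike.t_on) / spike.rise_s, 0.0, 1.0)
    down = np.clip((spike.t_off - times) / spike.fall_s, 0.0, 1.0)
    return spike.amplitude_dff * np.minimum(up, down)


def _double_exponential(times: np.ndarray, spike: SpikeSpec) -> tuple[np.ndarray, float, float]:
    """Rounded kernel with 5%-of-amplitude ground-truth boundaries.

    Shape ``exp(-t/tau_d) - exp(-t/tau_r)`` from a start point chosen so the
    analytic peak lands ``rise_s`` after the 5% onset crossing; time
    constants are matched to the requested rise/fall scales.
    """
    tau_r = spike.rise_s / 3.0
    tau_d = spike.fall_s / 1.5
    t_pk_rel = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    # Dense evaluation to locate the 5% crossings of the normalised shape.
    dense_t = np.linspace(0.0, t_pk_rel + 12.0 * tau_d, 4000)
    shape = np.exp(-dense_t / tau_d) - np.exp(-dense_t / tau_r)
    shape /= shape.max()
    above = np.nonzero(shape >= 0.05)[0]
    on_rel, off_rel = dense_t[above[0]], dense_t[above[-1]]
    # Anchor the 5% onset at spike.t_on.
    t0 = spike.t_on - on_rel
    rel = np.maximum(times - t0, 0.0)
    values = np.exp(-rel / tau_d) - np.exp(-rel / tau_r)
    values = np.where(times >= t0, values, 0.0)
    peak = np.exp(-t_pk_rel / tau_d) - np.exp(-t_pk_rel / tau_r)
    values = spike.amplitude_dff * values / peak
    return values, t0 + t_pk_rel, t0 + off_rel


def simulate_trace(
    config: SimulationConfig,
    spikes: Sequence[SpikeSpec] = (),
    *,
    plant_id: str = "plant01",
    cell_id: str = "cell01",
    channel: str = "nuclear",
    position_um: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[FluorescenceTrace, list[SpikeGroundTruth]]:
    """Simulate one raw trace with the given injected spikes.

    Tent spikes must have non-overlapping supports and lie within the
    recording; the returned ground truth carries their exact analytic
    boundaries (5%-amplitude crossings for the double-exponential kernel).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    times = _time_grid(config)
    for spike in spikes:
        if spike.t_on < 0 or spike.t_off > config.duration_s:
            raise ValueError(f"spike {spike} extends outside [0, {config.duration_s}] s")
    if config.kernel == "tent":
        intervals = sorted((s.t_on, s.t_off) for s in spikes)
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            if b0 < a1:
                raise ValueError("overlapping tent spikes are not supported")

    rel = np.zeros_like(times)
    if config.drift_coeffs:
        rel += np.polynomial.polynomial.polyval(
            times / config.duration_s, np.asarray(config.drift_coeffs, dtype=float)
        )
    truth: list[SpikeGroundTruth] = []
    for spike in spikes:
        if config.kernel == "tent":
            rel += _tent(times, spike)
            t_peak, t_off = spike.t_peak, spike.t_off
        else:
            values, t_peak, t_off = _double_exponential(times, spike)
            rel += values
        truth.append(
            SpikeGroundTruth(
                plant_id=plant_id,
                cell_id=cell_id,
                channel=channel,
                true_t_on=spike.t_on,
                true_t_peak=t_peak,
                true_t_off=t_off,
                true_amplitude_dff=spike.amplitude_dff,
                position_um=position_um,
            )
        )
    clean = config.f0_level * (1.0 + rel)
    if config.noise_model == "gaussian":
        raw = clean + config.noise_sigma * rng.standard_normal(times.size)
    else:
        # Shot-noise mode: photon counts proportional to the clean signal,
        # scaled so the baseline standard deviation matches noise_sigma.
        gain = config.noise_sigma**2 / config.f0_level if config.noise_sigma > 0 else 0.0
        if gain > 0:
            raw = gain * rng.poisson(np.maximum(clean, 0.0) / gain).astype(np.float64)
        else:
            raw = clean
    raw = np.maximum(raw, 0.0)
    trace = FluorescenceTrace(
        plant_id=plant_id,
        cell_id=cell_id,
        channel=channel,
        times=times,
        intensities=raw,
        frame_interval=config.frame_interval_s,
        position_um=position_um,
    )
    return trace, truth


def _draw_kinetics(config: SimulationConfig, rng: np.random.Generator) -> tuple[float, float]:
    """Truncated-normal rise and fall times (at least two frames each)."""
    lo = 2.0 * config.frame_interval_s
    for _ in range(1000):
        rise = rng.normal(config.rise_mean_s, config.rise_sd_s)
        fall = rng.normal(config.fall_mean_s, config.fall_sd_s)
        if rise >= lo and fall >= lo:
            return float(rise), float(fall)
    raise RuntimeError("could not draw valid kinetics; check config dispersions")


def simulate_cell_pair(
    config: SimulationConfig,
    *,
    plant_id: str = "plant01",
    cell_id: str = "cell01",
    position_um: float | None = None,
    t_on: float | None = None,
    rise_s: float | None = None,
    fall_s: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[FluorescenceTrace, FluorescenceTrace, list[SpikeGroundTruth]]:
    """Simulate the nuclear and cytosolic traces of one spiking cell.

    The cytosolic spike starts ``nuclear_cyto_lag_s`` after the nuclear one
    (the nucleus leads) with the same kinetics and a scaled amplitude.
    Returns ``(nuclear_trace, cytosolic_trace, ground_truth)``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if rise_s is None or fall_s is None:
        rise_s, fall_s = _draw_kinetics(config, rng)
    width = rise_s + fall_s
    margin = 0.05 * config.duration_s
    if t_on is None:
        latest = config.duration_s - margin - width - config.nuclear_cyto_lag_s
        if latest <= margin:
            raise ValueError("recording too short for the configured spike width")
        t_on = float(rng.uniform(margin, latest))
    nuclear_spike = SpikeSpec(t_on, rise_s, fall_s, config.amplitude_dff)
    cyto_spike = SpikeSpec(
        t_on + config.nuclear_cyto_lag_s,
        rise_s,
        fall_s,
        config.amplitude_dff * config.cyto_amplitude_scale,
    )
    nuc_trace, nuc_truth = simulate_trace(
        config,
        [nuclear_spike],
        plant_id=plant_id,
        cell_id=cell_id,
        channel="nuclear",
        position_um=position_um,
        rng=rng,
    )
    cyt_trace, cyt_truth = simulate_trace(
        config,
        [cyto_spike],
        plant_id=plant_id,
        cell_id=cell_id,
        channel="cytosolic",
        position_um=position_um,
        rng=rng,
    )
    return nuc_trace, cyt_trace, nuc_truth + cyt_truth


def _draw_position(config: SimulationConfig, rng: np.random.Generator) -> tuple[float, str]:
    if rng.random() < config.meristem_fraction:
        return float(rng.uniform(5.0, config.boundary_um)), "meristem"
    return (
        float(rng.uniform(config.boundary_um, config.boundary_um + config.elongation_extent_um)),
        "elongation",
    )


def simulate_cohort(config: SimulationConfig) -> CohortSimulation:
    """Simulate a whole cohort of plants with full ground truth.

    Each plant is a responder with probability ``responder_prob``;
    responders receive a Poisson(``spikes_per_responder_rate`` x hours)
    number of spiking cells (capped at ``cells_per_plant``), each with one
    nuclear-leading spike.  Every observed cell (spiking or not) yields a
    nuclear and a cytosolic trace with drift and noise, and a position drawn
    so the expected meristem share of cells equals ``meristem_fraction``.
    Plant metadata includes a synthetic growth record whose rate increases
    with the plant's true spiking rate, for exercising the growth-vs-rate
    regression.
    """
    root = np.random.SeedSequence(config.seed)
    hours = config.duration_s / 3600.0
    traces: list[FluorescenceTrace] = []
    truth_rows: list[dict] = []
    plant_rows: list[dict] = []
    for p, plant_seed in enumerate(root.spawn(config.n_plants), start=1):
        rng = np.random.default_rng(plant_seed)
        plant_id = f"plant{p:03d}"
        responder = rng.random() < config.responder_prob
        n_spiking = 0
        if responder:
            n_spiking = min(
                int(rng.poisson(config.spikes_per_responder_rate * hours)),
                config.cells_per_plant,
            )
        spiking_cells = set(rng.choice(config.cells_per_plant, size=n_spiking, replace=False))
        for c in range(config.cells_per_plant):
            cell_id = f"cell{c + 1:03d}"
            position, zone = _draw_position(config, rng)
            if c in spiking_cells:
                nuc, cyt, truth = simulate_cell_pair(
                    config,
                    plant_id=plant_id,
                    cell_id=cell_id,
                    position_um=position,
                    rng=rng,
                )
                traces.extend([nuc, cyt])
                for gt in truth:
                    truth_rows.append(
                        {
                            "plant_id": gt.plant_id,
                            "cell_id": gt.cell_id,
                            "channel": gt.channel,
                            "true_t_on": gt.true_t_on,
                            "true_t_peak": gt.true_t_peak,
                            "true_t_off": gt.true_t_off,
                            "true_amplitude_dff": gt.true_amplitude_dff,
                            "position_um": position,
                            "zone": zone,
                        }
                    )
            else:
                for channel in ("nuclear", "cytosolic"):
                    trace, _ = simulate_trace(
                        config,
                        [],
                        plant_id=plant_id,
                        cell_id=cell_id,
                        channel=channel,
                        position_um=position,
                        rng=rng,
                    )
                    traces.append(trace)
        true_rate = n_spiking / hours
        growth_rate = 0.15 + 0.03 * true_rate + rng.normal(0.0, 0.02)
        length_day3 = max(float(rng.normal(1.0, 0.1)), 0.1)
        plant_rows.append(
            {
                "plant_id": plant_id,
                "genotype": config.genotype_preset,
                "imaging_duration_s": config.duration_s,
                "boundary_um": config.boundary_um,
                "length_day3_cm": length_day3,
                "length_day5_cm": length_day3 + 2.0 * max(growth_rate, 0.0),
            }
        )
    return CohortSimulation(
        collection=TraceCollection.from_traces(traces),
        truth=pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS)),
        plants=pd.DataFrame(plant_rows, columns=list(PLANT_META_COLUMNS)),
    )


def single_spike_benchmark(
    n_traces: int,
    seed: int,
    *,
    rise_range: tuple[float, float] = (10.0, 30.0),
    fall_range: tuple[float, float] = (10.0, 30.0),
    config: SimulationConfig | None = None,
) -> list[tuple[FluorescenceTrace, SpikeGroundTruth]]:
    """Benchmark set of single-spike tent traces for boundary recovery.

    Rise and fall are drawn uniformly from the given ranges; everything
    else (frame interval, drift, peak amplitude at five noise scales)
    follows the supplied or default :class:`SimulationConfig`.
    """
    base = config or SimulationConfig(seed=seed)
    root = np.random.SeedSequence(seed)
    out: list[tuple[FluorescenceTrace, SpikeGroundTruth]] = []
    for i, child in enumerate(root.spawn(n_traces), start=1):
        rng = np.random.default_rng(child)
        rise = float(rng.uniform(*rise_range))
        fall = float(rng.uniform(*fall_range))
        margin = 0.05 * base.duration_s
        t_on = float(rng.uniform(margin, base.duration_s - margin - rise - fall))
        spike = SpikeSpec(t_on, rise, fall, base.amplitude_dff)
        trace, truth = simulate_trace(
            base, [spike], plant_id="bench", cell_id=f"cell{i:04d}", rng=rng
        )
        out.append((trace, truth[0]))
    return out


def write_cohort(sim: CohortSimulation, out_dir: str | Path) -> dict[str, Path]:
    """Write traces.csv, truth.csv and plants.csv for a simulated cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": out_dir / "traces.csv",
        "truth": out_dir / "truth.csv",
        "plants": out_dir / "plants.csv",
    }
    write_traces(sim.collection, paths["traces"])
    sim.truth.to_csv(paths["truth"], index=False)
    sim.plants.to_csv(paths["plants"], index=False)
    return paths
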