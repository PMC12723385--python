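"""Surrogate motoneuron spike commands for the virtual tadpole.

Recorded fictive rhythms define the statistics; this module synthesises
spatiotemporal motoneuron firing tables matched to them.  A roster of 311
motoneurons per side spans 0.5-4.8 mm from the mid/hindbrain border (248
within the classical 0.5-3.0 mm backfill range plus a caudal extension at
a density falling from 4 to 2 cells per 100 um).  Struggling commands run
at 4 Hz with left/right bursts in anti-phase, caudorostral onset
propagation near +40 mm/s, rostrally-biased spike counts (mean 6.1 per
burst rostrally vs 1.9 caudally) and inter-spike intervals drawn by
inverse-transform sampling from an empirical ISI distribution truncated
at 13 ms.  Swimming commands fire one spike per neuron per 20 Hz cycle
propagating rostrocaudally at 130 mm/s; "reverse" variants negate the
position-delay map; the initial coil fires a fixed 15-spike burst on the
side opposite to stimulation with < 1 ms of longitudinal spread.

Propagation sign convention: positive = caudorostral, as everywhere in
this package.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "MotoneuronRoster",
    "CommandConfig",
    "SpikeTable",
    "DEFAULT_DENSITY",
    "build_roster",
    "default_isi_source",
    "ecdf_sample",
    "generate_struggle",
    "generate_swim",
    "generate_initial_coil",
    "generate_reverse",
    "generate",
    "struggle_config",
    "swim_config",
    "initial_coil_config",
    "measure_onset_speed",
    "measure_burst_frequency",
]

ROSTER_SPAN = (0.5, 4.8)    # mm from the mid/hindbrain border
BIN_WIDTH = 0.1             # mm (100 um)
ISI_MAX_MS = 13.0           # intervals above this belong to different bursts

# Per-100-um motoneuron counts, one side.  The rostral 25 bins (0.5-3.0 mm)
# sum to 248, matching backfill totals; the caudal extension (3.0-4.8 mm)
# falls from 4 to 2 cells per bin and adds 63, for 311 in total.  The
# rostral bin-by-bin profile is a synthetic digitization pinned to those
# totals.
DEFAULT_DENSITY: tuple[tuple[float, int], ...] = tuple(
    (round(0.5 + 0.1 * i, 1), c) for i, c in enumerate(
        [15, 15, 14, 14, 13, 12, 12, 12, 12, 11, 11, 10, 10, 10, 9,
         9, 8, 8, 8, 7, 6, 6, 6, 5, 5]          # 0.5-3.0 mm, sum 248
        + [4] * 10 + [3] * 7 + [2]              # 3.0-4.8 mm, sum 63
    )
)


@dataclass(frozen=True)
class MotoneuronRoster:
    """Per-side motoneuron ids and rostrocaudal soma positions (mm)."""

    positions: np.ndarray     # one side; both sides share the layout

    @property
    def n_per_side(self) -> int:
        return int(self.positions.size)

    def side_frame(self, side: str) -> pd.DataFrame:
        tag = side[0].upper()
        return pd.DataFrame({
            "neuron_id": [f"{tag}{i:03d}" for i in range(self.n_per_side)],
            "side": side,
            "position_mm": self.positions,
        })


def build_roster(density=DEFAULT_DENSITY) -> MotoneuronRoster:
    """Deterministic roster from a per-100-um count table.

    Each (bin_start_mm, count) entry places ``count`` somata evenly inside
    its 100 um bin.  Bins must lie within 0.5-4.8 mm.
    """
    positions = []
    for start, count in density:
        if start < ROSTER_SPAN[0] - 1e-9 or start + BIN_WIDTH > ROSTER_SPAN[1] + 1e-9:
            raise ValueError(f"density bin at {start} mm outside roster span")
        if count < 0:
            raise ValueError("bin counts must be non-negative")
        offs = (np.arange(count) + 0.5) / max(count, 1) * BIN_WIDTH
        positions.extend(start + offs[:count])
    return MotoneuronRoster(positions=np.asarray(positions, dtype=float))


def default_isi_source(region: str = "rostral", n: int = 2000) -> np.ndarray:
    """Synthetic stand-in for the recorded inter-spike-interval samples.

    Log-normal with median 5 ms (sigma 0.5 rostral, 0.6 caudal), truncated
    to (0, 13] ms by resampling; deterministic (fixed internal seed) so
    the packaged default is reproducible.  Swap in a measured sample via
    ``CommandConfig.isi_source_*`` when available.
    """
    sigma = {"rostral": 0.5, "caudal": 0.6}[region]
    rng = np.random.default_rng(20240 + (0 if region == "rostral" else 1))
    out = np.empty(0)
    while out.size < n:
        draw = rng.lognormal(mean=np.log(5.0), sigma=sigma, size=2 * n)
        out = np.concatenate([out, draw[(draw > 0) & (draw <= ISI_MAX_MS)]])
    return out[:n]


def ecdf_sample(source_sample: np.ndarray, n: int,
                rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Inverse-transform draws from the linearly interpolated empirical CDF.

    Draws always lie within [min(source), max(source)]; identical seeds
    give identical draws.
    """
    src = np.sort(np.asarray(source_sample, dtype=float))
    if src.size == 0:
        raise ValueError("source sample must be non-empty")
    if n < 0:
        raise ValueError("n must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    u = rng.uniform(0.0, 1.0, size=n)
    grid = np.linspace(0.0, 1.0, src.size)
    return np.interp(u, grid, src)


@dataclass
class CommandConfig:
    """Parameters of one surrogate command pattern."""

    pattern: str                       # struggle | swim | initial_coil
    frequency: float                   # Hz
    propagation_speed: float           # mm/s signed, + = caudorostral
    n_cycles: int = 8
    seed: int = 0
    duty_rostral: float = 0.40         # duty cycle at 0.5 mm
    duty_caudal: float = 0.60          # duty cycle at 4.8 mm
    spikes_mean_rostral: float = 6.1   # mean spikes/burst, rostral group
    spikes_mean_caudal: float = 1.9
    spikes_sd_rostral: float = 4.1
    spikes_sd_caudal: float = 0.9
    rostral_center: float = 1.0        # mm, centroids of the recorded groups
    caudal_center: float = 2.25
    isi_region_split: float = 2.2      # mm, rostral vs caudal ISI source
    isi_source_rostral: np.ndarray | None = None
    isi_source_caudal: np.ndarray | None = None
    coil_spikes: int = 15
    coil_speed: float = 5000.0         # mm/s; near-synchronous onset spread
    stimulated_side: str = "right"

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.pattern != "initial_coil" and self.propagation_speed == 0:
            raise ValueError("propagation_speed must be non-zero")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    def isi_source(self, position: float) -> np.ndarray:
        if position < self.isi_region_split:
            if self.isi_source_rostral is None:
                self.isi_source_rostral = default_isi_source("rostral")
            return self.isi_source_rostral
        if self.isi_source_caudal is None:
            self.isi_source_caudal = default_isi_source("caudal")
        return self.isi_source_caudal

    def spikes_mean(self, x: float) -> float:
        return float(np.interp(x, [self.rostral_center, self.caudal_center],
                               [self.spikes_mean_rostral,
                                self.spikes_mean_caudal]))

    def spikes_sd(self, x: float) -> float:
        return float(np.interp(x, [self.rostral_center, self.caudal_center],
                               [self.spikes_sd_rostral, self.spikes_sd_caudal]))

    def duty(self, x: float) -> float:
        return float(np.interp(x, list(ROSTER_SPAN),
                               [self.duty_rostral, self.duty_caudal]))


def struggle_config(**kw) -> CommandConfig:
    """Default struggling command: 4 Hz, caudorostral +40 mm/s."""
    kw.setdefault("pattern", "struggle")
    kw.setdefault("frequency", 4.0)
    kw.setdefault("propagation_speed", 40.0)
    return CommandConfig(**kw)


def swim_config(**kw) -> CommandConfig:
    """Default swimming command: 20 Hz, rostrocaudal -130 mm/s, one
    spike per neuron per cycle."""
    kw.setdefault("pattern", "swim")
    kw.setdefault("frequency", 20.0)
    kw.setdefault("propagation_speed", -130.0)
    return CommandConfig(**kw)


def initial_coil_config(**kw) -> CommandConfig:
    kw.setdefault("pattern", "initial_coil")
    kw.setdefault("frequency", 4.0)
    kw.setdefault("propagation_speed", 5000.0)
    kw.setdefault("n_cycles", 1)
    return CommandConfig(**kw)


@dataclass
class SpikeTable:
    """Surrogate motor command: one row per spike.

    Columns: neuron_id, side, position_mm, spike_time_ms.  ``meta`` echoes
    the generating configuration and seed.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.frame["spike_time_ms"].to_numpy()
        if t.size and t.min() < 0:
            raise ValueError("spike times must be non-negative")

    def write(self, path) -> None:
        """TSV of spikes plus a JSON metadata sidecar (<path>.json)."""
        path = Path(path)
        out = self.frame.copy()
        out["position_mm"] = out["position_mm"].map(lambda v: f"{v:.6f}")
        out["spike_time_ms"] = out["spike_time_ms"].map(lambda v: f"{v:.6f}")
        out.to_csv(path, sep="\t", index=False)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(self.meta, indent=1, default=str))

    @classmethod
    def read(cls, path) -> "SpikeTable":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", dtype={"neuron_id": str})
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(frame=frame, meta=meta)


def _delay_ms(x: np.ndarray, speed: float, x_ref: float) -> np.ndarray:
    """Burst-onset delay map: caudal neurons lead when speed > 0."""
    return (x_ref - x) / speed * 1000.0


def _meta(config: CommandConfig) -> dict:
    d = dataclasses.asdict(config)
    d["isi_source_rostral"] = None
    d["isi_source_caudal"] = None
    return d


def generate_struggle(config: CommandConfig,
                      roster: MotoneuronRoster) -> SpikeTable:
    """Struggling command: anti-phase 4 Hz bursts, caudorostral onsets.

    Per neuron and cycle the burst onset follows the position-delay map;
    the spike count is a discretized normal with position-interpolated
    mean/SD truncated at >= 1; inter-spike intervals are empirical-CDF
    draws.  Bursts longer than the local duty window are truncated (with a
    warning).  Generation order is fixed (side, then position, then
    cycle), so one seed pins the whole table.
    """
    rng = np.random.default_rng(config.seed)
    period = 1000.0 / config.frequency
    x = roster.positions
    base_delay = _delay_ms(x, config.propagation_speed, ROSTER_SPAN[0])
    offset = -min(0.0, float(base_delay.min()))
    rows, truncated = [], 0
    for side, phase in (("left", 0.0), ("right", 0.5 * period)):
        tag = side[0].upper()
        for i, xi in enumerate(x):
            source = config.isi_source(xi)
            limit = config.duty(xi) * period
            for c in range(config.n_cycles):
                onset = c * period + phase + base_delay[i] + offset
                n_spk = max(1, int(round(rng.normal(config.spikes_mean(xi),
                                                    config.spikes_sd(xi)))))
                isis = ecdf_sample(source, n_spk - 1, rng)
                t = onset + np.concatenate(([0.0], np.cumsum(isis)))
                if t[-1] - onset > limit:
                    t = t[t - onset <= limit]
                    truncated += 1
                for ts in t:
                    rows.append((f"{tag}{i:03d}", side, xi, ts))
    if truncated:
        warnings.warn(f"{truncated} bursts truncated to the duty-cycle "
                      "window", stacklevel=2)
    frame = pd.DataFrame(rows, columns=["neuron_id", "side", "position_mm",
                                        "spike_time_ms"])
    return SpikeTable(frame, {"config": _meta(config), "seed": config.seed})


def generate_swim(config: CommandConfig,
                  roster: MotoneuronRoster) -> SpikeTable:
    """Swimming command: one spike per neuron per cycle, anti-phase sides,
    rostrocaudal propagation at the configured speed."""
    period = 1000.0 / config.frequency
    x = roster.positions
    delay = _delay_ms(x, config.propagation_speed, ROSTER_SPAN[0])
    offset = -min(0.0, float(delay.min()))
    rows = []
    for side, phase in (("left", 0.0), ("right", 0.5 * period)):
        tag = side[0].upper()
        for i, xi in enumerate(x):
            for c in range(config.n_cycles):
                rows.append((f"{tag}{i:03d}", side, xi,
                             c * period + phase + delay[i] + offset))
    frame = pd.DataFrame(rows, columns=["neuron_id", "side", "position_mm",
                                        "spike_time_ms"])
    return SpikeTable(frame, {"config": _meta(config), "seed": config.seed})


def generate_initial_coil(config: CommandConfig, roster: MotoneuronRoster,
                          stimulated_side: str | None = None) -> SpikeTable:
    """Initial coil: one fixed-count burst per motoneuron on the side
    opposite to stimulation, near-synchronous along the body."""
    rng = np.random.default_rng(config.seed)
    side = {"left": "right", "right": "left"}[
        stimulated_side or config.stimulated_side]
    tag = side[0].upper()
    x = roster.positions
    delay = np.abs(_delay_ms(x, config.coil_speed, ROSTER_SPAN[0]))
    rows = []
    for i, xi in enumerate(x):
        isis = ecdf_sample(config.isi_source(xi), config.coil_spikes - 1, rng)
        t = delay[i] + np.concatenate(([0.0], np.cumsum(isis)))
        for ts in t:
            rows.append((f"{tag}{i:03d}", side, xi, ts))
    frame = pd.DataFrame(rows, columns=["neuron_id", "side", "position_mm",
                                        "spike_time_ms"])
    return SpikeTable(frame, {"config": _meta(config), "seed": config.seed,
                              "stimulated_side": stimulated_side
                              or config.stimulated_side})


def generate_reverse(config: CommandConfig,
                     roster: MotoneuronRoster) -> SpikeTable:
    """Reverse variant: the same per-neuron spike multiset with the
    position-delay map negated (same seed, opposite propagation)."""
    flipped = dataclasses.replace(
        config, propagation_speed=-config.propagation_speed)
    return generate(flipped, roster)


def generate(config: CommandConfig, roster: MotoneuronRoster) -> SpikeTable:
    """Dispatch on the configured pattern."""
    if config.pattern == "struggle":
        return generate_struggle(config, roster)
    if config.pattern == "swim":
        return generate_swim(config, roster)
    if config.pattern == "initial_coil":
        return generate_initial_coil(config, roster)
    raise ValueError(f"unknown pattern {config.pattern!r}")


# ---------------------------------------------------------------------------
# measurements used to verify generated commands against their design targets

def _burst_onsets(times_ms: np.ndarray, max_gap: float = 20.0) -> np.ndarray:
    t = np.sort(times_ms)
    if t.size == 0:
        return t
    splits = np.nonzero(np.diff(t) > max_gap)[0]
    starts = np.concatenate(([0], splits + 1))
    return t[starts]


def measure_onset_speed(table: SpikeTable, max_gap: float = 20.0,
                        side: str = "left") -> float:
    """Mean propagation speed (mm/s, + = caudorostral) of burst onsets.

    Per neuron, spikes are grouped into bursts (gap > ``max_gap`` ms);
    per cycle rank, onset time is regressed on position and the speed is
    -1000/slope, averaged over cycles.
    """
    sub = table.frame[table.frame["side"] == side]
    onsets, positions = [], []
    n_cycles = None
    for _, g in sub.groupby("neuron_id"):
        o = _burst_onsets(g["spike_time_ms"].to_numpy(), max_gap)
        if n_cycles is None:
            n_cycles = o.size
        if o.size != n_cycles:
            continue
        onsets.append(o)
        positions.append(float(g["position_mm"].iloc[0]))
    onsets = np.asarray(onsets)
    positions = np.asarray(positions)
    speeds = []
    for c in range(onsets.shape[1]):
        fit = _stats.linregress(positions, onsets[:, c])
        if fit.slope != 0:
            speeds.append(-1000.0 / fit.slope)
    return float(np.mean(speeds))


def measure_burst_frequency(table: SpikeTable, max_gap: float = 20.0,
                            positions: tuple[float, float] = (0.5, 1.5),
                            side: str = "left") -> float:
    """Mean burst rate (Hz) of neurons within a rostrocaudal window."""
    sub = table.frame[(table.frame["side"] == side)
                      & (table.frame["position_mm"] >= positions[0])
                      & (table.frame["position_mm"] <= positions[1])]
    freqs = []
    for _, g in sub.groupby("neuron_id"):
        o = _burst_onsets(g["spike_time_ms"].to_numpy(), max_gap)
        if o.size >= 2:
            freqs.append(1000.0 / float(np.mean(np.diff(o))))
    return float(np.mean(freqs))
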