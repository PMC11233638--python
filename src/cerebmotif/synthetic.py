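"""Seeded generators for every input the analysis pipeline consumes.

The connectivity generator realizes exactly the independence null model the
motif test assumes (independent Bernoulli draw per zone, lobules allocated
consistently with the zone-mapping rule), with an optional enrichment knob
that appends extra cells of a fixed pattern for power studies.  Coordinate,
sweep, spike-train and puncta generators realize the alternative and null
hypotheses of the downstream stages with known ground truth, so each
analysis can be validated as a recovery problem.  Every generator is a pure
function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import defaults
from .connectivity import (
    CellConnectivity,
    ConnectivityDataset,
    Lobule,
    Zone,
    ZONES,
    zones_from_lobules,
)
from .puncta import PunctaField
from .signal_features import SpikeTrain, SweepSet
from .topography import CellCoordinate, PLANES, Plane

#: Zone marginals of the canonical dataset (counts 13/26/16/13 over 75).
FIXTURE_ZONE_PROBS: dict[Zone, float] = {
    Zone.ANTERIOR: 13 / 75,
    Zone.CENTRAL: 26 / 75,
    Zone.POSTERIOR: 16 / 75,
    Zone.NODULAR: 13 / 75,
}

#: Zone-count group sizes of the canonical dataset.
FIXTURE_GROUP_SIZES: dict[int, int] = {0: 34, 1: 24, 2: 10, 3: 4, 4: 3}

_AMP = lambda lob: 40.0 + 20.0 * lob.index  # same deterministic scheme as the fixture


@dataclass(frozen=True)
class SimConnectivityConfig:
    n_cells: int = 75
    zone_probs: Mapping[Zone, float] = field(
        default_factory=lambda: dict(FIXTURE_ZONE_PROBS)
    )
    lobule_allocation: str = "one_per_zone"   # or "dense"
    enrichment: tuple[frozenset, int] | None = None  # (pattern, extra_count)
    seed: int = 0

    def __post_init__(self) -> None:
        for z, p in self.zone_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"zone probability for {z} outside [0,1]")
        if self.enrichment is not None and self.enrichment[1] < 0:
            raise ValueError("enrichment extra_count must be >= 0")
        if self.lobule_allocation not in ("one_per_zone", "dense"):
            raise ValueError(f"unknown lobule allocation: {self.lobule_allocation!r}")


def _allocate_lobules(
    zones: frozenset, mode: str, rng: np.random.Generator
) -> frozenset[Lobule]:
    """Realize a zone set as a lobule set consistent with the mapping rule.

    ``one_per_zone`` draws exactly one lobule per zone (so zone and lobule
    marginals coincide); ``dense`` includes each in-zone lobule
    independently with probability 0.7, forcing at least one.  When both
    posterior and nodular are drawn, posterior is realized through VIII
    (IX would count as nodular alongside X).
    """
    lobules: set[Lobule] = set()
    if Zone.ANTERIOR in zones:
        cands = [Lobule.III, Lobule.IV_V]
        lobules |= _pick(cands, mode, rng)
    if Zone.CENTRAL in zones:
        lobules.add(Lobule.VI_VII)
    if Zone.NODULAR in zones:
        lobules.add(Lobule.X)
    if Zone.POSTERIOR in zones:
        if Zone.NODULAR in zones:
            lobules.add(Lobule.VIII)
            if mode == "dense" and rng.random() < 0.7:
                lobules.add(Lobule.IX)
        else:
            lobules |= _pick([Lobule.VIII, Lobule.IX], mode, rng)
    realized = zones_from_lobules(lobules)
    if realized != zones:
        raise RuntimeError(
            f"allocation rule inconsistent with zone map: {zones} -> {realized}"
        )
    return frozenset(lobules)


def _pick(cands: list[Lobule], mode: str, rng: np.random.Generator) -> set[Lobule]:
    if mode == "one_per_zone":
        return {cands[rng.integers(len(cands))]}
    chosen = {c for c in cands if rng.random() < 0.7}
    if not chosen:
        chosen = {cands[rng.integers(len(cands))]}
    return chosen


def simulate_connectivity(cfg: SimConnectivityConfig) -> ConnectivityDataset:
    """Draw a dataset from the zone-independence model.

    Each cell's zone set is an independent Bernoulli draw per zone; lobules
    are then allocated per the configured rule.  ``enrichment`` appends
    ``extra_count`` additional cells with the fixed pattern.  Amplitudes
    use the package's deterministic per-lobule scheme.
    """
    rng = np.random.default_rng(cfg.seed)
    cells = []
    for i in range(cfg.n_cells):
        zones = frozenset(
            z for z in ZONES if rng.random() < cfg.zone_probs.get(z, 0.0)
        )
        lobules = _allocate_lobules(zones, cfg.lobule_allocation, rng)
        cells.append(_make_cell(f"sim{i:03d}", lobules))
    if cfg.enrichment is not None:
        pattern, extra = cfg.enrichment
        for j in range(extra):
            lobules = _allocate_lobules(frozenset(pattern), cfg.lobule_allocation, rng)
            cells.append(_make_cell(f"enr{j:03d}", lobules))
    return ConnectivityDataset(cells=tuple(cells))


def _make_cell(cell_id: str, lobules: frozenset[Lobule]) -> CellConnectivity:
    from .connectivity import TABLE_LOBULES

    return CellConnectivity(
        cell_id=cell_id,
        connected={lob: lob in lobules for lob in TABLE_LOBULES},
        amplitude_pA={lob: _AMP(lob) for lob in lobules},
        terminal_amplitude_pA=defaults.SIM_TERMINAL_AMPLITUDE_PA,
    )


def simulate_coordinates(
    n_total: int = 75,
    group_sizes: Mapping[int, int] | None = None,
    biased_group: int | None = None,
    plane: Plane = "rc_dv",
    noise_sd: float = 25.0,
    spread_sd: float = 150.0,
    slope: float = 1.0,
    seed: int = 0,
) -> list[CellCoordinate]:
    """Cell coordinates with an optional topographically biased group.

    Unbiased cells are i.i.d. isotropic Gaussians (SD ``spread_sd`` µm) in
    all three axes.  The biased group is placed along a line of the given
    slope in the chosen plane, plus Gaussian perpendicular noise
    (``noise_sd``); its off-plane coordinate stays isotropic.  With
    ``noise_sd = 0`` the group is exactly collinear.
    """
    if plane not in PLANES:
        raise ValueError(f"unknown plane: {plane!r}")
    if group_sizes is None:
        group_sizes = dict(FIXTURE_GROUP_SIZES)
    if sum(group_sizes.values()) > n_total:
        raise ValueError("group sizes exceed n_total")
    rng = np.random.default_rng(seed)
    xattr, yattr = PLANES[plane]
    coords: list[CellCoordinate] = []
    i = 0
    for group, size in sorted(group_sizes.items()):
        for _ in range(size):
            vals = {
                "x_ml": float(rng.normal(0, spread_sd)),
                "y_ap": float(rng.normal(0, spread_sd)),
                "z_dv": float(rng.normal(0, spread_sd)),
            }
            if group == biased_group:
                t = float(rng.uniform(-spread_sd, spread_sd))
                vals[xattr] = t
                vals[yattr] = slope * t + float(rng.normal(0, noise_sd))
            coords.append(CellCoordinate(cell_id=f"cell{i:03d}", n_zones=group, **vals))
            i += 1
    return coords


@dataclass(frozen=True)
class SimEphysConfig:
    firing_rate_hz: float = defaults.SIM_FIRING_RATE_HZ
    isi_cv: float = defaults.SIM_ISI_CV
    pause_factor: float = defaults.SIM_PAUSE_FACTOR
    amplitude_pA: float = defaults.SIM_IPSC_AMPLITUDE_PA
    rise_tau_ms: float = defaults.SIM_RISE_TAU_MS
    decay_tau1_ms: float = defaults.SIM_DECAY_TAU1_MS
    decay_tau2_ms: float = defaults.SIM_DECAY_TAU2_MS
    decay_frac1: float = defaults.SIM_DECAY_FRAC1
    noise_sd_pA: float = defaults.SIM_NOISE_SD_PA
    n_sweeps: int = 10
    failure_prob: float = 0.0
    sampling_interval_ms: float = defaults.SIM_SAMPLING_INTERVAL_MS
    stim_onset_ms: float = defaults.STIM_ONSET_MS
    stim_duration_ms: float = defaults.STIM_DURATION_MS
    sweep_duration_ms: float = defaults.SIM_SWEEP_DURATION_MS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.firing_rate_hz <= 0:
            raise ValueError("firing rate must be positive")
        if self.noise_sd_pA < 0:
            raise ValueError("noise SD must be nonnegative")
        if not 0.0 <= self.failure_prob <= 1.0:
            raise ValueError("failure_prob outside [0,1]")


def ipsc_waveform(cfg: SimEphysConfig, t_ms: np.ndarray) -> np.ndarray:
    """Unit-peak IPSC shape: saturating rise times a double-exponential decay."""
    t = np.clip(t_ms, 0.0, None)
    shape = (1.0 - np.exp(-t / cfg.rise_tau_ms)) * (
        cfg.decay_frac1 * np.exp(-t / cfg.decay_tau1_ms)
        + (1.0 - cfg.decay_frac1) * np.exp(-t / cfg.decay_tau2_ms)
    )
    shape[t_ms < 0] = 0.0
    peak = shape.max()
    return shape / peak if peak > 0 else shape


def simulate_sweeps(cfg: SimEphysConfig) -> tuple[SweepSet, dict]:
    """Synthesize stimulus-aligned current sweeps with known ground truth.

    Each sweep is baseline 0 plus, with probability ``1 - failure_prob``,
    an IPSC of configured amplitude and kinetics, plus white Gaussian noise.
    Returns the SweepSet and a ground-truth record (per-sweep success flags
    and the configured feature values).
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.sweep_duration_ms / cfg.sampling_interval_ms))
    t = np.arange(n_samples) * cfg.sampling_interval_ms
    shape = ipsc_waveform(cfg, t - cfg.stim_onset_ms)
    successes = rng.random(cfg.n_sweeps) >= cfg.failure_prob
    sweeps = np.zeros((cfg.n_sweeps, n_samples))
    for i, ok in enumerate(successes):
        if ok:
            sweeps[i] += cfg.amplitude_pA * shape
        if cfg.noise_sd_pA > 0:
            sweeps[i] += rng.normal(0, cfg.noise_sd_pA, n_samples)
    truth = {
        "amplitude_pA": cfg.amplitude_pA,
        "successes": successes,
        "failure_fraction": float(1.0 - successes.mean()),
        "decay_tau1_ms": cfg.decay_tau1_ms,
        "decay_tau2_ms": cfg.decay_tau2_ms,
        "decay_frac1": cfg.decay_frac1,
    }
    return (
        SweepSet(
            sampling_interval_ms=cfg.sampling_interval_ms,
            stim_onset_ms=cfg.stim_onset_ms,
            stim_duration_ms=cfg.stim_duration_ms,
            sweeps=sweeps,
        ),
        truth,
    )


def simulate_spike_train(
    cfg: SimEphysConfig,
    stim_time_ms: float = 250.0,
    duration_ms: float = 1000.0,
    trial_id: str | None = None,
) -> SpikeTrain:
    """Gamma-renewal spike train with a stimulus-locked pause.

    ISIs are gamma with shape 1/CV^2 at the configured rate; the interval
    containing the end of the light pulse is stretched by ``pause_factor``
    (all later spikes shift accordingly), so in the CV -> 0 limit the ISI
    ratio equals the pause factor exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    mean_isi = 1000.0 / cfg.firing_rate_hz
    cv = max(cfg.isi_cv, 1e-9)
    shape = 1.0 / cv**2
    scale = mean_isi / shape
    offset = stim_time_ms + cfg.stim_duration_ms
    isis = []
    total = float(rng.uniform(0, mean_isi))  # random phase for the first spike
    spikes = [total]
    while total < offset + duration_ms:
        isi = float(rng.gamma(shape, scale))
        isis.append(isi)
        total += isi
        spikes.append(total)
    arr = np.array(spikes)
    # stretch the ISI containing the stimulus offset
    idx = int(np.searchsorted(arr, offset, side="right") - 1)
    if 0 <= idx < arr.size - 1:
        extra = (cfg.pause_factor - 1.0) * (arr[idx + 1] - arr[idx])
        arr[idx + 1 :] += extra
    return SpikeTrain(spike_times=arr, stim_time_ms=stim_time_ms, trial_id=trial_id)


def simulate_puncta(
    channel_intensities: Mapping[str, float],
    area: tuple[float, float],
    seed: int = 0,
    animal_id: str | None = None,
) -> PunctaField:
    """Independent homogeneous Poisson point processes, one per channel.

    ``channel_intensities`` are in puncta per µm²; ``area`` is the (width,
    height) of the rectangular field in µm.
    """
    w, h = area
    if w <= 0 or h <= 0:
        raise ValueError("area dimensions must be positive")
    for name, lam in channel_intensities.items():
        if lam <= 0:
            raise ValueError(f"intensity for channel {name!r} must be positive")
    rng = np.random.default_rng(seed)
    channels = {}
    for name in sorted(channel_intensities):
        lam = channel_intensities[name]
        n = rng.poisson(lam * w * h)
        xy = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
        channels[name] = xy
    return PunctaField(channels=channels, animal_id=animal_id)
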