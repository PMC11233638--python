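"""Feature extraction from voltage-clamp sweeps and spike trains.

IPSC features: peak amplitude relative to a pre-stimulus baseline, 20-80%
rise time with sub-sample interpolation, double-exponential decay fit with
amplitude-weighted time constant, per-lobule failure fraction and a
responsiveness call.  Spike-train features: the inter-spike-interval (ISI)
ratio read-out of stimulus-evoked pauses, with exclusion of slow-firing
(< 20 Hz) and bursting trials.  Also small derived statistics: the
disparity index (coefficient of variation of per-lobule amplitudes), the
squared Pearson correlation between amplitude and ISI ratio, and the
dendritic branch index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import defaults


class InsufficientDataError(ValueError):
    """Too few sweeps/spikes to compute the requested feature."""


class ExcludedTrialError(ValueError):
    """Trial rejected by an exclusion rule (slow firing, bursting)."""


class DecayFitError(RuntimeError):
    """Double-exponential decay fit failed to converge."""


@dataclass(frozen=True)
class SweepSet:
    """Stimulus-aligned current sweeps for one stimulation site.

    ``sweeps`` is (n_sweeps, n_samples) in pA; time is implicit from
    ``sampling_interval_ms`` starting at 0.
    """

    sampling_interval_ms: float
    stim_onset_ms: float
    sweeps: np.ndarray
    stim_duration_ms: float = defaults.STIM_DURATION_MS

    def __post_init__(self) -> None:
        arr = np.asarray(self.sweeps, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError("sweeps must be a non-empty 2-D array")
        object.__setattr__(self, "sweeps", arr)
        if not 0 <= self.stim_onset_ms < arr.shape[1] * self.sampling_interval_ms:
            raise ValueError("stim_onset_ms outside the trace")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[1]) * self.sampling_interval_ms


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (ms) for one trial with the light-stimulus onset time."""

    spike_times: np.ndarray
    stim_time_ms: float
    trial_id: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.spike_times, dtype=float)
        if arr.ndim != 1 or np.any(np.diff(arr) <= 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "spike_times", arr)


def _window_slices(sweeps: SweepSet, baseline_ms: float, response_ms: float):
    dt = sweeps.sampling_interval_ms
    onset = int(round(sweeps.stim_onset_ms / dt))
    b0 = max(0, onset - int(round(baseline_ms / dt)))
    r1 = onset + int(round(response_ms / dt))
    if r1 > sweeps.sweeps.shape[1]:
        raise ValueError("response window extends beyond the trace")
    if onset <= b0:
        raise ValueError("baseline window empty")
    return slice(b0, onset), slice(onset, r1)


def _smooth(x: np.ndarray, width_samples: int) -> np.ndarray:
    if width_samples <= 1:
        return x
    kernel = np.ones(width_samples) / width_samples
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), -1, x)


def sweep_amplitudes(
    sweeps: SweepSet,
    baseline_ms: float = defaults.BASELINE_WINDOW_MS,
    response_ms: float = defaults.RESPONSE_WINDOW_MS,
    smooth_ms: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sweep (amplitude, baseline mean, baseline SD).

    Amplitude is the maximal absolute deviation from the per-sweep baseline
    within the response window (stimulus onset -> onset + ``response_ms``),
    as a positive magnitude.  An optional boxcar of width ``smooth_ms`` is
    applied before the peak search (used for detection, not measurement).
    """
    bsl, rsl = _window_slices(sweeps, baseline_ms, response_ms)
    traces = sweeps.sweeps
    baseline = traces[:, bsl].mean(axis=1)
    noise_sd = traces[:, bsl].std(axis=1, ddof=1)
    dev = traces - baseline[:, None]
    if smooth_ms > 0:
        width = max(1, int(round(smooth_ms / sweeps.sampling_interval_ms)))
        dev = _smooth(dev, width)
    amp = np.abs(dev[:, rsl]).max(axis=1)
    return amp, baseline, noise_sd


def ipsc_amplitude(
    sweeps: SweepSet,
    baseline_ms: float = defaults.BASELINE_WINDOW_MS,
    response_ms: float = defaults.RESPONSE_WINDOW_MS,
    threshold_sd: float = defaults.DETECTION_THRESHOLD_SD,
) -> tuple[float, np.ndarray]:
    """Mean IPSC amplitude over non-failure sweeps, plus per-sweep amplitudes.

    A sweep is a failure when its (detection-smoothed) amplitude does not
    clear ``threshold_sd`` baseline-noise SDs; if every sweep fails, the
    mean over all sweeps is returned.
    """
    amp, _, noise_sd = sweep_amplitudes(sweeps, baseline_ms, response_ms)
    det_amp, _, _ = sweep_amplitudes(
        sweeps, baseline_ms, response_ms, smooth_ms=defaults.DETECTION_SMOOTH_MS
    )
    success = _success_mask(det_amp, noise_sd, threshold_sd)
    mean_amp = float(amp[success].mean()) if success.any() else float(amp.mean())
    return mean_amp, amp


def _success_mask(amp: np.ndarray, noise_sd: np.ndarray, threshold_sd: float) -> np.ndarray:
    # amplitude must both clear the noise floor and be nonzero (so a noiseless
    # flat sweep, where SD == 0, still counts as a failure)
    return (amp >= threshold_sd * noise_sd) & (amp > 0)


def classify_connected(
    sweeps: SweepSet,
    threshold_sd: float = defaults.DETECTION_THRESHOLD_SD,
    success_fraction: float = defaults.SUCCESS_FRACTION,
    baseline_ms: float = defaults.BASELINE_WINDOW_MS,
    response_ms: float = defaults.RESPONSE_WINDOW_MS,
    smooth_ms: float = defaults.DETECTION_SMOOTH_MS,
) -> tuple[bool, float]:
    """Responsiveness call and failure fraction for one stimulation site.

    A sweep succeeds when its boxcar-smoothed peak deviation reaches
    ``threshold_sd`` x baseline-noise SD; the site is responsive when the
    success fraction is >= ``success_fraction``.  Requires >= 3 sweeps.
    """
    if sweeps.sweeps.shape[0] < defaults.MIN_SWEEPS:
        raise InsufficientDataError(
            f"need >= {defaults.MIN_SWEEPS} sweeps, got {sweeps.sweeps.shape[0]}"
        )
    det_amp, _, noise_sd = sweep_amplitudes(
        sweeps, baseline_ms, response_ms, smooth_ms=smooth_ms
    )
    success = _success_mask(det_amp, noise_sd, threshold_sd)
    frac = float(success.mean())
    return frac >= success_fraction, 1.0 - frac


def rise_time_20_80(
    sweep: np.ndarray,
    baseline: float,
    sampling_interval_ms: float,
    peak_index: int | None = None,
) -> float | None:
    """Time between the 20% and 80% crossings of the peak deviation (ms).

    Crossings are located with linear interpolation between samples on the
    rising limb (start of trace -> peak).  Returns None when the peak
    deviation is zero.
    """
    dev = np.abs(np.asarray(sweep, dtype=float) - baseline)
    if peak_index is None:
        peak_index = int(np.argmax(dev))
    peak = dev[peak_index]
    if peak == 0:
        return None

    def first_crossing(level: float) -> float:
        above = np.nonzero(dev[: peak_index + 1] >= level)[0]
        i = int(above[0])
        if i == 0 or dev[i] == dev[i - 1]:
            return float(i)
        # interpolate between the bracketing samples
        return (i - 1) + (level - dev[i - 1]) / (dev[i] - dev[i - 1])

    t20 = first_crossing(0.2 * peak)
    t80 = first_crossing(0.8 * peak)
    return float((t80 - t20) * sampling_interval_ms)


@dataclass(frozen=True)
class DecayFit:
    """Double-exponential decay fit, components ordered tau1 <= tau2."""

    a1_pA: float
    tau1_ms: float
    a2_pA: float
    tau2_ms: float
    cost: float

    @property
    def tau_weighted_ms(self) -> float:
        """Amplitude-weighted decay time constant
        (A1*tau1 + A2*tau2) / (A1 + A2)."""
        total = self.a1_pA + self.a2_pA
        return (self.a1_pA * self.tau1_ms + self.a2_pA * self.tau2_ms) / total


def fit_decay_double_exp(
    segment: np.ndarray,
    sampling_interval_ms: float,
    tau_inits: Sequence[tuple[float, float]] = ((2.0, 20.0), (1.0, 8.0), (5.0, 50.0)),
) -> DecayFit:
    """Bounded least-squares fit of A1*exp(-t/tau1) + A2*exp(-t/tau2).

    ``segment`` is the decay phase from the peak onward, as positive
    deviations from baseline (>= 20 samples).  Component amplitudes are
    constrained nonnegative; several tau starting pairs are tried and the
    lowest-cost solution kept, with components returned in tau1 <= tau2
    order to remove label switching.
    """
    y = np.asarray(segment, dtype=float)
    if y.size < 20:
        raise InsufficientDataError("decay segment must have >= 20 samples")
    t = np.arange(y.size) * sampling_interval_ms
    peak = max(y[0], 1e-12)

    def resid(params: np.ndarray) -> np.ndarray:
        a1, tau1, a2, tau2 = params
        return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) - y

    lower = [0.0, 1e-3, 0.0, 1e-3]
    upper = [10 * peak, 1e4, 10 * peak, 1e4]
    best = None
    for t1, t2 in tau_inits:
        x0 = [0.6 * peak, t1, 0.4 * peak, t2]
        try:
            sol = least_squares(resid, x0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise DecayFitError("double-exponential fit did not converge from any start")
    a1, tau1, a2, tau2 = best.x
    if tau1 > tau2:
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    return DecayFit(a1_pA=float(a1), tau1_ms=float(tau1),
                    a2_pA=float(a2), tau2_ms=float(tau2), cost=float(best.cost))


def disparity_index(values: Sequence[float]) -> float | None:
    """Coefficient of variation (sample SD / mean) of per-lobule amplitudes.

    Returns None for fewer than two values; requires a positive mean.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        return None
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("disparity index requires a positive mean")
    return float(vals.std(ddof=1) / mean)


IsiMode = Literal["containing", "first_complete"]


def isi_ratio(
    train: SpikeTrain,
    stim_duration_ms: float = defaults.STIM_DURATION_MS,
    min_rate_hz: float = defaults.MIN_FIRING_RATE_HZ,
    burst_cv_max: float = defaults.BURST_CV_MAX,
    mode: IsiMode = "containing",
) -> float:
    """Post-stimulus ISI divided by the trial's mean of all other ISIs.

    The post-stimulus ISI is the interval containing the end of the light
    pulse (the interval interrupted by the stimulus); ``first_complete``
    instead takes the first interval starting at or after light offset.
    Trials firing slower than ``min_rate_hz`` or with ISI coefficient of
    variation above ``burst_cv_max`` (bursting rather than tonic firing)
    are rejected.
    """
    spikes = train.spike_times
    n_before = int(np.sum(spikes < train.stim_time_ms))
    n_after = int(np.sum(spikes >= train.stim_time_ms))
    if n_before < 2 or n_after < 1:
        raise InsufficientDataError("need >= 2 spikes before and >= 1 after the stimulus")
    isis = np.diff(spikes)
    mean_isi = isis.mean()
    rate = 1000.0 / mean_isi
    if rate < min_rate_hz:
        raise ExcludedTrialError(f"firing rate {rate:.1f} Hz below {min_rate_hz} Hz")
    cv = isis.std(ddof=1) / mean_isi
    if cv > burst_cv_max:
        raise ExcludedTrialError(f"ISI CV {cv:.2f} marks a bursting trial")
    offset = train.stim_time_ms + stim_duration_ms
    if mode == "containing":
        idx = np.searchsorted(spikes, offset, side="right") - 1
        if idx < 0 or idx >= isis.size:
            raise InsufficientDataError("no ISI contains the stimulus offset")
    elif mode == "first_complete":
        idx = int(np.searchsorted(spikes, offset, side="left"))
        if idx >= isis.size:
            raise InsufficientDataError("no complete ISI after the stimulus offset")
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    others = np.delete(isis, idx)
    return float(isis[idx] / others.mean())


def amplitude_isi_correlation(pairs: Sequence[tuple[float, float]]) -> float | None:
    """Squared Pearson correlation between IPSC amplitude and ISI ratio.

    Returns None when either variable has zero variance; needs >= 3 pairs.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.shape[0] < 3:
        raise InsufficientDataError("need >= 3 (amplitude, ratio) pairs")
    x, y = arr[:, 0], arr[:, 1]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def branch_index(crossings_at_25um: int, primary_dendrites: int) -> float:
    """Dendritic crossings at 25 µm from the soma per primary dendrite."""
    if primary_dendrites < 1:
        raise ValueError("primary_dendrites must be >= 1")
    if crossings_at_25um < 0:
        raise ValueError("crossings must be nonnegative")
    return crossings_at_25um / primary_dendrites


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_sweeps(data_path: str | Path, meta_path: str | Path) -> SweepSet:
    """Read sweeps from a columnar file (``time_ms`` + one column per sweep)
    plus a key=value sidecar with ``stim_onset_ms`` and ``stim_duration_ms``."""
    df = pd.read_csv(data_path)
    if "time_ms" not in df.columns:
        raise ValueError("sweep file must have a time_ms column")
    t = df["time_ms"].to_numpy()
    if t.size < 2:
        raise ValueError("sweep file too short")
    dt = float(t[1] - t[0])
    sweeps = df.drop(columns=["time_ms"]).to_numpy().T
    meta: dict[str, float] = {}
    for line in Path(meta_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        meta[key.strip()] = float(value)
    return SweepSet(
        sampling_interval_ms=dt,
        stim_onset_ms=meta["stim_onset_ms"],
        stim_duration_ms=meta.get("stim_duration_ms", defaults.STIM_DURATION_MS),
        sweeps=sweeps,
    )


def write_sweeps(sweeps: SweepSet, data_path: str | Path, meta_path: str | Path) -> None:
    df = pd.DataFrame({"time_ms": sweeps.times_ms})
    for i, trace in enumerate(sweeps.sweeps):
        df[f"sweep_{i}"] = trace
    df.to_csv(data_path, index=False)
    Path(meta_path).write_text(
        f"stim_onset_ms = {sweeps.stim_onset_ms}\n"
        f"stim_duration_ms = {sweeps.stim_duration_ms}\n"
    )


def read_spike_trains(spikes_path: str | Path, stims_path: str | Path) -> list[SpikeTrain]:
    """Read trains from ``trial_id,spike_time_ms`` and ``trial_id,stim_time_ms`` tables."""
    spikes = pd.read_csv(spikes_path, dtype={"trial_id": str})
    stims = pd.read_csv(stims_path, dtype={"trial_id": str})
    stim_by_trial = dict(zip(stims["trial_id"], stims["stim_time_ms"]))
    trains = []
    for trial_id, group in spikes.groupby("trial_id", sort=True):
        if trial_id not in stim_by_trial:
            raise ValueError(f"no stimulus time for trial {trial_id!r}")
        trains.append(
            SpikeTrain(
                spike_times=np.sort(group["spike_time_ms"].to_numpy()),
                stim_time_ms=float(stim_by_trial[trial_id]),
                trial_id=str(trial_id),
            )
        )
    return trains
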