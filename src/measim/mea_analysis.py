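"""MEA signal-analysis chain: filtering, spike and network-burst detection.

The identical code path handles in vitro-style multichannel recordings and
simulated virtual-electrode signals: band-pass filter (100–3500 Hz, 5th-order
Butterworth, causal), amplitude-threshold spike detection at 4× the RMS of
each electrode's filtered trace, and network-burst (NB) detection on the
population spike rate.  A NB opens when the rate stays at or above 1/4 of the
recording's maximum rate for 60 ms, closes when the rate drops below 1/100 of
the maximum, and is discarded when more than 80% of its spikes come from a
single electrode.

Features: NBR (bursts/min), NBD (mean burst duration, s; undefined without
bursts), PSIB (% of spikes inside bursts) and MFR (spikes/s per electrode).

`synth_raster` generates surrogate spike rasters (Poisson background plus
synchronized burst epochs with known ground truth) for testing the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable constants of the analysis chain (defaults as used throughout)."""

    f_low: float = 100.0        # band-pass edges, Hz
    f_high: float = 3500.0
    filter_order: int = 5
    threshold_factor: float = 4.0  # spike threshold in units of trace RMS
    dead_time: float = 2e-3        # per-electrode detector lockout, s
    rate_bin: float = 10e-3        # population-rate bin, s
    smooth_bins: int = 3           # moving-average width for the rate trace
    open_fraction: float = 0.25    # NB opens at max_rate × this ...
    sustain: float = 60e-3         # ... sustained at least this long, s
    close_fraction: float = 0.01   # NB closes below max_rate × this
    single_electrode_fraction: float = 0.8  # NB exclusion rule


@dataclass
class SpikeTrainSet:
    """Per-electrode ordered spike times over one recording window."""

    trains: list[np.ndarray]   # seconds, strictly increasing per electrode
    duration: float            # s

    @property
    def n_electrodes(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.trains))

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All spikes sorted in time, with their electrode indices."""
        if self.n_spikes == 0:
            return np.zeros(0), np.zeros(0, dtype=int)
        times = np.concatenate(self.trains)
        elec = np.concatenate(
            [np.full(len(t), i, dtype=int) for i, t in enumerate(self.trains)]
        )
        order = np.argsort(times, kind="stable")
        return times[order], elec[order]

    def to_frame(self) -> pd.DataFrame:
        times, elec = self.pooled()
        return pd.DataFrame({"electrode": elec, "time_s": times})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, duration: float,
                   n_electrodes: int) -> "SpikeTrainSet":
        trains = [
            np.sort(df.loc[df["electrode"] == i, "time_s"].to_numpy(dtype=float))
            for i in range(n_electrodes)
        ]
        return cls(trains=trains, duration=duration)


@dataclass
class NetworkBurstSet:
    """Detected network-burst intervals with per-electrode spike counts."""

    intervals: list[tuple[float, float]]   # (start_s, end_s), ordered, disjoint
    electrode_counts: list[np.ndarray]     # spikes per electrode per burst

    @property
    def n_bursts(self) -> int:
        return len(self.intervals)

    @property
    def durations(self) -> np.ndarray:
        return np.array([e - s for s, e in self.intervals])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": [s for s, _ in self.intervals],
                "end_s": [e for _, e in self.intervals],
                "n_spikes": [int(c.sum()) for c in self.electrode_counts],
            }
        )


@dataclass
class FeatureVector:
    """Summary features of one recording."""

    NBR: float   # network bursts per minute
    NBD: float   # mean network-burst duration, s (NaN when no bursts)
    PSIB: float  # % of spikes inside network bursts
    MFR: float   # spikes per second per electrode


def bandpass_filter(
    signals: np.ndarray, fs: float, params: AnalysisParams = AnalysisParams()
) -> np.ndarray:
    """Causal 5th-order Butterworth band-pass, applied per channel."""
    if fs <= 2 * params.f_high:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {params.f_high} Hz band edge"
        )
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    b, a = butter(
        params.filter_order, [params.f_low, params.f_high], btype="bandpass", fs=fs
    )
    return lfilter(b, a, signals, axis=-1)


def detect_spikes(
    filtered: np.ndarray, fs: float, params: AnalysisParams = AnalysisParams()
) -> SpikeTrainSet:
    """Amplitude-threshold spike detection on filtered signals.

    Per electrode the threshold is ``threshold_factor`` × the RMS of the whole
    filtered trace; an event is the first sample of a suprathreshold
    excursion (either polarity), with a dead time so one action-potential
    waveform yields one event.
    """
    filtered = np.atleast_2d(np.asarray(filtered, dtype=float))
    dead = max(1, int(round(params.dead_time * fs)))
    trains = []
    for trace in filtered:
        rms = float(np.sqrt(np.mean(trace**2)))
        if rms == 0.0:
            trains.append(np.zeros(0))
            continue
        above = np.flatnonzero(np.abs(trace) > params.threshold_factor * rms)
        kept = []
        next_ok = -1
        for idx in above:
            if idx >= next_ok:
                kept.append(idx)
                next_ok = idx + dead
        trains.append(np.asarray(kept, dtype=float) / fs)
    return SpikeTrainSet(trains=trains, duration=filtered.shape[1] / fs)


def population_rate(
    spikes: SpikeTrainSet, params: AnalysisParams = AnalysisParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed population spike rate (spikes/s) on a uniform bin grid."""
    n_bins = max(1, int(np.ceil(spikes.duration / params.rate_bin)))
    edges = np.arange(n_bins + 1) * params.rate_bin
    times, _ = spikes.pooled()
    counts, _ = np.histogram(times, bins=edges)
    rate = counts / params.rate_bin
    if params.smooth_bins > 1:
        kernel = np.ones(params.smooth_bins) / params.smooth_bins
        rate = np.convolve(rate, kernel, mode="same")
    return edges[:-1], rate


def detect_network_bursts(
    spikes: SpikeTrainSet, params: AnalysisParams = AnalysisParams()
) -> NetworkBurstSet:
    """Threshold-based network-burst detection on the population rate.

    Opens where the rate holds ≥ max_rate×open_fraction for the sustain
    window, closes at the first bin below max_rate×close_fraction; the burst
    interval runs from the first sustained-above bin to the first below-close
    bin.  Bursts dominated (> 80% of spikes) by one electrode are excluded.
    """
    if spikes.duration <= 0:
        raise ValueError("recording duration must be positive")
    if spikes.n_spikes == 0:
        return NetworkBurstSet(intervals=[], electrode_counts=[])

    bin_starts, rate = population_rate(spikes, params)
    max_rate = float(rate.max())
    if max_rate <= 0:
        return NetworkBurstSet(intervals=[], electrode_counts=[])
    open_thr = max_rate * params.open_fraction
    close_thr = max_rate * params.close_fraction
    sustain_bins = max(1, int(round(params.sustain / params.rate_bin)))

    times, elec = spikes.pooled()
    n_elec = spikes.n_electrodes
    intervals: list[tuple[float, float]] = []
    counts: list[np.ndarray] = []

    n_bins = len(rate)
    i = 0
    while i < n_bins:
        if rate[i] >= open_thr:
            run = i
            while run < n_bins and rate[run] >= open_thr:
                run += 1
            if run - i >= sustain_bins:
                j = run
                while j < n_bins and rate[j] >= close_thr:
                    j += 1
                start = bin_starts[i]
                end = bin_starts[j] if j < n_bins else spikes.duration
                sel = (times >= start) & (times < end)
                c = np.bincount(elec[sel], minlength=n_elec).astype(float)
                total = c.sum()
                if total > 0 and (
                    c.max() / total <= params.single_electrode_fraction
                ):
                    intervals.append((float(start), float(end)))
                    counts.append(c)
                i = j
            else:
                i = run
        else:
            i += 1
    return NetworkBurstSet(intervals=intervals, electrode_counts=counts)


def compute_features(
    spikes: SpikeTrainSet,
    bursts: NetworkBurstSet,
    duration: float | None = None,
) -> FeatureVector:
    """NBR, NBD, PSIB and MFR from detected spikes and bursts.

    With zero bursts NBD is reported as NaN (missing, to avoid biasing means),
    NBR and PSIB as 0.
    """
    duration = float(duration if duration is not None else spikes.duration)
    if duration <= 0:
        raise ValueError("duration must be positive")
    nbr = bursts.n_bursts / duration * 60.0
    nbd = float(np.mean(bursts.durations)) if bursts.n_bursts else float("nan")
    total = spikes.n_spikes
    if total and bursts.n_bursts:
        times, _ = spikes.pooled()
        inside = np.zeros(len(times), dtype=bool)
        for s, e in bursts.intervals:
            inside |= (times >= s) & (times < e)
        psib = 100.0 * inside.sum() / total
    else:
        psib = 0.0
    mfr = total / (max(1, spikes.n_electrodes) * duration)
    return FeatureVector(NBR=nbr, NBD=nbd, PSIB=psib, MFR=mfr)


def analyze_signals(
    signals: np.ndarray,
    fs: float,
    params: AnalysisParams = AnalysisParams(),
) -> tuple[SpikeTrainSet, NetworkBurstSet, FeatureVector]:
    """Full chain on raw multichannel signals: filter → spikes → bursts → features."""
    filt = bandpass_filter(signals, fs, params)
    spikes = detect_spikes(filt, fs, params)
    bursts = detect_network_bursts(spikes, params)
    return spikes, bursts, compute_features(spikes, bursts)


def analyze_result(result, params: AnalysisParams = AnalysisParams()) -> FeatureVector:
    """Feature vector of one :class:`~measim.engine.SimulationResult`."""
    _, _, fv = analyze_signals(result.signals, result.fs, params)
    return fv


def load_external_recording(path) -> tuple[np.ndarray, float]:
    """Read an external multichannel recording from an HDF5 container.

    Expects one 2-D dataset (channels × samples) and a sampling-rate
    attribute ``fs`` (Hz) on the dataset or the file root.
    """
    import h5py

    with h5py.File(path, "r") as f:
        name = next(
            (k for k, v in f.items() if isinstance(v, h5py.Dataset) and v.ndim == 2),
            None,
        )
        if name is None:
            raise ValueError(f"{path}: no 2-D channels×samples dataset found")
        dset = f[name]
        fs = dset.attrs.get("fs", f.attrs.get("fs"))
        if fs is None:
            raise ValueError(f"{path}: missing sampling-rate attribute 'fs'")
        return dset[()], float(fs)


def load_spike_csv(path, duration: float | None = None,
                   n_electrodes: int = 12) -> SpikeTrainSet:
    """Read a per-electrode spike-time table (columns: electrode, time_s)."""
    df = pd.read_csv(path)
    if not {"electrode", "time_s"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'electrode' and 'time_s'")
    if duration is None:
        duration = float(df["time_s"].max()) + 1e-9 if len(df) else 1.0
    n_electrodes = max(n_electrodes, int(df["electrode"].max()) + 1 if len(df) else 0)
    return SpikeTrainSet.from_frame(df, duration=duration, n_electrodes=n_electrodes)


@dataclass(frozen=True)
class RasterSpec:
    """Specification of a surrogate spike raster with known ground truth."""

    duration: float = 100.0          # s
    n_electrodes: int = 12
    background_rate: float = 0.1     # Hz per electrode, Poisson
    epochs: tuple[tuple[float, float], ...] = ()  # synchronized burst windows, s
    epoch_rate: float = 50.0         # Hz per electrode inside an epoch
    jitter: float = 2e-3             # per-spike Gaussian jitter, s


def synth_raster(
    spec: RasterSpec, rng: np.random.Generator | int | None = None
) -> tuple[SpikeTrainSet, list[tuple[float, float]]]:
    """Poisson background plus synchronized burst epochs, with ground truth.

    Returns the spike trains and the true burst intervals for oracle
    comparison against the detector.
    """
    rng = np.random.default_rng(rng)
    trains = []
    for _ in range(spec.n_electrodes):
        n_bg = rng.poisson(spec.background_rate * spec.duration)
        t = list(rng.uniform(0.0, spec.duration, size=n_bg))
        for s, e in spec.epochs:
            n_ep = rng.poisson(spec.epoch_rate * (e - s))
            ep = rng.uniform(s, e, size=n_ep)
            if spec.jitter > 0:
                ep = ep + rng.normal(0.0, spec.jitter, size=n_ep)
            t.extend(np.clip(ep, 0.0, np.nextafter(spec.duration, 0.0)))
        arr = np.unique(np.asarray(t, dtype=float))
        trains.append(arr[(arr >= 0) & (arr < spec.duration)])
    return (
        SpikeTrainSet(trains=trains, duration=spec.duration),
        [tuple(ep) for ep in spec.epochs],
    )


def synth_voltage(
    spikes: SpikeTrainSet,
    fs: float,
    amplitude: float,
    noise_std: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Synthetic multichannel voltage: Gaussian noise plus biphasic impulses.

    Embeds a two-sample positive/negative impulse of the given amplitude at
    every spike time — a minimal stand-in for an extracellular AP waveform,
    used to exercise the filter + threshold detector end to end.
    """
    rng = np.random.default_rng(rng)
    n_samp = int(round(spikes.duration * fs))
    out = rng.normal(0.0, noise_std, size=(spikes.n_electrodes, n_samp))
    for ch, train in enumerate(spikes.trains):
        idx = np.round(train * fs).astype(int)
        idx = idx[idx < n_samp - 1]
        out[ch, idx] += amplitude
        out[ch, idx + 1] -= amplitude
    return out
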