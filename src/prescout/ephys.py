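"""Current-clamp sweep analysis and rule-based fast-spiking classification.

Implements the standard single-cell feature set from square-pulse
current-clamp protocols: resting membrane potential, input resistance from
the subthreshold V-I slope, spike detection, firing output over 800 ms
depolarizing steps, rheobase, single-AP waveform features (threshold by the
third-derivative maximum, max dV/dt, amplitude, half-width, fAHP), and
spike-frequency accommodation.  A cell is classified fast-spiking (FS) if it
meets at least three of four criteria: AP half-width < 0.5 ms, max firing
frequency > 50 Hz, fAHP amplitude > 15 mV, SFA < 2; otherwise
regular-spiking (RS).

Derivatives are numerically fragile on raw traces, so they are estimated
directly from a Savitzky-Golay local polynomial fit (0.5 ms window);
amplitude, half-width and fAHP are measured on the raw trace with
sub-sample linear interpolation for the half-width crossings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter


class SweepError(ValueError):
    """Raised on invalid sweep sets or protocols."""


class SpikeAnalysisError(RuntimeError):
    """Raised when a required spike/sweep for feature extraction is missing
    or the trace is unusable (e.g. clipped)."""


class SweepSet:
    """A family of current-step voltage traces from one cell.

    Parameters
    ----------
    sampling_rate : float, Hz (>= 10 kHz for AP analysis)
    stim_onset, stim_duration : float, seconds
    currents : 1-D array of injected currents, pA, strictly increasing
    voltages : 2-D array (n_sweeps, n_samples), mV
    """

    def __init__(self, sampling_rate, stim_onset, stim_duration, currents, voltages):
        self.sampling_rate = float(sampling_rate)
        self.stim_onset = float(stim_onset)
        self.stim_duration = float(stim_duration)
        self.currents = np.asarray(currents, dtype=float)
        self.voltages = np.asarray(voltages, dtype=float)
        if self.voltages.ndim != 2 or self.voltages.shape[0] != self.currents.size:
            raise SweepError("voltages must be (n_sweeps, n_samples) matching currents")
        if np.any(np.diff(self.currents) <= 0):
            raise SweepError("injected currents must be strictly increasing")
        if self.sampling_rate < 10_000:
            raise SweepError("sampling rate must be >= 10 kHz for AP analysis")
        if self.stim_onset < 0 or self.stim_duration <= 0:
            raise SweepError("invalid stimulus timing")

    @property
    def n_sweeps(self):
        return self.currents.size

    @property
    def times(self):
        return np.arange(self.voltages.shape[1]) / self.sampling_rate

    def sweep(self, current):
        idx = np.flatnonzero(np.isclose(self.currents, current))
        if idx.size == 0:
            raise SweepError(f"no sweep at {current} pA")
        return self.voltages[idx[0]]

    def _window(self, t0, t1):
        fs = self.sampling_rate
        return slice(max(0, int(round(t0 * fs))), int(round(t1 * fs)))


@dataclass(frozen=True)
class APFeatures:
    """Single-AP waveform features (first AP of the analysis sweep)."""

    threshold: float  # mV
    max_dvdt: float  # mV/ms
    amplitude: float  # mV, threshold to peak
    half_width: float  # ms, at half amplitude above threshold
    fahp: float  # mV, threshold to post-spike trough

    def __post_init__(self):
        if self.amplitude <= 0 or self.half_width <= 0:
            raise ValueError("amplitude and half-width must be positive")


@dataclass
class CellPhysiology:
    """Extracted physiology and FS/RS classification for one cell."""

    rmp: float | None = None  # mV
    rin: float | None = None  # MOhm
    rheobase: float | None = None  # pA
    firing_counts: dict = field(default_factory=dict)  # current pA -> spike count
    max_firing_frequency: float | None = None  # Hz (mean rate over the step)
    sfa: float | None = None  # last ISI / first ISI
    ap: APFeatures | None = None
    classification: str | None = None  # "FS" | "RS"
    criteria_met: dict = field(default_factory=dict)


def resting_membrane_potential(sweeps: SweepSet) -> float:
    """Mean voltage over the 50 ms baseline preceding the stimulus on the
    zero-current sweep."""
    v = sweeps.sweep(0.0)
    win = sweeps._window(sweeps.stim_onset - 0.050, sweeps.stim_onset)
    if win.stop - win.start < 2:
        raise SweepError("baseline window shorter than 2 samples")
    return float(v[win].mean())


def input_resistance(sweeps: SweepSet) -> float:
    """OLS slope of steady-state voltage deflection vs injected current.

    Deflection is mean of the last 100 ms of the step minus the 50 ms
    pre-stimulus baseline, per subthreshold (spike-free) sweep; the slope of
    dV (mV) against I (nA) is the input resistance in MOhm.  Requires at
    least three subthreshold sweeps.
    """
    base = sweeps._window(sweeps.stim_onset - 0.050, sweeps.stim_onset)
    t_end = sweeps.stim_onset + sweeps.stim_duration
    steady = sweeps._window(t_end - 0.100, t_end)
    dvs, cur = [], []
    for i in range(sweeps.n_sweeps):
        v = sweeps.voltages[i]
        if detect_spikes(v, sweeps.sampling_rate).size:
            continue
        dvs.append(v[steady].mean() - v[base].mean())
        cur.append(sweeps.currents[i])
    if len(dvs) < 3:
        raise SweepError(f"need >=3 subthreshold sweeps, got {len(dvs)}")
    slope = np.polyfit(np.asarray(cur) / 1000.0, np.asarray(dvs), 1)[0]  # mV / nA
    return float(slope)


def detect_spikes(trace, sampling_rate) -> np.ndarray:
    """Spike peak sample indices.

    A spike is a peak above 0 mV preceded by an upward crossing of -20 mV
    with dV/dt >= 10 mV/ms; accepted peaks are at least 1 ms apart (the
    earlier one wins).
    """
    v = np.asarray(trace, dtype=float)
    if v.size < 3:
        return np.array([], dtype=int)
    dvdt = np.diff(v) * sampling_rate / 1000.0  # mV/ms at i -> i+1
    up = np.flatnonzero((v[:-1] < -20.0) & (v[1:] >= -20.0) & (dvdt >= 10.0))
    down = np.flatnonzero((v[:-1] >= -20.0) & (v[1:] < -20.0)) + 1
    peaks = []
    min_gap = int(round(sampling_rate * 1e-3))
    for c in up:
        # follow the depolarization until it returns below -20 mV
        j = c + 1
        nxt = np.searchsorted(down, j)
        end = int(down[nxt]) if nxt < down.size else v.size
        if end <= j:
            continue
        pk = j + int(np.argmax(v[j:end]))
        if v[pk] <= 0.0:
            continue
        if peaks and pk - peaks[-1] < min_gap:
            continue
        peaks.append(pk)
    return np.array(peaks, dtype=int)


@dataclass
class FiringResult:
    counts: dict  # current pA -> spike count within the step
    frequencies: dict  # current pA -> Hz (count / stim_duration)
    rheobase: float | None  # pA; None if no sweep fired
    max_firing_frequency: float | None
    spike_times: dict  # current pA -> array of spike times (s, absolute)


def firing_analysis(sweeps: SweepSet) -> FiringResult:
    """Spike counts and rates per depolarizing step; rheobase; max rate.

    Counts cover the stimulus window; frequency is the mean rate over the
    step (count / stim_duration).
    """
    fs = sweeps.sampling_rate
    lo = int(round(sweeps.stim_onset * fs))
    hi = int(round((sweeps.stim_onset + sweeps.stim_duration) * fs))
    counts, freqs, times = {}, {}, {}
    rheo = None
    for i, cur in enumerate(sweeps.currents):
        pk = detect_spikes(sweeps.voltages[i], fs)
        pk = pk[(pk >= lo) & (pk < hi)]
        counts[float(cur)] = int(pk.size)
        freqs[float(cur)] = pk.size / sweeps.stim_duration
        times[float(cur)] = pk / fs
        if pk.size and (rheo is None):
            rheo = float(cur)
    maxf = max(freqs.values()) if any(counts.values()) else None
    return FiringResult(counts, freqs, rheo, maxf, times)


def _interp_crossing(t0, t1, v0, v1, level):
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_features(
    sweeps: SweepSet,
    rheobase: float,
    delta_pa: float = 50.0,
    smooth_window_ms: float = 0.5,
    smooth_polyorder: int = 3,
) -> APFeatures:
    """Waveform features of the first AP on the sweep 50 pA above rheobase.

    If no sweep sits exactly at rheobase + 50 pA, the nearest larger sweep
    is used (the largest available as a last resort).  Threshold is the
    voltage at the maximum of the third derivative of the smoothed trace
    within the 2 ms preceding the AP peak; amplitude is threshold to raw
    peak; half-width is measured between linearly interpolated crossings of
    threshold + amplitude/2; fAHP is threshold minus the trough between the
    peak and the next spike onset (capped at peak + 10 ms).
    """
    target = rheobase + delta_pa
    cands = sweeps.currents[sweeps.currents >= target - 1e-9]
    cur = float(cands[0]) if cands.size else float(sweeps.currents[-1])
    v = sweeps.sweep(cur)
    fs = sweeps.sampling_rate
    peaks = detect_spikes(v, fs)
    lo = int(round(sweeps.stim_onset * fs))
    hi = int(round((sweeps.stim_onset + sweeps.stim_duration) * fs))
    peaks = peaks[(peaks >= lo) & (peaks < hi)]
    if peaks.size == 0:
        raise SpikeAnalysisError(f"no spike on the {cur:g} pA sweep")
    pk = int(peaks[0])
    near = v[max(0, pk - int(0.5e-3 * fs)): pk + int(0.5e-3 * fs)]
    if np.sum(np.abs(near - v[pk]) < 1e-9) > max(3, int(0.3e-3 * fs)):
        raise SpikeAnalysisError("clipped/saturating trace at the AP peak")

    dt_ms = 1000.0 / fs
    win = int(round(smooth_window_ms * fs / 1000.0))
    win = max(smooth_polyorder + 4, win) | 1
    if win >= v.size:
        raise SpikeAnalysisError("trace too short to smooth")
    # derivatives straight from the local polynomial fit: cascaded finite
    # differences of a noisy trace drown the third derivative in noise
    d1 = savgol_filter(v, win, smooth_polyorder, deriv=1, delta=dt_ms)
    d3 = savgol_filter(v, win, smooth_polyorder + 2, deriv=3, delta=dt_ms)

    w0 = max(0, pk - int(round(2e-3 * fs)))
    if pk - w0 < 3:
        raise SpikeAnalysisError("AP peak too close to trace start")
    th_idx = w0 + int(np.argmax(d3[w0:pk]))
    # the smoothed-derivative argmax sits ~half a window early; a short
    # forward average of the raw trace recentres the estimate on the onset
    fwd = max(1, int(round(0.1e-3 * fs)))
    threshold = float(np.median(v[th_idx : th_idx + fwd]))
    max_dvdt = float(d1[th_idx : pk + 1].max())
    amplitude = float(v[pk] - threshold)
    if amplitude <= 0:
        raise SpikeAnalysisError("non-positive AP amplitude")

    # half-width on the raw trace, interpolated crossings of the half level
    level = threshold + amplitude / 2.0
    rise = None
    for i in range(pk, th_idx, -1):
        if v[i - 1] < level <= v[i]:
            rise = _interp_crossing((i - 1) * dt_ms, i * dt_ms, v[i - 1], v[i], level)
            break
    fall = None
    stop = int(peaks[1]) if peaks.size > 1 else min(v.size - 1, pk + int(round(10e-3 * fs)))
    for i in range(pk, stop):
        if v[i] >= level > v[i + 1]:
            fall = _interp_crossing(i * dt_ms, (i + 1) * dt_ms, v[i], v[i + 1], level)
            break
    if rise is None or fall is None:
        raise SpikeAnalysisError("could not locate half-amplitude crossings")
    half_width = float(fall - rise)

    # fAHP: trough between the peak and the next spike onset, <= 10 ms out
    end = min(v.size, pk + int(round(10e-3 * fs)))
    if peaks.size > 1:
        # walk back from the next peak to its -20 mV upward crossing (onset)
        j = int(peaks[1])
        while j > pk and v[j] > -20.0:
            j -= 1
        end = min(end, max(pk + 1, j))
    trough = float(v[pk:end].min())
    fahp = float(threshold - trough)
    return APFeatures(threshold, max_dvdt, amplitude, half_width, max(fahp, 0.0))


def spike_frequency_accommodation(spike_times) -> float:
    """Ratio of the last inter-spike interval to the first.

    Requires at least three spikes (two ISIs); invariant to uniform time
    rescaling and shifts.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 3:
        raise SpikeAnalysisError("SFA needs at least 3 spikes")
    isi = np.diff(np.sort(t))
    return float(isi[-1] / isi[0])


FS_CRITERIA = {
    "half_width_lt_0.5ms": lambda hw, mf, fahp, sfa: hw < 0.5,
    "max_rate_gt_50Hz": lambda hw, mf, fahp, sfa: mf > 50.0,
    "fahp_gt_15mV": lambda hw, mf, fahp, sfa: fahp > 15.0,
    "sfa_lt_2": lambda hw, mf, fahp, sfa: sfa is not None and sfa < 2.0,
}


def classify_fs_rs(half_width, max_firing_frequency, fahp, sfa):
    """FS if at least three of four criteria hold (strict inequalities):
    half-width < 0.5 ms, max firing frequency > 50 Hz, fAHP > 15 mV,
    SFA < 2.  If SFA is unavailable (too few spikes) the cell must meet all
    three remaining criteria to be called FS.

    Returns (label, criteria_met dict).
    """
    met = {
        name: bool(rule(half_width, max_firing_frequency, fahp, sfa))
        for name, rule in FS_CRITERIA.items()
    }
    if sfa is None:
        met.pop("sfa_lt_2")
        label = "FS" if all(met.values()) else "RS"
    else:
        label = "FS" if sum(met.values()) >= 3 else "RS"
    return label, met


def analyze_cell(firing_sweeps: SweepSet, rin_sweeps: SweepSet | None = None) -> CellPhysiology:
    """End-to-end single-cell analysis: firing, rheobase, AP features, SFA,
    and FS/RS classification.  SFA is measured on the maximal-firing sweep
    (needs >= 3 spikes there, else SFA is left undefined)."""
    phys = CellPhysiology()
    if rin_sweeps is not None:
        phys.rmp = resting_membrane_potential(rin_sweeps)
        phys.rin = input_resistance(rin_sweeps)
    fr = firing_analysis(firing_sweeps)
    phys.firing_counts = fr.counts
    phys.rheobase = fr.rheobase
    phys.max_firing_frequency = fr.max_firing_frequency
    if fr.rheobase is None:
        raise SpikeAnalysisError("cell fired no spikes on any sweep")
    best = max(fr.counts, key=lambda c: (fr.counts[c], -c))
    if fr.counts[best] >= 3:
        phys.sfa = spike_frequency_accommodation(fr.spike_times[best])
    phys.ap = ap_features(firing_sweeps, fr.rheobase)
    phys.classification, phys.criteria_met = classify_fs_rs(
        phys.ap.half_width, phys.max_firing_frequency, phys.ap.fahp, phys.sfa
    )
    return phys


# ---------------------------------------------------------------------------
# CSV I/O (long format: sweep_id, current_pA, time_s, voltage_mV)
# ---------------------------------------------------------------------------

def read_sweeps_csv(path, stim_onset, stim_duration) -> SweepSet:
    import pandas as pd

    df = pd.read_csv(path)
    need = {"sweep_id", "current_pA", "time_s", "voltage_mV"}
    if not need.issubset(df.columns):
        raise SweepError(f"CSV must have columns {sorted(need)}")
    sweeps = []
    for sid, grp in df.groupby("sweep_id"):
        grp = grp.sort_values("time_s")
        sweeps.append((float(grp["current_pA"].iloc[0]), grp["voltage_mV"].to_numpy(),
                       grp["time_s"].to_numpy()))
    sweeps.sort(key=lambda s: s[0])
    t = sweeps[0][2]
    fs = 1.0 / np.median(np.diff(t))
    currents = [s[0] for s in sweeps]
    voltages = np.vstack([s[1] for s in sweeps])
    return SweepSet(fs, stim_onset, stim_duration, currents, voltages)


def write_sweeps_csv(sweeps: SweepSet, path) -> None:
    import pandas as pd

    t = sweeps.times
    frames = []
    for i, cur in enumerate(sweeps.currents):
        frames.append(
            pd.DataFrame(
                {
                    "sweep_id": i,
                    "current_pA": cur,
                    "time_s": t,
                    "voltage_mV": sweeps.voltages[i],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
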