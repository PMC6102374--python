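"""Feature extraction from voltage traces and network spike trains.

Uncertainty quantification of a neural model is often more informative on
salient response features (spike count, AP width, interspike-interval
statistics, ...) than on the raw voltage trace, whose point-to-point
values vary with spike timing.  This module provides

* spike detection on a voltage trace (``find_spikes``) and the seven
  classical spiking features derived from it,
* conversion of network spike trains to regular binary (0/1) sequences,
* thirteen network features (rates, ISI statistics, Fano factor,
  Victor-Purpura and van Rossum distances, binned-train correlations),
* small feature-set classes that plug into the ensemble runner: a
  ``preprocess`` step shared by all features of a set, followed by the
  individual feature functions.

A feature that is undefined for a particular model evaluation (e.g. the
afterhyperpolarization depth of a trace with fewer than two spikes)
returns ``None``; that evaluation is flagged invalid for this feature and
handled by the UQ method's invalid-evaluation policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Spike",
    "Spikes",
    "SpikeTrainSet",
    "find_spikes",
    "spiking_features",
    "binary_spike_postprocess",
    "network_features",
    "victor_purpura_distance",
    "van_rossum_distance",
    "FeatureSet",
    "SpikingFeatures",
    "NetworkFeatures",
]

SPIKING_FEATURE_NAMES = (
    "nr_spikes", "spike_rate", "time_before_first_spike",
    "accommodation_index", "average_AP_overshoot", "average_AHP_depth",
    "average_AP_width",
)

NETWORK_FEATURE_NAMES = (
    "average_firing_rate", "instantaneous_rate", "average_isi", "cv",
    "average_cv", "local_variation", "average_local_variation",
    "fanofactor", "victor_purpura_dist", "van_rossum_dist", "binned_isi",
    "corrcoef", "covariance",
)


# ---------------------------------------------------------------------------
# spikes in a voltage trace
# ---------------------------------------------------------------------------

@dataclass
class Spike:
    """One detected action potential: a brief trace window around the peak."""

    time: np.ndarray        # time samples of the window
    V: np.ndarray           # voltage samples of the window
    peak_time: float
    peak_voltage: float
    onset_index: int        # index (within the window) of the threshold crossing

    @property
    def onset_voltage(self) -> float:
        return float(self.V[self.onset_index])


class Spikes:
    """Ordered container of detected spikes plus the source trace."""

    def __init__(self, spikes: Sequence[Spike], time: np.ndarray,
                 V: np.ndarray):
        self.spikes = list(spikes)
        self.time = np.asarray(time, float)
        self.V = np.asarray(V, float)

    def __len__(self):
        return len(self.spikes)

    def __iter__(self):
        return iter(self.spikes)

    def __getitem__(self, i):
        return self.spikes[i]

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([s.peak_time for s in self.spikes])


def find_spikes(time, V, threshold: float = -30.0,
                extent_before: float = 5.0,
                extent_after: float = 5.0) -> Spikes:
    """Detect action potentials as contiguous super-threshold excursions.

    One spike is reported per excursion, with the peak at the maximum of
    the excursion and a window spanning up to ``extent_before``/
    ``extent_after`` (same units as ``time``) around the peak.  Windows
    are truncated at the midpoints between adjacent peaks so they never
    overlap, and always include the upward threshold crossing.
    Deterministic; requires strictly increasing time.
    """
    time = np.asarray(time, float)
    V = np.asarray(V, float)
    if time.shape != V.shape:
        raise ValueError("time and V must have equal length")
    if time.size > 1 and np.any(np.diff(time) <= 0):
        raise ValueError("time axis must be strictly increasing")
    above = V > threshold
    if not np.any(above):
        return Spikes([], time, V)
    # rising/falling edges of the super-threshold mask
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(V.size)
    peaks = [s + int(np.argmax(V[s:e])) for s, e in zip(starts, ends)]

    spikes = []
    for k, (start, peak) in enumerate(zip(starts, peaks)):
        t_peak = time[peak]
        lo_t = t_peak - extent_before
        hi_t = t_peak + extent_after
        if k > 0:
            lo_t = max(lo_t, 0.5 * (time[peaks[k - 1]] + t_peak))
        if k + 1 < len(peaks):
            hi_t = min(hi_t, 0.5 * (t_peak + time[peaks[k + 1]]))
        lo = int(np.searchsorted(time, lo_t, side="left"))
        hi = int(np.searchsorted(time, hi_t, side="right"))
        lo = min(lo, start)            # window must contain the crossing
        window_t = time[lo:hi]
        window_v = V[lo:hi]
        spikes.append(Spike(time=window_t, V=window_v, peak_time=float(t_peak),
                            peak_voltage=float(V[peak]),
                            onset_index=start - lo))
    return Spikes(spikes, time, V)


# ---------------------------------------------------------------------------
# spiking features
# ---------------------------------------------------------------------------

def _ap_width(spike: Spike) -> float | None:
    """Width of one AP at the voltage midway between onset and peak."""
    v_half = 0.5 * (spike.onset_voltage + spike.peak_voltage)
    t, v = spike.time, spike.V
    peak_idx = int(np.argmax(v))
    up = None
    for i in range(peak_idx, 0, -1):        # walk left from the peak
        if v[i - 1] <= v_half <= v[i]:
            frac = (v_half - v[i - 1]) / (v[i] - v[i - 1]) if v[i] != v[i - 1] else 0.0
            up = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    down = None
    for i in range(peak_idx, v.size - 1):   # walk right from the peak
        if v[i] >= v_half >= v[i + 1]:
            frac = (v[i] - v_half) / (v[i] - v[i + 1]) if v[i] != v[i + 1] else 0.0
            down = t[i] + frac * (t[i + 1] - t[i])
            break
    if up is None or down is None:
        return None
    return down - up


def spiking_features(spikes: Spikes, info: dict,
                     isi_discard: int | None = None) -> dict:
    """The seven classical spiking features of a voltage trace.

    Requires ``info["stimulus_start"]`` and ``info["stimulus_end"]``.
    Features that are undefined for the observed spike count return
    ``None`` (e.g. the afterhyperpolarization depth needs two spikes,
    the accommodation index enough interspike intervals).

    ``isi_discard`` is the number of initial interspike intervals
    excluded from the accommodation index; by default 0 when fewer than
    five ISIs are available and 1 otherwise.
    """
    for key in ("stimulus_start", "stimulus_end"):
        if info is None or key not in info:
            raise KeyError(f"spiking features require info[{key!r}]")
    t_on = info["stimulus_start"]
    t_off = info["stimulus_end"]
    peaks = spikes.peak_times
    in_stim = peaks[(peaks >= t_on) & (peaks <= t_off)]
    out: dict[str, float | None] = {}
    out["nr_spikes"] = float(in_stim.size)
    out["spike_rate"] = in_stim.size / (t_off - t_on)
    out["time_before_first_spike"] = (float(in_stim[0] - t_on)
                                      if in_stim.size else None)

    isis = np.diff(peaks)
    if isi_discard is None:
        isi_discard = 0 if isis.size < 5 else 1
    kept = isis[isi_discard:]
    if kept.size >= 2:
        pairs = (kept[1:] - kept[:-1]) / (kept[1:] + kept[:-1])
        out["accommodation_index"] = float(np.mean(pairs))
    else:
        out["accommodation_index"] = None

    if len(spikes):
        out["average_AP_overshoot"] = float(
            np.mean([s.peak_voltage for s in spikes]))
    else:
        out["average_AP_overshoot"] = None

    if len(spikes) >= 2:
        # global minimum of the source trace between consecutive peaks
        mins = []
        full_t, full_v = spikes.time, spikes.V
        for a, b in zip(peaks[:-1], peaks[1:]):
            seg = full_v[(full_t > a) & (full_t < b)]
            if seg.size:
                mins.append(seg.min())
        out["average_AHP_depth"] = float(np.mean(mins)) if mins else None
    else:
        out["average_AHP_depth"] = None

    widths = [w for w in (_ap_width(s) for s in spikes) if w is not None]
    out["average_AP_width"] = float(np.mean(widths)) if widths else None
    return out


# ---------------------------------------------------------------------------
# spike trains of a network
# ---------------------------------------------------------------------------

class SpikeTrainSet:
    """Spike-time sequences (ms) of recorded units over [0, end]."""

    def __init__(self, trains: Sequence[np.ndarray], end: float,
                 resolution: float | None = None):
        self.trains = [np.sort(np.asarray(t, float).ravel()) for t in trains]
        self.end = float(end)
        self.resolution = resolution
        for t in self.trains:
            if t.size and (t[0] < 0 or t[-1] > self.end):
                raise ValueError("spike times must lie in [0, end]")

    def __len__(self):
        return len(self.trains)

    def __iter__(self):
        return iter(self.trains)

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trains])

    def to_text(self, path):
        """One unit per line, whitespace-separated spike times in ms.

        A leading comment line records the simulation end time.
        """
        lines = [f"# end {self.end!r}"]
        for t in self.trains:
            lines.append(" ".join(f"{x:.6f}" for x in t))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path) -> "SpikeTrainSet":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("# end"):
            raise ValueError("missing '# end <t>' header line")
        end = float(lines[0].split()[2])
        trains = [np.array([float(x) for x in line.split()])
                  for line in lines[1:]]
        return cls(trains, end=end)


def binary_spike_postprocess(trains: SpikeTrainSet, dt: float):
    """Convert spike trains to regular binary sequences.

    The grid is 0, dt, ..., floor(end/dt)*dt; a bin is 1 if at least one
    spike maps to it.  A spike at time s maps to bin round(s/dt), ties at
    bin edges rounding half up.  Returns (grid, matrix) with the matrix
    of shape (n_units, len(grid)).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_bins = int(np.floor(trains.end / dt)) + 1
    grid = np.arange(n_bins) * dt
    out = np.zeros((len(trains), n_bins), dtype=int)
    for i, t in enumerate(trains):
        if t.size and t[-1] > trains.end:
            raise ValueError("spike time beyond simulation end")
        idx = np.floor(t / dt + 0.5).astype(int)
        idx = idx[idx < n_bins]           # a spike exactly at `end` may round up
        out[i, idx] = 1
    return grid, out


def victor_purpura_distance(a: np.ndarray, b: np.ndarray,
                            cost: float = 0.2) -> float:
    """Victor-Purpura spike-train edit distance.

    Inserting or deleting a spike costs 1; moving a spike by dt costs
    ``cost * |dt|``.  ``cost`` has units 1/ms; the default 0.2/ms makes a
    5 ms shift as expensive as a deletion-insertion pair is cheap.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n, m = a.size, b.size
    prev = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        cur = np.empty(m + 1)
        cur[0] = i
        for j in range(1, m + 1):
            cur[j] = min(prev[j] + 1.0, cur[j - 1] + 1.0,
                         prev[j - 1] + cost * abs(a[i - 1] - b[j - 1]))
        prev = cur
    return float(prev[m])


def van_rossum_distance(a: np.ndarray, b: np.ndarray,
                        tau: float = 10.0) -> float:
    """Van Rossum distance with a causal exponential kernel of width tau.

    Each spike is convolved with e^{-t/tau} (t >= 0) and the L2 distance
    of the resulting functions, normalized by tau, is returned in closed
    form: d^2 = (Saa + Sbb - 2 Sab) / 2 with
    S_xy = sum_ij exp(-|x_i - y_j| / tau).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)

    def cross(x, y):
        if x.size == 0 or y.size == 0:
            return 0.0
        return float(np.sum(np.exp(-np.abs(x[:, None] - y[None, :]) / tau)))

    d2 = 0.5 * (cross(a, a) + cross(b, b) - 2.0 * cross(a, b))
    return float(np.sqrt(max(d2, 0.0)))


def network_features(trains: SpikeTrainSet, end_time: float | None = None,
                     rate_window: float = 10.0, rate_step: float = 1.0,
                     vp_cost: float = 0.2, vr_tau: float = 10.0,
                     bin_width: float | None = None,
                     isi_bins: int = 10) -> dict:
    """The thirteen network features of a set of recorded spike trains.

    Per-unit features are vectors over units; pairwise features are
    symmetric matrices over units; ``instantaneous_rate`` is a
    (time, rate) series; entries that need more interspike intervals
    than a train provides are NaN, and a feature undefined for every
    unit is ``None``.  ``bin_width`` (ms) for the binned-train
    correlation and covariance defaults to the spike trains' recorded
    resolution, falling back to 1 ms.
    """
    if len(trains) == 0:
        raise ValueError("need at least one recorded spike train")
    end = float(end_time if end_time is not None else trains.end)
    n = len(trains)
    duration_s = end / 1000.0
    out: dict = {}

    counts = trains.counts()
    out["average_firing_rate"] = counts / duration_s      # Hz, per unit

    grid = np.arange(0.0, end + rate_step / 2, rate_step)
    rates = np.zeros((n, grid.size))
    half = rate_window / 2.0
    for i, t in enumerate(trains):
        rates[i] = (np.searchsorted(t, grid + half, side="left")
                    - np.searchsorted(t, grid - half, side="left"))
    out["instantaneous_rate"] = (grid, rates.mean(axis=0) / (rate_window / 1000.0))

    isis = [np.diff(t) for t in trains]
    unit_mean_isi = np.array([i.mean() if i.size else np.nan for i in isis])
    out["average_isi"] = (float(np.nanmean(unit_mean_isi))
                          if np.any(np.isfinite(unit_mean_isi)) else None)

    cv = np.full(n, np.nan)
    lv = np.full(n, np.nan)
    for i, isi in enumerate(isis):
        if isi.size >= 2:
            cv[i] = isi.std(ddof=0) / isi.mean()
            ratio = ((isi[:-1] - isi[1:]) / (isi[:-1] + isi[1:]))**2
            lv[i] = 3.0 * np.mean(ratio)
    out["cv"] = cv
    out["average_cv"] = float(np.nanmean(cv)) if np.any(np.isfinite(cv)) else None
    out["local_variation"] = lv
    out["average_local_variation"] = (float(np.nanmean(lv))
                                      if np.any(np.isfinite(lv)) else None)

    mean_count = counts.mean()
    out["fanofactor"] = (float(counts.var(ddof=0) / mean_count)
                         if mean_count > 0 else None)

    vp = np.zeros((n, n))
    vr = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vp[i, j] = vp[j, i] = victor_purpura_distance(
                trains.trains[i], trains.trains[j], cost=vp_cost)
            vr[i, j] = vr[j, i] = van_rossum_distance(
                trains.trains[i], trains.trains[j], tau=vr_tau)
    out["victor_purpura_dist"] = vp
    out["van_rossum_dist"] = vr

    pooled = np.concatenate(isis) if any(i.size for i in isis) else np.array([])
    if pooled.size:
        hist, _ = np.histogram(pooled, bins=isi_bins, range=(0.0, end))
        out["binned_isi"] = hist.astype(float)
    else:
        out["binned_isi"] = np.zeros(isi_bins)

    if bin_width is None:
        bin_width = trains.resolution or 1.0
    _, binned = binary_spike_postprocess(trains, dt=bin_width)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["corrcoef"] = np.corrcoef(binned)
    out["covariance"] = np.cov(binned)
    return out


# ---------------------------------------------------------------------------
# feature sets pluggable into the ensemble runner
# ---------------------------------------------------------------------------

class FeatureSet:
    """A named collection of feature functions with a shared preprocess.

    ``preprocess(time, values, info)`` turns one model evaluation into
    the arguments handed to each feature function; a feature function
    returns ``(time_feature, values_feature)`` where either may be
    ``None`` (no time axis / undefined feature).
    """

    def __init__(self, features: dict[str, Callable] | None = None,
                 features_to_run="all"):
        self.features = dict(features or {})
        if features_to_run == "all":
            self.features_to_run = list(self.features)
        else:
            unknown = set(features_to_run) - set(self.features)
            if unknown:
                raise ValueError(f"unknown features: {sorted(unknown)}")
            self.features_to_run = list(features_to_run)

    def add(self, func: Callable, name: str | None = None):
        name = name or func.__name__
        self.features[name] = func
        self.features_to_run.append(name)

    def preprocess(self, time, values, info):
        return time, values, info

    def calculate(self, time, values, info) -> dict:
        """All selected features for one model evaluation.

        Returns name -> (time_feature, values_feature); an exception or a
        ``None`` result marks the feature evaluation invalid (``values``
        None).
        """
        pre = self.preprocess(time, values, info)
        out = {}
        for name in self.features_to_run:
            try:
                res = self.features[name](*pre)
            except Exception:
                res = None
            if res is None:
                out[name] = (None, None)
                continue
            t_f, v_f = res
            out[name] = (t_f, v_f)
        return out


class SpikingFeatures(FeatureSet):
    """The seven spiking features, computed from detected spikes.

    ``threshold`` is the absolute detection voltage; -30 mV suits traces
    on the physiological scale, while models using the original
    0-mV-resting convention should pass a value well above their
    baseline (e.g. +20 mV).
    """

    def __init__(self, threshold: float = -30.0, extent_before: float = 5.0,
                 extent_after: float = 5.0, features_to_run="all",
                 isi_discard: int | None = None):
        self.threshold = threshold
        self.extent_before = extent_before
        self.extent_after = extent_after
        self.isi_discard = isi_discard

        def make(name):
            def feature(time, spikes, info):
                value = spiking_features(spikes, info,
                                         isi_discard=self.isi_discard)[name]
                return None if value is None else (None, value)
            feature.__name__ = name
            return feature

        super().__init__({name: make(name) for name in SPIKING_FEATURE_NAMES},
                         features_to_run=features_to_run)

    def preprocess(self, time, values, info):
        spikes = find_spikes(time, values, threshold=self.threshold,
                             extent_before=self.extent_before,
                             extent_after=self.extent_after)
        return time, spikes, info


class NetworkFeatures(FeatureSet):
    """Scalar network features of a SpikeTrainSet-valued model.

    Matrix-valued features are reduced to regular form for the UQ:
    pairwise distance/correlation matrices contribute their
    upper-triangle entries as a fixed-length vector.
    """

    def __init__(self, features_to_run="all", **options):
        self.options = options

        scalars = ("average_isi", "average_cv", "average_local_variation",
                   "fanofactor")
        vectors = ("average_firing_rate", "cv", "local_variation",
                   "binned_isi")
        pairwise = ("victor_purpura_dist", "van_rossum_dist", "corrcoef",
                    "covariance")

        def make(name):
            def feature(end_time, trains):
                value = network_features(trains, end_time=end_time,
                                         **self.options)[name]
                if value is None:
                    return None
                if name == "instantaneous_rate":
                    return value            # (time, rate) series
                if name in pairwise:
                    iu = np.triu_indices(len(trains), k=1)
                    return None, np.asarray(value)[iu]
                return None, value
            feature.__name__ = name
            return feature

        names = scalars + vectors + pairwise + ("instantaneous_rate",)
        super().__init__({name: make(name) for name in names},
                         features_to_run=features_to_run)

    def preprocess(self, time, values, info):
        if not isinstance(values, SpikeTrainSet):
            raise TypeError("network features expect a SpikeTrainSet output")
        end = values.end
        if info and "end_time" in info:
            end = info["end_time"]
        return end, values
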