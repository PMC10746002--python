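"""Spike detection, burst segmentation and firing-pattern classification.

Spikes are prominent local maxima of the membrane potential x(t); bursts are
runs of spikes separated by long gaps, identified from bimodality of the
inter-spike-interval (ISI) distribution.  The periodic/chaotic call is made
from the leading Lyapunov exponent, not from the spike train itself, so the
labels stay consistent with the dynamics modules.

The taxonomy: quiescent (fixed point), subthreshold_oscillation (a driven
limit cycle that never crosses the spike threshold), periodic_spiking,
periodic_bursting, chaotic_spiking, chaotic_bursting, plus indeterminate when
the exponent sits inside the numerical zero band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .integration import Trajectory
from .lyapunov import classify_le1

__all__ = ["SpikeTrain", "FiringPattern", "detect_spikes", "segment_bursts",
           "classify_firing"]

DEFAULT_HEIGHT_MIN = 0.0
#: true action potentials in this model rise >2 x-units above the local
#: envelope while drive-induced subthreshold ripples stay below ~1.1
DEFAULT_PROMINENCE_MIN = 1.5
DEFAULT_MIN_SEPARATION = 0.5
#: groups must average at least this many spikes to count as bursting
MIN_MEAN_BURST_SIZE = 2.0
#: two drive tones count as a high-low pair past this frequency ratio
TIMESCALE_SEPARATION = 5.0
#: an ISI longer than this multiple of the intra-burst ISI opens a new burst
BURST_GAP_RATIO = 3.0
#: peak amplitudes closer than this are one periodic cluster (x units)
PERIOD_CLUSTER_TOL = 1e-2


@dataclass(frozen=True)
class SpikeTrain:
    spike_times: np.ndarray
    peak_values: np.ndarray

    @property
    def isi(self) -> np.ndarray:
        return np.diff(self.spike_times)

    @property
    def n(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class FiringPattern:
    label: str
    period_count: int | None = None
    spikes_per_burst: int | None = None
    le1: float | None = None
    #: coefficient of variation of intra-burst ISIs (irregularity descriptor)
    intra_burst_isi_cv: float | None = None


def detect_spikes(traj: Trajectory,
                  height_min: float = DEFAULT_HEIGHT_MIN,
                  prominence_min: float = DEFAULT_PROMINENCE_MIN,
                  min_separation: float = DEFAULT_MIN_SEPARATION) -> SpikeTrain:
    """Spikes = local maxima of x with height and topographic prominence
    thresholds and a minimum separation.

    Peak times/values are refined by a parabolic fit through the three
    samples around each discrete maximum, so peak amplitudes are accurate to
    well below the sampling quantization.
    """
    x = traj.x
    dt = float(traj.t[1] - traj.t[0]) if len(traj.t) > 1 else 1.0
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(x, height=height_min, prominence=prominence_min,
                        distance=distance)
    times = np.empty(len(idx))
    vals = np.empty(len(idx))
    for j, i in enumerate(idx):
        if 0 < i < len(x) - 1:
            a = 0.5 * (x[i - 1] + x[i + 1]) - x[i]
            b = 0.5 * (x[i + 1] - x[i - 1])
            off = -b / (2 * a) if a < 0 else 0.0
            off = min(0.5, max(-0.5, off))
            times[j] = traj.t[i] + off * dt
            vals[j] = x[i] + b * off + a * off * off
        else:
            times[j] = traj.t[i]
            vals[j] = x[i]
    return SpikeTrain(spike_times=times, peak_values=vals)


def segment_bursts(train: SpikeTrain,
                   gap_ratio: float = BURST_GAP_RATIO) -> list[np.ndarray]:
    """Split a spike train into bursts at long inter-spike gaps.

    The ISI distribution is bimodal in bursting regimes; an ISI exceeding
    ``gap_ratio`` times the median of the short-ISI mode starts a new burst.
    A unimodal (tonic) train comes back as a single segment.  Requires at
    least 4 spikes; fewer raises ValueError (quiescent/indeterminate signal).
    """
    if train.n < 4:
        raise ValueError("too few spikes to segment (quiescent or "
                         "indeterminate signal)")
    isi = train.isi
    med_low = np.median(isi[isi <= np.median(isi)])
    threshold = gap_ratio * med_low
    if isi.max() < threshold:
        return [np.arange(train.n)]
    breaks = np.flatnonzero(isi >= threshold) + 1
    return [seg for seg in np.split(np.arange(train.n), breaks)]


def _amplitude_clusters(values: np.ndarray,
                        tol: float = PERIOD_CLUSTER_TOL) -> int:
    """Number of distinct amplitude levels, merging values within tol."""
    if len(values) == 0:
        return 0
    v = np.sort(values)
    return int(1 + np.sum(np.diff(v) > tol))


def classify_firing(traj: Trajectory, train: SpikeTrain | None = None,
                    bursts: list[np.ndarray] | None = None,
                    le1: float | None = None,
                    quiescent_rate: float = 1e-3,
                    quiescent_var: float = 1e-4) -> FiringPattern:
    """Classify the firing pattern of a post-transient trajectory.

    Periodic vs chaotic comes from the sign of le1 (with the numerical zero
    band mapped to 'indeterminate'); spiking vs bursting from ISI
    bimodality; the period count of a periodic tonic train from clustering
    of the spike peak amplitudes.  For bursting patterns the modal
    spikes-per-burst and the intra-burst ISI dispersion are reported.
    """
    if train is None:
        train = detect_spikes(traj)
    duration = float(traj.t[-1] - traj.t[0])
    rate = train.n / duration if duration > 0 else 0.0
    tail = traj.states[len(traj) // 2:]

    if train.n < 4:
        if float(np.var(tail[:, 0])) < quiescent_var:
            return FiringPattern(label="quiescent", le1=le1)
        return FiringPattern(label="subthreshold_oscillation", le1=le1)
    if rate < quiescent_rate:
        return FiringPattern(label="quiescent", le1=le1)

    if bursts is None:
        bursts = segment_bursts(train)
    sizes = np.array([len(b) for b in (bursts[1:-1] if len(bursts) > 2
                                       else bursts)])
    bursting = len(bursts) > 1 and sizes.mean() >= MIN_MEAN_BURST_SIZE
    # under a high-low frequency drive, bursting means the spike groups are
    # locked to the slow cycle (one burst per slow period); incidental
    # clustering at a fraction of the slow rate is chaotic spiking
    d = traj.drive
    tones = [f for A, f in ((d.A1, d.f1), (d.A2, d.f2)) if A != 0 and f > 0]
    if bursting and len(tones) == 2 \
            and max(tones) / min(tones) >= TIMESCALE_SEPARATION:
        group_rate = len(bursts) / duration
        bursting = 0.5 <= group_rate / min(tones) <= 2.5

    rhythm = classify_le1(le1) if le1 is not None else "indeterminate"
    if rhythm == "indeterminate":
        prefix = "indeterminate"
    elif rhythm == "chaotic":
        prefix = "chaotic"
    else:
        prefix = "periodic"

    if bursting:
        intra = np.concatenate([train.isi[b[:-1]] for b in bursts if len(b) > 1]) \
            if any(len(b) > 1 for b in bursts) else np.array([])
        cv = float(np.std(intra) / np.mean(intra)) if len(intra) > 1 else None
        return FiringPattern(label=f"{prefix}_bursting",
                             spikes_per_burst=int(round(np.median(sizes))),
                             le1=le1, intra_burst_isi_cv=cv)
    period = _amplitude_clusters(train.peak_values) if prefix == "periodic" else None
    return FiringPattern(label=f"{prefix}_spiking", period_count=period,
                         le1=le1)
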