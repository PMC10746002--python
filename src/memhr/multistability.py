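"""Coexisting-attractor detection, elimination threshold, convergence time.

Two trajectories started from different initial conditions are compared via
an attractor *fingerprint*: the leading Lyapunov exponent, the mean and
standard deviation of x, a fixed-binning normalized ISI histogram and the set
of spike peak-amplitude clusters.  Distinct long-run fingerprints mean
coexisting attractors (multistability); when strongly negative memristor
coupling makes every initial condition converge to one attractor, the
fingerprints merge and a convergence (merging) time can be read off by
sliding a window over the transient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParams, DriveParams
from .integration import Trajectory, integrate, discard_transient
from .lyapunov import lyapunov_spectrum
from .firing import detect_spikes, _amplitude_clusters

__all__ = ["AttractorFingerprint", "fingerprint", "fingerprint_distance",
           "detect_coexistence", "convergence_time", "elimination_threshold",
           "CoexistenceResult", "ThresholdResult"]

#: ISI histogram binning shared by every fingerprint (dimensionless time)
ISI_BINS = np.concatenate([np.linspace(0.0, 50.0, 26), [np.inf]])
#: fingerprints farther apart than this are distinct attractors
COEXISTENCE_TOL = 0.25
#: looser tolerance for short windowed fingerprints (no LE term, more noise)
WINDOW_TOL = 0.5
DEFAULT_WINDOW = 50.0


@dataclass(frozen=True)
class AttractorFingerprint:
    le1: float | None
    mean_x: float
    std_x: float
    isi_hist: np.ndarray  # normalized; zero vector when < 2 spikes
    peak_clusters: int


def fingerprint(traj: Trajectory, le1: float | None = None,
                min_duration: float = 500.0) -> AttractorFingerprint:
    """Deterministic long-run summary of a post-transient trajectory."""
    duration = float(traj.t[-1] - traj.t[0])
    if duration < min_duration:
        raise ValueError(f"trajectory too short for a fingerprint "
                         f"({duration:.0f} < {min_duration:.0f} time units)")
    return _fingerprint_nocheck(traj, le1)


def _fingerprint_nocheck(traj: Trajectory, le1: float | None) -> AttractorFingerprint:
    train = detect_spikes(traj)
    if train.n >= 2:
        hist, _ = np.histogram(train.isi, bins=ISI_BINS)
        hist = hist / hist.sum()
    else:
        hist = np.zeros(len(ISI_BINS) - 1)
    return AttractorFingerprint(
        le1=le1,
        mean_x=float(traj.x.mean()),
        std_x=float(traj.x.std()),
        isi_hist=hist,
        peak_clusters=_amplitude_clusters(train.peak_values, tol=0.05),
    )


def fingerprint_distance(fa: AttractorFingerprint,
                         fb: AttractorFingerprint) -> float:
    """Weighted distance: |dLE1| + |d mean| + |d std| + L1(hist)/2.

    The LE term is skipped when either side lacks an exponent (windowed
    fingerprints).  The histogram term is in [0, 1].
    """
    d = abs(fa.mean_x - fb.mean_x) + abs(fa.std_x - fb.std_x)
    d += 0.5 * float(np.abs(fa.isi_hist - fb.isi_hist).sum())
    if fa.le1 is not None and fb.le1 is not None:
        d += abs(fa.le1 - fb.le1)
    return d


@dataclass(frozen=True)
class CoexistenceResult:
    coexists: bool
    distance: float
    fingerprints: tuple[AttractorFingerprint, AttractorFingerprint]


def _long_run_fingerprint(params, drive, ic, t_end, with_le1=True):
    traj = integrate(params, drive, ic, (0.0, t_end))
    tail = discard_transient(traj, t_end / 2)
    le1 = None
    if with_le1:
        le1 = lyapunov_spectrum(params, drive, ic, t_transient=t_end / 2,
                                t_horizon=max(2000.0, t_end / 2),
                                renorm_dt=1.0).le1
    return _fingerprint_nocheck(tail, le1), traj


def detect_coexistence(params: ModelParams, drive: DriveParams,
                       ic_pair, t_end: float = 2000.0,
                       tol: float = COEXISTENCE_TOL) -> CoexistenceResult:
    """Do two initial conditions settle onto distinct attractors?

    Each IC is integrated to ``t_end``; fingerprints are computed on the
    final 50% of each run and compared.  Symmetric in the pair by
    construction.
    """
    ic_a, ic_b = ic_pair
    fa, _ = _long_run_fingerprint(params, drive, ic_a, t_end)
    fb, _ = _long_run_fingerprint(params, drive, ic_b, t_end)
    dist = fingerprint_distance(fa, fb)
    return CoexistenceResult(coexists=bool(dist > tol), distance=dist,
                             fingerprints=(fa, fb))


def _window_fingerprints(traj: Trajectory, window: float, hop: float):
    """(start_times, fingerprints) for sliding windows over a trajectory."""
    starts = np.arange(traj.t[0], traj.t[-1] - window + 1e-9, hop)
    fps = []
    for s in starts:
        i0 = int(np.searchsorted(traj.t, s - 1e-12))
        i1 = int(np.searchsorted(traj.t, s + window + 1e-12))
        sub = Trajectory(t=traj.t[i0:i1], states=traj.states[i0:i1],
                         params=traj.params, drive=traj.drive, ic=traj.ic,
                         rtol=traj.rtol, atol=traj.atol,
                         sample_dt=traj.sample_dt)
        fps.append(_fingerprint_nocheck(sub, le1=None))
    return starts, fps


def convergence_time(params: ModelParams, drive: DriveParams, ic_pair,
                     window: float = DEFAULT_WINDOW,
                     t_end: float = 2000.0,
                     tol: float | None = None) -> float | None:
    """Time at which the second trajectory merges onto the first's attractor.

    The first IC's run defines the asymptotic fingerprint (final 50%,
    without the LE term).  A window slides over the second run from t=0
    (transients kept); the earliest window start from which every subsequent
    window matches the reference is the merging time.  Returns None when the
    runs never merge (persistent coexistence).

    Windowed fingerprints of a chaotic attractor scatter, so the match
    threshold is calibrated from the reference run itself: 1.15 times the
    largest distance between the reference's own asymptotic windows and its
    long-run fingerprint.  Pass ``tol`` to override.  The estimate resolves
    the transition to about +/- window/2.
    """
    ic_a, ic_b = ic_pair
    ref_traj = integrate(params, drive, ic_a, (0.0, t_end))
    ref_tail = discard_transient(ref_traj, t_end / 2)
    ref = _fingerprint_nocheck(ref_tail, le1=None)
    if tol is None:
        _, self_fps = _window_fingerprints(ref_tail, window, hop=window / 2)
        tol = 1.15 * max(fingerprint_distance(f, ref) for f in self_fps)
    traj_b = integrate(params, drive, ic_b, (0.0, t_end))
    starts, fps = _window_fingerprints(traj_b, window, hop=window / 2)
    matched = np.array([fingerprint_distance(f, ref) < tol for f in fps])
    if not matched.any():
        return None
    # earliest start after which every window matches
    idx = len(matched)
    for i in range(len(matched) - 1, -1, -1):
        if not matched[i]:
            break
        idx = i
    if idx == len(matched):
        return None
    return float(starts[idx])


@dataclass(frozen=True)
class ThresholdResult:
    critical_k: float | None
    k_grid: np.ndarray
    coexists: np.ndarray
    monotone: bool


def elimination_threshold(k_grid, params: ModelParams, drive: DriveParams,
                          ic_pair, t_end: float = 3000.0,
                          tol: float = COEXISTENCE_TOL) -> ThresholdResult:
    """Largest coupling k at which multistability is already eliminated.

    Sweeps ``k_grid`` (ascending), running :func:`detect_coexistence` at each
    point, then refines the boundary between the last merged and first
    coexisting grid point with a single bisection step.  ``critical_k`` is
    None when no transition lies inside the grid.  ``monotone`` flags whether
    elimination is monotone over the grid (chaotic transients can make the
    boundary fuzzy; this is reported, not assumed).
    """
    k_grid = np.asarray(k_grid, dtype=float)
    flags = np.empty(len(k_grid), dtype=bool)
    for i, k in enumerate(k_grid):
        flags[i] = detect_coexistence(params.replace(k=k), drive, ic_pair,
                                      t_end=t_end, tol=tol).coexists
    eliminated = ~flags
    if not eliminated.any() or eliminated.all():
        return ThresholdResult(critical_k=None, k_grid=k_grid,
                               coexists=flags, monotone=True)
    i_last = int(np.flatnonzero(eliminated).max())
    monotone = bool(eliminated[:i_last + 1].all())
    crit = float(k_grid[i_last])
    if i_last + 1 < len(k_grid):
        mid = 0.5 * (k_grid[i_last] + k_grid[i_last + 1])
        if not detect_coexistence(params.replace(k=mid), drive, ic_pair,
                                  t_end=t_end, tol=tol).coexists:
            crit = float(mid)
    return ThresholdResult(critical_k=crit, k_grid=k_grid, coexists=flags,
                           monotone=monotone)
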