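"""Parameter sweeps: bifurcation diagrams and Lyapunov-exponent curves.

The bifurcation ordinate is the multiset of post-transient local maxima of
x(t) (peak sampling, the standard choice for HR-type models); a stroboscopic
variant (one sample per drive period) is available for cross-checking.  Each
grid point restarts from the declared initial condition, so branches keep
their IC identity and grid traversal order is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParams, DriveParams
from .integration import integrate, discard_transient, IntegrationError
from .lyapunov import lyapunov_spectrum
from .firing import detect_spikes
from .multistability import (_long_run_fingerprint, fingerprint_distance,
                             COEXISTENCE_TOL)

__all__ = ["BifurcationBranch", "bifurcation_sweep", "coexistence_region"]

SWEEP_PARAMS = ("A1", "f1", "f2", "k")


@dataclass(frozen=True)
class BifurcationBranch:
    param_name: str
    param_values: np.ndarray
    ic: tuple[float, float, float]
    samples: list[np.ndarray]  # per-parameter x-peak values; None on failure
    le1: np.ndarray            # NaN on failure or when not requested
    failures: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (param_value, ic_id, peak_value) table."""
        ic_id = ",".join(f"{v:g}" for v in self.ic)
        rows = []
        for v, pk in zip(self.param_values, self.samples):
            if pk is None:
                continue
            for y in pk:
                rows.append((v, ic_id, y))
        return pd.DataFrame(rows, columns=["param_value", "ic_id", "peak_value"])


def _apply(param_name: str, value: float, params: ModelParams,
           drive: DriveParams):
    if param_name == "k":
        return params.replace(k=value), drive
    if param_name in ("A1", "f1", "A2", "f2"):
        return params, drive.replace(**{param_name: value})
    raise ValueError(f"unknown sweep parameter {param_name!r}; "
                     f"expected one of {SWEEP_PARAMS}")


def _peaks(traj, stroboscopic: bool) -> np.ndarray:
    if stroboscopic:
        f = traj.drive.f1 if traj.drive.f1 > 0 else traj.drive.f2
        if f <= 0:
            raise ValueError("stroboscopic sampling needs a nonzero drive "
                             "frequency")
        period = 1.0 / f
        ts = np.arange(traj.t[0], traj.t[-1], period)
        idx = np.searchsorted(traj.t, ts)
        return traj.x[idx]
    return detect_spikes(traj, height_min=-np.inf, prominence_min=0.05,
                         min_separation=0.05).peak_values


def bifurcation_sweep(param_name: str, grid, ics, params: ModelParams,
                      drive: DriveParams, t_end: float = 1000.0,
                      t_transient: float = 500.0,
                      compute_le: bool = True,
                      le_horizon: float = 2000.0,
                      stroboscopic: bool = False) -> list[BifurcationBranch]:
    """Sweep one parameter over ``grid`` for each initial condition.

    Per grid point: integrate from the declared IC (no state inheritance),
    discard the transient, record the x-peak multiset and (optionally) the
    leading Lyapunov exponent.  Integration failures are recorded per point
    and the sweep continues.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    branches = []
    for ic in ics:
        samples: list[np.ndarray | None] = []
        le1 = np.full(len(grid), np.nan)
        failures = []
        for i, v in enumerate(grid):
            p, d = _apply(param_name, v, params, drive)
            try:
                traj = integrate(p, d, ic, (0.0, t_end))
                tail = discard_transient(traj, t_transient)
                samples.append(_peaks(tail, stroboscopic))
                if compute_le:
                    le1[i] = lyapunov_spectrum(
                        p, d, ic, t_transient=t_transient,
                        t_horizon=le_horizon, renorm_dt=1.0).le1
            except (IntegrationError, RuntimeError):
                samples.append(None)
                failures.append(i)
        branches.append(BifurcationBranch(
            param_name=param_name, param_values=grid,
            ic=tuple(float(x) for x in np.asarray(ic, float)),
            samples=samples, le1=le1, failures=failures))
    return branches


def coexistence_region(param_name: str, grid, ic_pair, params: ModelParams,
                       drive: DriveParams, t_end: float = 1500.0,
                       tol: float = COEXISTENCE_TOL) -> np.ndarray:
    """Boolean vector: do the two ICs reach distinct attractors per point?

    Fingerprints (with LE term) are compared on the final 50% of each run,
    exactly as in :func:`memhr.multistability.detect_coexistence`.
    """
    ic_a, ic_b = ic_pair
    if np.allclose(np.asarray(ic_a, float), np.asarray(ic_b, float)):
        return np.zeros(len(np.asarray(grid)), dtype=bool)
    grid = np.asarray(grid, dtype=float)
    out = np.zeros(len(grid), dtype=bool)
    for i, v in enumerate(grid):
        p, d = _apply(param_name, v, params, drive)
        fa, _ = _long_run_fingerprint(p, d, ic_a, t_end)
        fb, _ = _long_run_fingerprint(p, d, ic_b, t_end)
        out[i] = fingerprint_distance(fa, fb) > tol
    return out
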