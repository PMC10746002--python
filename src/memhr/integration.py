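"""Trajectory integration for the non-autonomous neuron model.

Uses an adaptive Dormand-Prince 5(4) stepper (the ODE45 contract) compiled in
:mod:`memhr._core`, with dense output sampled on a uniform grid.  The maximum
internal step is capped at ``min(1/(20 f1), 1/(20 f2), 0.1)`` so the drive is
always resolved regardless of the local error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _core
from .model import ModelParams, DriveParams, State, pack

__all__ = ["Trajectory", "IntegrationError", "integrate", "discard_transient",
           "default_max_step"]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_SAMPLE_DT = 0.01


class IntegrationError(RuntimeError):
    """Integration failed (non-finite state or step-size underflow)."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} at t={t_fail:.6g}")
        self.t_fail = t_fail


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled (x, y, phi) time series with full provenance.

    ``meta`` carries everything needed to re-run the integration
    bit-identically: parameters, drive, initial condition, tolerances,
    sampling step and any transient cut applied afterwards.
    """

    t: np.ndarray
    states: np.ndarray
    params: ModelParams
    drive: DriveParams
    ic: tuple[float, float, float]
    rtol: float
    atol: float
    sample_dt: float
    t_cut: float | None = None

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def phi(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def meta(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "drive": self.drive.to_dict(),
            "ic": list(self.ic),
            "rtol": self.rtol,
            "atol": self.atol,
            "sample_dt": self.sample_dt,
            "t_cut": self.t_cut,
            "t_span": [float(self.t[0]), float(self.t[-1])],
        }

    def __len__(self) -> int:
        return len(self.t)


def default_max_step(drive: DriveParams) -> float:
    """Cap the adaptive step so each drive period is sampled >= 20 times."""
    cap = 0.1
    for f in (drive.f1, drive.f2):
        if f > 0:
            cap = min(cap, 1.0 / (20.0 * f))
    return cap


def _as_ic(ic) -> np.ndarray:
    if isinstance(ic, State):
        return ic.as_array()
    arr = np.asarray(ic, dtype=float)
    if arr.shape != (3,) or not np.all(np.isfinite(arr)):
        raise ValueError("initial condition must be three finite numbers")
    return arr


def integrate(params: ModelParams, drive: DriveParams, ic,
              t_span: tuple[float, float],
              rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
              sample_dt: float = DEFAULT_SAMPLE_DT,
              max_step: float | None = None) -> Trajectory:
    """Integrate the model over ``t_span`` and sample every ``sample_dt``.

    Deterministic for fixed inputs; raises :class:`IntegrationError` with the
    failure time on step underflow or non-finite states.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError("t_span must satisfy t1 > t0")
    if rtol <= 0 or atol <= 0 or sample_dt <= 0:
        raise ValueError("tolerances and sample_dt must be positive")
    y0 = _as_ic(ic)
    cap = default_max_step(drive) if max_step is None else float(max_step)
    ts, ys, status, t_fail = _core.dp45(_core.rhs, pack(params, drive), y0,
                                        t0, t1, rtol, atol, cap, sample_dt)
    if status == _core.NONFINITE:
        raise IntegrationError("state became non-finite", t_fail)
    if status == _core.STEP_UNDERFLOW:
        raise IntegrationError("step size underflow", t_fail)
    return Trajectory(t=ts, states=ys, params=params, drive=drive,
                      ic=tuple(float(v) for v in y0),
                      rtol=rtol, atol=atol, sample_dt=sample_dt)


def discard_transient(traj: Trajectory, t_cut: float) -> Trajectory:
    """Keep the suffix with t >= t_cut; the cut is recorded in meta."""
    t_cut = float(t_cut)
    if t_cut < traj.t[0] - 1e-12 or t_cut > traj.t[-1]:
        raise ValueError(f"t_cut={t_cut} outside trajectory range "
                         f"[{traj.t[0]}, {traj.t[-1]}]")
    i0 = int(np.searchsorted(traj.t, t_cut - 1e-12))
    return replace(traj, t=traj.t[i0:], states=traj.states[i0:], t_cut=t_cut)
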