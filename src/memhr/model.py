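"""Memristive Hindmarsh-Rose neuron model with multi-frequency AC drive.

The classic two-variable HR neuron (membrane potential ``x``, recovery
variable ``y``) is extended with a flux-controlled memristor: the magnetic
flux ``phi`` across the membrane evolves as ``phi' = x - phi`` and feeds an
electromagnetic-induction current ``k * W(phi) * x`` back into the membrane
equation, where ``W(phi) = alpha + beta * phi**2`` is the memductance.  The
external stimulus is the sum of two sinusoidal currents
``I1 = A1 sin(2 pi f1 t)`` and ``I2 = A2 sin(2 pi f2 t)``; single excitation
is the special case ``A2 = 0``.

Full system::

    x' = y + a x^2 - b x^3 + k W(phi) x + I1(t) + I2(t)
    y' = c - d x^2 - y
    phi' = x - phi

Time is an explicit argument throughout (non-autonomous form); no auxiliary
time state is introduced.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np

__all__ = [
    "ModelParams",
    "DriveParams",
    "State",
    "memductance",
    "drive_current",
    "vector_field",
    "jacobian",
    "pack",
]

TWO_PI = 2.0 * math.pi


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless HR coefficients plus memristor constants.

    Defaults are the canonical values a=3, b=1, c=1, d=5 with memductance
    coefficients alpha=0, beta=0.01; ``k`` is the memristor coupling strength.
    """

    a: float = 3.0
    b: float = 1.0
    c: float = 1.0
    d: float = 5.0
    k: float = 1.0
    alpha: float = 0.0
    beta: float = 0.01

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "k", "alpha", "beta"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    def replace(self, **kw) -> "ModelParams":
        return ModelParams(**{**asdict(self), **kw})

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass(frozen=True)
class DriveParams:
    """Two sinusoidal current sources; A2=0 encodes single excitation."""

    A1: float = 0.0
    f1: float = 0.0
    A2: float = 0.0
    f2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("A1", "f1", "A2", "f2"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        if self.f1 < 0 or self.f2 < 0:
            raise ValueError("drive frequencies must be non-negative")

    def replace(self, **kw) -> "DriveParams":
        return DriveParams(**{**asdict(self), **kw})

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DriveParams":
        return cls(**d)


@dataclass(frozen=True)
class State:
    """Phase-space point: membrane potential, recovery variable, flux."""

    x: float
    y: float
    phi: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "phi"):
            _require_finite(name, getattr(self, name))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.phi], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "State":
        x, y, phi = (float(v) for v in arr)
        return cls(x, y, phi)


def memductance(phi: float, params: ModelParams) -> float:
    """Flux-controlled memductance W(phi) = alpha + beta * phi**2."""
    return params.alpha + params.beta * phi * phi


def drive_current(t, drive: DriveParams):
    """Total injected current I1(t) + I2(t); accepts scalar or array t."""
    t = np.asarray(t, dtype=float)
    out = (drive.A1 * np.sin(TWO_PI * drive.f1 * t)
           + drive.A2 * np.sin(TWO_PI * drive.f2 * t))
    return float(out) if out.ndim == 0 else out


def vector_field(t: float, state, params: ModelParams,
                 drive: DriveParams | None = None) -> np.ndarray:
    """Right-hand side (x', y', phi') at time t."""
    if isinstance(state, State):
        state = state.as_array()
    x, y, phi = (float(v) for v in state)
    I = drive_current(t, drive) if drive is not None else 0.0
    W = memductance(phi, params)
    return np.array([
        y + params.a * x * x - params.b * x ** 3 + params.k * W * x + I,
        params.c - params.d * x * x - y,
        x - phi,
    ])


def jacobian(state_or_eta, params: ModelParams) -> np.ndarray:
    """State-space Jacobian of the vector field.

    Accepts either a full state (general variant) or a scalar equilibrium
    root ``eta`` (evaluated at x = phi = eta, the equilibrium convention).
    The drive enters additively and contributes nothing.
    """
    if np.isscalar(state_or_eta):
        eta = float(state_or_eta)
        x, phi = eta, eta
    else:
        s = state_or_eta.as_array() if isinstance(state_or_eta, State) else np.asarray(state_or_eta, float)
        x, phi = float(s[0]), float(s[2])
    a, b, d, k, beta = params.a, params.b, params.d, params.k, params.beta
    return np.array([
        [2 * a * x - 3 * b * x * x + k * memductance(phi, params), 1.0, 2 * k * beta * phi * x],
        [-2 * d * x, -1.0, 0.0],
        [1.0, 0.0, -1.0],
    ])


def pack(params: ModelParams, drive: DriveParams | None = None) -> np.ndarray:
    """Flatten parameters into the float64 vector the compiled core expects."""
    if drive is None:
        drive = DriveParams()
    return np.array([params.a, params.b, params.c, params.d, params.k,
                     params.alpha, params.beta,
                     drive.A1, drive.f1, drive.A2, drive.f2], dtype=float)


def save_config(path, params: ModelParams, drive: DriveParams, **extra) -> None:
    """Serialize a parameter scenario to a flat JSON key-value file."""
    doc = {**params.to_dict(), **drive.to_dict(), **extra}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path) -> tuple[ModelParams, DriveParams, dict]:
    """Load a scenario saved by :func:`save_config`."""
    with open(path) as fh:
        doc = json.load(fh)
    pkeys = {"a", "b", "c", "d", "k", "alpha", "beta"}
    dkeys = {"A1", "f1", "A2", "f2"}
    params = ModelParams(**{k: v for k, v in doc.items() if k in pkeys})
    drive = DriveParams(**{k: v for k, v in doc.items() if k in dkeys})
    extra = {k: v for k, v in doc.items() if k not in pkeys | dkeys}
    return params, drive, extra
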