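"""Equilibrium analysis of the forced memristive HR neuron.

The system is non-autonomous; equilibria are defined by freezing the drive
I1 + I2 at its instantaneous value (the standard convention for slowly
inspected forced systems).  Setting the right-hand side to zero gives
``y = c - d x^2`` and ``phi = x``; writing ``x = eta`` the equilibrium is
``E = (eta, c - d eta^2, eta)`` and eta solves the cubic

    P(eta) = (beta*k - b) eta^3 + (a - d) eta^2 + (alpha*k) eta + c + I = 0

which for the canonical parameters (a=3, b=1, c=1, d=5, alpha=0, beta=0.01)
is ``(0.01 k - 1) eta^3 - 2 eta^2 + 1 + I = 0``.  Roots are classified with
the Cardano discriminant and stability follows from the Jacobian eigenvalues
at E.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParams, DriveParams, drive_current, jacobian, vector_field

__all__ = [
    "CardanoReport",
    "EquilibriumReport",
    "cubic_coefficients",
    "cardano_discriminant",
    "solve_equilibria",
    "characteristic_coeffs",
    "eigenvalues_at",
    "classify_stability",
    "equilibrium_track",
    "stability_intervals",
]

STABILITY_TOL = 1e-9
#: relative tolerance for declaring the discriminant zero (double root)
DELTA_ZERO_RTOL = 1e-12


class DegenerateCubicError(ValueError):
    """The leading cubic coefficient vanishes (beta*k == b); use the
    quadratic path in :func:`solve_equilibria`."""


@dataclass(frozen=True)
class CardanoReport:
    p: float
    q: float
    delta: float
    n_real_roots: int


@dataclass(frozen=True)
class EquilibriumReport:
    eta: float
    point: tuple[float, float, float]
    m1: float
    m2: float
    m3: float
    eigenvalues: tuple[complex, complex, complex]
    stability: str  # "stable" | "unstable"

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


def cubic_coefficients(k: float, I_total: float,
                       params: ModelParams | None = None):
    """Coefficients (A, B, C, D) of the equilibrium cubic and a degeneracy flag.

    ``A = beta*k - b`` vanishes when k = b/beta (k = 100 at defaults); the
    caller must then fall back to the quadratic branch.
    """
    if params is None:
        params = ModelParams(k=k)
    A = params.beta * k - params.b
    B = params.a - params.d
    C = params.alpha * k
    D = params.c + I_total
    return (A, B, C, D), A == 0.0


def cardano_discriminant(cubic) -> CardanoReport:
    """Depressed-cubic coefficients p, q and discriminant Delta = q^2/4 + p^3/27.

    Real-root trichotomy: Delta > 0 one real root, Delta < 0 three,
    Delta = 0 two (a double root; counted as two even when p = q = 0).
    """
    A, B, C, D = cubic
    if A == 0.0:
        raise DegenerateCubicError(
            "leading coefficient is zero; solve the quadratic instead")
    p = (3 * A * C - B * B) / (3 * A * A)
    q = (27 * A * A * D - 9 * A * B * C + 2 * B ** 3) / (27 * A ** 3)
    delta = q * q / 4 + p ** 3 / 27
    tol = DELTA_ZERO_RTOL * max(1.0, q * q)
    if abs(delta) <= tol:
        n = 2
    elif delta > 0:
        n = 1
    else:
        n = 3
    return CardanoReport(p=p, q=q, delta=delta, n_real_roots=n)


def _cardano_roots(cubic) -> list[float]:
    """Real roots of the cubic via Cardano / trigonometric forms."""
    A, B, C, D = cubic
    rep = cardano_discriminant(cubic)
    p, q, delta = rep.p, rep.q, rep.delta
    shift = -B / (3 * A)
    tol = DELTA_ZERO_RTOL * max(1.0, q * q)
    if abs(delta) <= tol:
        if p == 0.0 and q == 0.0:
            ts = [0.0]
        else:
            ts = [3 * q / p, -3 * q / (2 * p)]
    elif delta > 0:
        u = np.cbrt(-q / 2 + math.sqrt(delta))
        v = np.cbrt(-q / 2 - math.sqrt(delta))
        ts = [float(u + v)]
    else:
        # three real roots: trigonometric form avoids complex cube roots
        r = 2 * math.sqrt(-p / 3)
        arg = 3 * q / (2 * p) * math.sqrt(-3 / p)
        arg = min(1.0, max(-1.0, arg))
        theta = math.acos(arg) / 3
        ts = [r * math.cos(theta - 2 * math.pi * j / 3) for j in range(3)]
    roots = [t + shift for t in ts]

    def P(x):
        return ((A * x + B) * x + C) * x + D

    def dP(x):
        return (3 * A * x + 2 * B) * x + C

    polished = []
    for x in roots:
        for _ in range(3):  # Newton polish decouples accuracy from closed form
            d = dP(x)
            if d == 0:
                break
            step = P(x) / d
            x -= step
            if abs(step) < 1e-15 * max(1.0, abs(x)):
                break
        polished.append(x)
    return sorted(polished)


def characteristic_coeffs(eta: float, k: float,
                          params: ModelParams | None = None):
    """Coefficients (m1, m2, m3) of det(lambda*I - J_E) = l^3+m1 l^2+m2 l+m3.

    At the canonical parameters these reduce to the rational forms
    m1 = (200 - 600 eta + 300 eta^2 - k eta^2)/100,
    m2 = (600 eta^2 - 4 k eta^2 - 200 eta + 100)/100,
    m3 = (400 eta + 300 eta^2 - 3 k eta^2)/100.
    """
    if params is None:
        params = ModelParams(k=k)
    else:
        params = params.replace(k=k)
    J = jacobian(eta, params)
    m1 = -np.trace(J)
    m3 = -np.linalg.det(J)
    # sum of principal 2x2 minors
    m2 = (J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
          + J[0, 0] * J[2, 2] - J[0, 2] * J[2, 0]
          + J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
    return float(m1), float(m2), float(m3)


def eigenvalues_at(eta: float, k: float,
                   params: ModelParams | None = None):
    """Eigenvalues at the equilibrium with root eta, sorted by descending
    real part (ties by descending imaginary part).

    One eigenvalue is always exactly -1: the flux row phi' = x - phi makes
    (J + I) singular for every eta and k.
    """
    m1, m2, m3 = characteristic_coeffs(eta, k, params)
    eigs = np.roots([1.0, m1, m2, m3])
    eigs = sorted((complex(e) for e in eigs),
                  key=lambda z: (-z.real, -z.imag))
    return tuple(eigs)


def classify_stability(eigs, tol: float = STABILITY_TOL) -> str:
    """'stable' iff every eigenvalue real part < -tol (strict rule:
    marginal cases count as unstable)."""
    return "stable" if all(e.real < -tol for e in eigs) else "unstable"


def _report_for_root(eta: float, params: ModelParams) -> EquilibriumReport:
    m1, m2, m3 = characteristic_coeffs(eta, params.k, params)
    eigs = eigenvalues_at(eta, params.k, params)
    point = (eta, params.c - params.d * eta * eta, eta)
    return EquilibriumReport(eta=eta, point=point, m1=m1, m2=m2, m3=m3,
                             eigenvalues=eigs,
                             stability=classify_stability(eigs))


def solve_equilibria(k: float, I_total: float,
                     params: ModelParams | None = None) -> list[EquilibriumReport]:
    """All real equilibrium roots at coupling k with frozen drive I_total.

    Handles the degenerate leading coefficient (k = b/beta) by dropping to
    the quadratic; a degenerate *linear* sub-case with no real root raises.
    Reports are sorted by eta ascending.
    """
    if params is None:
        params = ModelParams(k=k)
    else:
        params = params.replace(k=k)
    (A, B, C, D), degenerate = cubic_coefficients(k, I_total, params)
    if degenerate:
        if B == 0.0:
            if C == 0.0:
                raise ValueError("equilibrium equation degenerates to a "
                                 "constant; no isolated root")
            roots = [-D / C]
        else:
            disc = C * C - 4 * B * D
            if disc < 0:
                roots = []
            else:
                r = math.sqrt(disc)
                roots = sorted({(-C + r) / (2 * B), (-C - r) / (2 * B)})
    else:
        roots = _cardano_roots((A, B, C, D))

    # drop numerically duplicated roots (double-root case)
    dedup: list[float] = []
    for r in roots:
        if not any(abs(r - r0) < 1e-9 * max(1.0, abs(r)) for r0 in dedup):
            dedup.append(r)
    return [_report_for_root(r, params) for r in dedup]


def equilibrium_track(params: ModelParams, drive: DriveParams,
                      t_grid) -> pd.DataFrame:
    """Per-time equilibrium solve along a time grid.

    Returns a tidy DataFrame with one row per (time, root): columns
    t, root_index, eta, re_l1, re_l2, re_l3, stability.  Roots are indexed
    by ascending eta at each time; the drive is frozen at its instantaneous
    value (non-autonomous convention).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-d vector")
    rows = []
    for t in t_grid:
        I = drive_current(t, drive)
        for i, rep in enumerate(solve_equilibria(params.k, I, params)):
            re = [e.real for e in rep.eigenvalues]
            rows.append((t, i, rep.eta, re[0], re[1], re[2], rep.stability))
    return pd.DataFrame(rows, columns=["t", "root_index", "eta",
                                       "re_l1", "re_l2", "re_l3", "stability"])


def stability_intervals(track: pd.DataFrame) -> list[tuple[float, float]]:
    """Maximal time intervals over which at least one root is stable."""
    by_t = track.groupby("t")["stability"].apply(lambda s: (s == "stable").any())
    ts = by_t.index.to_numpy()
    flags = by_t.to_numpy()
    intervals = []
    start = None
    for t, f in zip(ts, flags):
        if f and start is None:
            start = t
        elif not f and start is not None:
            intervals.append((start, prev_t))
            start = None
        prev_t = t
    if start is not None:
        intervals.append((start, ts[-1]))
    return intervals
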