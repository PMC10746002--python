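"""Analog-circuit realization: dimensionless parameters <-> component values.

The model is realized with inverting integrator/adder op-amp stages (UA741)
and 0.1-gain analog multipliers (AD633).  Time is rescaled by the integrator
constant tau0 = 1/(R C); with the canonical tau0 = 10,000 1/s and C = 50 nF
the base resistance is R = 2 kOhm.  Matching the circuit equations against
the dimensionless model gives one identity per coefficient (the factors of 10
come from the multiplier gain):

    a = R7/(10 R1)    b = R7/(100 R3)   k = R7/(10 R4)
    c = R11/R9        d = R11/(10 R8)   beta = Ro/(10 R15)

with unit-gain identities R7/R2 = R7/R5 = R7/R6 = R11/R10 = R14/R12 =
R14/R13 = 1.  Anchors R7 = 300, R11 = R14 = 100 (kOhm) and R15 = 100 kOhm
are fixed; everything else is solved.  A drive frequency f (dimensionless)
maps to f * tau0 Hz in the physical circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .model import ModelParams

__all__ = ["CircuitAnchors", "CircuitParams", "map_to_circuit",
           "circuit_to_params", "scale_frequency", "component_table"]


@dataclass(frozen=True)
class CircuitAnchors:
    R7: float = 300.0    # kOhm
    R11: float = 100.0   # kOhm
    R14: float = 100.0   # kOhm
    R15: float = 100.0   # kOhm
    C: float = 50.0      # nF
    tau0: float = 10_000.0  # 1/s


@dataclass(frozen=True)
class CircuitParams:
    """All component values in kOhm / nF; R is the base integrator resistor."""

    R: float
    R1: float
    R2: float
    R3: float
    R4: float
    R5: float
    R6: float
    R7: float
    R8: float
    R9: float
    R10: float
    R11: float
    R12: float
    R13: float
    R14: float
    R15: float
    Ro: float
    C: float
    tau0: float

    def resistances(self) -> dict[str, float]:
        d = asdict(self)
        return {k: v for k, v in d.items() if k.startswith("R") or k == "Ro"}


def map_to_circuit(params: ModelParams,
                   anchors: CircuitAnchors | None = None) -> CircuitParams:
    """Solve the coefficient identities for every resistor.

    Raises ValueError when a parameter set is not realizable with the given
    anchors (a zero or negative solved resistance, or a nonzero alpha, which
    has no branch in this topology).
    """
    if anchors is None:
        anchors = CircuitAnchors()
    if params.alpha != 0.0:
        raise ValueError("the realized memductance block implements "
                         "W(phi) = beta*phi^2 only (alpha must be 0)")
    R7, R11, R14, R15 = anchors.R7, anchors.R11, anchors.R14, anchors.R15
    # base resistor from the time-scaling factor: tau0 = 1/(R C)
    R_base = 1.0 / (anchors.tau0 * anchors.C * 1e-9) / 1e3  # kOhm
    try:
        values = {
            "R": R_base,
            "R1": R7 / (10.0 * params.a),
            "R2": R7,
            "R3": R7 / (100.0 * params.b),
            "R4": R7 / (10.0 * params.k),
            "R5": R7,
            "R6": R7,
            "R7": R7,
            "R8": R11 / (10.0 * params.d),
            "R9": R11 / params.c,
            "R10": R11,
            "R11": R11,
            "R12": R14,
            "R13": R14,
            "R14": R14,
            "R15": R15,
            "Ro": 10.0 * R15 * params.beta,
        }
    except ZeroDivisionError as exc:
        raise ValueError("parameter set not realizable (division by zero "
                         "coefficient)") from exc
    bad = [name for name, v in values.items() if not v > 0]
    if bad:
        raise ValueError(f"parameter set not realizable with these anchors: "
                         f"non-positive {', '.join(bad)}")
    return CircuitParams(**values, C=anchors.C, tau0=anchors.tau0)


def circuit_to_params(circ: CircuitParams) -> ModelParams:
    """Invert the coefficient identities back to dimensionless parameters."""
    for name, v in circ.resistances().items():
        if not v > 0:
            raise ValueError(f"non-positive resistance {name}={v}")
    return ModelParams(
        a=circ.R7 / (10.0 * circ.R1),
        b=circ.R7 / (100.0 * circ.R3),
        c=circ.R11 / circ.R9,
        d=circ.R11 / (10.0 * circ.R8),
        k=circ.R7 / (10.0 * circ.R4),
        alpha=0.0,
        beta=circ.Ro / (10.0 * circ.R15),
    )


def scale_frequency(f_dimensionless: float, tau0: float = 10_000.0) -> float:
    """Physical drive frequency in Hz: f_physical = f * tau0."""
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    return f_dimensionless * tau0


def component_table(circ: CircuitParams) -> pd.DataFrame:
    """Component list (name, role, value, unit) in the canonical grouping."""
    rows = [
        ("R", "integrator base resistance", circ.R, "kOhm"),
        ("R1", "x^2 gain (a)", circ.R1, "kOhm"),
        ("R2", "y feed", circ.R2, "kOhm"),
        ("R3", "x^3 gain (b)", circ.R3, "kOhm"),
        ("R4", "memristor coupling (k)", circ.R4, "kOhm"),
        ("R5", "drive I1 feed", circ.R5, "kOhm"),
        ("R6", "drive I2 feed", circ.R6, "kOhm"),
        ("R7", "x-equation feedback anchor", circ.R7, "kOhm"),
        ("R8", "x^2 gain in y-equation (d)", circ.R8, "kOhm"),
        ("R9", "constant drive (c)", circ.R9, "kOhm"),
        ("R10", "y feedback", circ.R10, "kOhm"),
        ("R11", "y-equation anchor", circ.R11, "kOhm"),
        ("R12", "x feed in flux equation", circ.R12, "kOhm"),
        ("R13", "flux feedback", circ.R13, "kOhm"),
        ("R14", "flux-equation anchor", circ.R14, "kOhm"),
        ("R15", "memductance divider", circ.R15, "kOhm"),
        ("Ro", "memductance output (beta)", circ.Ro, "kOhm"),
        ("C", "integrator capacitance", circ.C, "nF"),
    ]
    return pd.DataFrame(rows, columns=["name", "role", "value", "unit"])
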