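"""Named parameter scenarios and one-call structured reports.

Every study condition analysed by the toolkit is registered here as a
:class:`Preset`: the stability track under symmetric two-tone drive, the
single-excitation bifurcation sweeps and coexistence pairs, the
multistability-elimination scenarios at strongly negative coupling, the four
high-low-frequency drive conditions, and the canonical circuit realization.
``run_report`` executes a preset's full analysis chain deterministically and
returns one JSON-serializable document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import ModelParams, DriveParams
from .integration import integrate, discard_transient
from .lyapunov import lyapunov_spectrum
from .firing import detect_spikes, classify_firing
from .equilibria import equilibrium_track, stability_intervals
from .multistability import detect_coexistence
from .circuit import map_to_circuit, component_table

__all__ = ["Preset", "REGISTRY", "list_presets", "get_preset", "run_report"]


@dataclass(frozen=True)
class Preset:
    name: str
    kind: str  # "point" | "pair" | "sweep" | "track" | "circuit"
    params: ModelParams
    drive: DriveParams
    ics: tuple = ()
    t_end: float = 2000.0
    t_transient: float = 500.0
    le_transient: float = 1000.0
    le_horizon: float = 10000.0
    note: str = ""
    sweep: dict | None = None


_K1 = ModelParams(k=1.0)


def _p(name, kind, params, drive, ics=(), note="", **kw):
    return Preset(name=name, kind=kind, params=params, drive=drive,
                  ics=tuple(tuple(ic) for ic in ics), note=note, **kw)


REGISTRY: dict[str, Preset] = {p.name: p for p in [
    _p("stability_track", "track", _K1,
       DriveParams(A1=1.0, f1=0.05, A2=1.0, f2=0.05),
       note="symmetric two-tone drive; equilibrium stability flips along one "
            "drive period, stable only inside a sub-interval"),
    _p("A1_bifurcation", "sweep", _K1, DriveParams(A1=3.0, f1=0.5),
       ics=[(5.0, 0.0, 0.0), (-5.0, 0.0, 0.0)],
       sweep={"param": "A1", "lo": 0.05, "hi": 8.0, "n": 400},
       note="single excitation; reverse period-doubling branch from "
            "(-5,0,0), stable periodic branch from (5,0,0)"),
    _p("coexist_A1_0.1", "pair", _K1, DriveParams(A1=0.1, f1=0.5),
       ics=[(-5.0, 0.0, 0.0), (5.0, 0.0, 0.0)],
       note="coexistence of chaotic spiking and a fixed point"),
    _p("coexist_A1_3", "pair", _K1, DriveParams(A1=3.0, f1=0.5),
       ics=[(-5.0, 0.0, 0.0), (5.0, 0.0, 0.0)],
       note="coexistence of chaotic bursting and a periodic limit cycle"),
    _p("coexist_A1_5.5", "pair", _K1, DriveParams(A1=5.5, f1=0.5),
       ics=[(-5.0, 0.0, 0.0), (5.0, 0.0, 0.0)],
       note="coexistence of periodic spiking and a periodic limit cycle"),
    _p("f1_sweep_low", "sweep", _K1, DriveParams(A1=3.0, f1=0.05),
       ics=[(-5.0, 0.0, 0.0)],
       sweep={"param": "f1", "lo": 0.01, "hi": 0.1, "n": 400},
       note="low-frequency range: chaos, periodic windows, crisis; no "
            "coexistence"),
    _p("f1_sweep_high", "sweep", _K1, DriveParams(A1=3.0, f1=0.5),
       ics=[(-5.0, 0.0, 0.0), (5.0, 0.0, 0.0)],
       sweep={"param": "f1", "lo": 0.1, "hi": 1.0, "n": 400},
       note="high-frequency range: coexistence appears in part of "
            "(~0.44, 1)"),
    _p("elimination_k_-7", "pair", _K1.replace(k=-7.0),
       DriveParams(A1=3.0, f1=0.5),
       ics=[(-5.0, 0.0, 0.0), (5.0, 0.0, 0.0)], t_end=2000.0,
       note="multistability eliminated; the (5,0,0) run merges into chaotic "
            "bursting near t~270"),
    _p("elimination_k_-10", "pair", _K1.replace(k=-10.0),
       DriveParams(A1=0.1, f1=0.5),
       ics=[(-5.0, 0.0, 0.0), (5.0, 0.0, 0.0)], t_end=2000.0,
       note="multistability eliminated; the (5,0,0) run enters spiking "
            "after t~200"),
    _p("two_tone_f2_0.002", "point", _K1,
       DriveParams(A1=3.0, f1=0.5, A2=3.0, f2=0.002),
       ics=[(-5.0, 0.0, 0.0)], t_end=3000.0,
       note="periodic bursting envelope with irregular intra-burst spiking; "
            "all Lyapunov exponents negative"),
    _p("two_tone_f2_0.02", "point", _K1,
       DriveParams(A1=3.0, f1=0.5, A2=3.0, f2=0.02),
       ics=[(-5.0, 0.0, 0.0)], t_end=3000.0,
       note="periodic bursting with three spikes per burst"),
    _p("two_tone_f2_0.04", "point", _K1,
       DriveParams(A1=3.0, f1=0.5, A2=3.0, f2=0.04),
       ics=[(-5.0, 0.0, 0.0)], t_end=3000.0,
       note="period-2 spiking"),
    _p("two_tone_f2_0.07", "point", _K1,
       DriveParams(A1=3.0, f1=0.5, A2=3.0, f2=0.07),
       ics=[(-5.0, 0.0, 0.0)], t_end=3000.0,
       note="chaotic spiking, positive leading Lyapunov exponent"),
    _p("circuit_defaults", "circuit", _K1, DriveParams(),
       note="canonical analog realization: tau0=10000 1/s, C=50 nF, "
            "anchors R7=300, R11=R14=R15=100 kOhm"),
]}


def list_presets() -> dict[str, Preset]:
    """The full preset registry, keyed by name."""
    return dict(REGISTRY)


def get_preset(name: str) -> Preset:
    if name not in REGISTRY:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{', '.join(sorted(REGISTRY))}")
    return REGISTRY[name]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_report(preset_name: str, fast: bool = False) -> dict:
    """Run a preset's full analysis chain and return a JSON-ready document.

    For point/pair presets: integrate each IC, compute the Lyapunov
    spectrum, classify the firing pattern, and (for pairs) test coexistence.
    Track presets produce the stability-interval summary; circuit presets
    the component table.  ``fast=True`` shortens horizons (smoke runs).
    Deterministic: identical calls produce identical documents.
    """
    p = get_preset(preset_name)
    doc: dict = {
        "preset": p.name,
        "kind": p.kind,
        "params": p.params.to_dict(),
        "drive": p.drive.to_dict(),
        "ics": [list(ic) for ic in p.ics],
        "note": p.note,
    }
    scale = 0.1 if fast else 1.0
    if p.kind in ("point", "pair"):
        t_end = max(200.0, p.t_end * scale)
        le_h = max(500.0, p.le_horizon * scale)
        le_tr = max(100.0, p.le_transient * scale)
        branches = []
        for ic in p.ics:
            res = lyapunov_spectrum(p.params, p.drive, ic,
                                    t_transient=le_tr, t_horizon=le_h)
            traj = discard_transient(
                integrate(p.params, p.drive, ic, (0.0, t_end)),
                min(p.t_transient, t_end / 2))
            pat = classify_firing(traj, le1=res.le1)
            branches.append({
                "ic": list(ic),
                "exponents": list(res.exponents),
                "label": pat.label,
                "period_count": pat.period_count,
                "spikes_per_burst": pat.spikes_per_burst,
            })
        doc["branches"] = branches
        if p.kind == "pair" and len(p.ics) == 2:
            co = detect_coexistence(p.params, p.drive, p.ics, t_end=t_end)
            doc["coexists"] = co.coexists
            doc["fingerprint_distance"] = co.distance
    elif p.kind == "track":
        grid = np.linspace(5.0, 25.0, 401)
        track = equilibrium_track(p.params, p.drive, grid)
        doc["stability_intervals"] = [list(iv) for iv in
                                      stability_intervals(track)]
    elif p.kind == "sweep":
        doc["sweep"] = dict(p.sweep)  # executed via memhr.sweeps / CLI
    elif p.kind == "circuit":
        circ = map_to_circuit(p.params)
        doc["components"] = component_table(circ).to_dict(orient="records")
    return _round_floats(doc)


def report_json(doc: dict) -> str:
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"
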