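"""Shared fixtures: canonical parameter scenarios and cached heavy runs.

Session-scoped fixtures hold the expensive trajectory/Lyapunov computations
so the firing, multistability and acceptance tests reuse one run each.
"""

import numpy as np
import pytest

from memhr import (ModelParams, DriveParams, integrate, discard_transient,
                   lyapunov_spectrum, detect_coexistence)

IC_NEG = (-5.0, 0.0, 0.0)
IC_POS = (5.0, 0.0, 0.0)
F2_VALUES = (0.002, 0.02, 0.04, 0.07)


@pytest.fixture(scope="session")
def k1():
    return ModelParams(k=1.0)


def two_tone_drive(f2: float) -> DriveParams:
    return DriveParams(A1=3.0, f1=0.5, A2=3.0, f2=f2)


@pytest.fixture(scope="session")
def two_tone_spectra(k1):
    """Full-horizon Lyapunov spectra for the four high-low drive scenarios."""
    return {f2: lyapunov_spectrum(k1, two_tone_drive(f2), IC_NEG)
            for f2 in F2_VALUES}


@pytest.fixture(scope="session")
def two_tone_tails(k1):
    """Post-transient trajectories for the four high-low drive scenarios."""
    out = {}
    for f2 in F2_VALUES:
        traj = integrate(k1, two_tone_drive(f2), IC_NEG, (0.0, 3000.0))
        out[f2] = discard_transient(traj, 500.0)
    return out


@pytest.fixture(scope="session")
def single_tone_pairs(k1):
    """Coexistence results for the three single-excitation amplitudes."""
    return {A1: detect_coexistence(k1, DriveParams(A1=A1, f1=0.5),
                                   (IC_NEG, IC_POS), t_end=2000.0)
            for A1 in (0.1, 3.0, 5.5)}


@pytest.fixture(scope="session")
def single_tone_branches(k1):
    """Per-branch (trajectory tail, le1) for the single-excitation scenarios."""
    out = {}
    for A1 in (0.1, 3.0, 5.5):
        d = DriveParams(A1=A1, f1=0.5)
        for ic in (IC_NEG, IC_POS):
            le1 = lyapunov_spectrum(k1, d, ic, t_transient=500.0,
                                    t_horizon=4000.0).le1
            tail = discard_transient(integrate(k1, d, ic, (0.0, 2000.0)),
                                     500.0)
            out[(A1, ic)] = (tail, le1)
    return out
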