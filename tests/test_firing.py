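"""Spike detection, burst segmentation and firing-pattern taxonomy."""

import numpy as np
import pytest

from memhr import ModelParams, DriveParams
from memhr.integration import Trajectory
from memhr.firing import (detect_spikes, segment_bursts, classify_firing,
                          SpikeTrain)


def make_traj(t, x, drive=DriveParams()):
    states = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    return Trajectory(t=t, states=states, params=ModelParams(), drive=drive,
                      ic=(0.0, 0.0, 0.0), rtol=1e-8, atol=1e-10,
                      sample_dt=float(t[1] - t[0]))


def gaussian_bumps(times, t_end=100.0, dt=0.01, amp=2.5, width=0.15):
    t = np.arange(0.0, t_end, dt)
    x = np.full_like(t, -1.5)
    for tc in times:
        x += (amp + 1.5) * np.exp(-0.5 * ((t - tc) / width) ** 2)
    return t, x


def test_constant_trace_has_no_spikes():
    t = np.arange(0, 100, 0.01)
    train = detect_spikes(make_traj(t, np.full_like(t, 0.7)))
    assert train.n == 0


def test_synthetic_bumps_recovered_at_known_times():
    times = np.array([10.0, 22.5, 47.3, 60.0, 88.8])
    t, x = gaussian_bumps(times)
    train = detect_spikes(make_traj(t, x))
    assert train.n == len(times)
    np.testing.assert_allclose(train.spike_times, times, atol=0.01)
    np.testing.assert_allclose(train.peak_values, 2.5, atol=0.01)


def test_no_false_positives_on_troughs():
    """Downward troughs between true spikes are never counted as spikes."""
    up = np.array([15.0, 40.0, 75.0])
    down = np.array([27.0, 58.0, 90.0])
    t, x = gaussian_bumps(up)
    for tc in down:
        x -= 4.0 * np.exp(-0.5 * ((t - tc) / 0.15) ** 2)
    train = detect_spikes(make_traj(t, x))
    assert train.n == len(up)
    np.testing.assert_allclose(train.spike_times, up, atol=0.01)


def test_periodic_preset_near_constant_isi(single_tone_branches):
    tail, _ = single_tone_branches[(5.5, (-5.0, 0.0, 0.0))]
    train = detect_spikes(tail)
    assert train.n > 100
    cv = np.std(train.isi) / np.mean(train.isi)
    assert cv <= 0.05  # period-2 spiking: slight ISI alternation


def test_uniform_train_is_tonic():
    times = np.arange(5.0, 95.0, 3.0)
    t, x = gaussian_bumps(times)
    segs = segment_bursts(detect_spikes(make_traj(t, x)))
    assert len(segs) == 1


def test_three_spikes_then_gap_pattern():
    times = []
    for start in np.arange(5.0, 90.0, 20.0):
        times.extend([start, start + 1.5, start + 3.0])
    t, x = gaussian_bumps(np.array(times))
    segs = segment_bursts(detect_spikes(make_traj(t, x)))
    assert [len(s) for s in segs] == [3, 3, 3, 3, 3]


def test_too_few_spikes_raises():
    t, x = gaussian_bumps(np.array([10.0, 50.0]))
    with pytest.raises(ValueError):
        segment_bursts(detect_spikes(make_traj(t, x)))


@pytest.mark.parametrize("f2, label, spb, period", [
    (0.002, "periodic_bursting", "many", None),
    (0.02, "periodic_bursting", 3, None),
    (0.04, "periodic_spiking", None, 2),
    (0.07, "chaotic_spiking", None, None),
])
def test_two_tone_taxonomy(two_tone_tails, two_tone_spectra, f2, label, spb,
                           period):
    """The four high-low-frequency drive rows classify as described."""
    pat = classify_firing(two_tone_tails[f2], le1=two_tone_spectra[f2].le1)
    assert pat.label == label
    if spb == "many":
        assert pat.spikes_per_burst >= 10
        assert pat.intra_burst_isi_cv > 0.1  # irregular intra-burst spiking
    elif spb is not None:
        assert pat.spikes_per_burst == spb
    if period is not None:
        assert pat.period_count == period


@pytest.mark.parametrize("A1, ic_sign, expected", [
    (0.1, -1, "chaotic_spiking"),
    (0.1, +1, "quiescent"),
    (3.0, -1, "chaotic_bursting"),
    (3.0, +1, "subthreshold_oscillation"),
    (5.5, -1, "periodic_spiking"),
    (5.5, +1, "subthreshold_oscillation"),
])
def test_single_excitation_branch_labels(single_tone_branches, A1, ic_sign,
                                         expected):
    """Coexisting branch labels under single excitation."""
    tail, le1 = single_tone_branches[(A1, (5.0 * ic_sign, 0.0, 0.0))]
    assert classify_firing(tail, le1=le1).label == expected


def test_classification_invariant_to_resampling(two_tone_tails,
                                                two_tone_spectra):
    """Halving the sampling rate does not change the taxonomy call."""
    import dataclasses
    for f2 in (0.02, 0.04):
        tail = two_tone_tails[f2]
        coarse = dataclasses.replace(tail, t=tail.t[::2],
                                     states=tail.states[::2],
                                     sample_dt=tail.sample_dt * 2)
        a = classify_firing(tail, le1=two_tone_spectra[f2].le1)
        b = classify_firing(coarse, le1=two_tone_spectra[f2].le1)
        assert a.label == b.label
        assert a.spikes_per_burst == b.spikes_per_burst


def test_indeterminate_band():
    t, x = gaussian_bumps(np.arange(5.0, 95.0, 3.0))
    pat = classify_firing(make_traj(t, x), le1=0.001)
    assert pat.label.startswith("indeterminate")
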