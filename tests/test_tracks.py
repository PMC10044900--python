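"""Synthetic multi-track pulse generator: geometry, Poisson statistics,
energy bookkeeping, determinism."""

import math

import numpy as np
import pytest
from scipy import stats

import frickesim as fs
from frickesim.tracks import (DEFAULT_INITIAL_YIELDS, DEFAULT_SPUR_RMS_NM,
                              CalibrationError, PulseConfig,
                              calibrate_initial_yields, generate_pulse,
                              sample_deposition_events, sample_track_axes,
                              segment_length, speciate_event)


def test_axes_uniform_over_disc():
    rng = np.random.default_rng(1)
    axes = sample_track_axes(100_000, 0.1, rng)
    r = np.hypot(axes[:, 0], axes[:, 1])
    r0_nm = 100.0
    assert r.max() <= r0_nm
    # mean radius of a uniform disc is 2R/3
    assert abs(r.mean() - 2 * r0_nm / 3) / (2 * r0_nm / 3) < 0.01
    # Kolmogorov-Smirnov against the radial CDF r^2/R0^2
    ks = stats.kstest(r, lambda x: (x / r0_nm) ** 2)
    assert ks.pvalue > 1e-3


def test_axes_determinism_and_validation():
    a = sample_track_axes(50, 0.1, np.random.default_rng(7))
    b = sample_track_axes(50, 0.1, np.random.default_rng(7))
    assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        sample_track_axes(0, 0.1, np.random.default_rng(0))
    with pytest.raises(ValueError):
        sample_track_axes(1, -0.1, np.random.default_rng(0))


def test_deposition_events_poisson_statistics():
    rng = np.random.default_rng(3)
    totals, counts = [], []
    for _ in range(300):
        centers, energies = sample_deposition_events(
            np.zeros(2), 100.0, 0.3, 60.0, rng)
        totals.append(energies.sum())
        counts.append(len(energies))
        assert centers[:, 1].min() >= 0 and centers[:, 1].max() <= 100e3
    # expected total energy LET*L = 30 keV; events/um = LET/mean_event = 5
    assert abs(np.mean(totals) - 30e3) / 30e3 < 0.02
    assert abs(np.mean(counts) / 100.0 - 5.0) < 0.1


def test_zero_length_gives_no_events():
    centers, energies = sample_deposition_events(
        np.zeros(2), 0.0, 0.3, 60.0, np.random.default_rng(0))
    assert len(energies) == 0


def test_speciate_event_zero_radius_pins_particles():
    rng = np.random.default_rng(0)
    center = np.array([5.0, 6.0, 7.0])
    names, pos = speciate_event(center, 500.0, {"OH": 5.0}, {"OH": 0.0}, rng)
    assert len(names) > 0
    assert np.allclose(pos, center)


def test_speciate_event_unknown_species_rejected():
    with pytest.raises(KeyError):
        speciate_event(np.zeros(3), 100.0, {"OH": 5.0}, {"H": 1.0},
                       np.random.default_rng(0))


def test_total_particle_count_matches_yield_table():
    # law of large numbers over ~1e4 events
    rng = np.random.default_rng(11)
    yields = {"OH": 5.0, "e-aq": 4.0}
    rms = {"OH": 1.0, "e-aq": 3.0}
    total, energy = 0, 0.0
    for _ in range(10_000):
        e = rng.exponential(60.0)
        names, _pos = speciate_event(np.zeros(3), e, yields, rms, rng)
        total += len(names)
        energy += e
    expected = energy * sum(yields.values()) / 100.0
    assert abs(total - expected) < 3.0 * math.sqrt(expected)


def test_generate_pulse_energy_bookkeeping_and_determinism():
    cfg = PulseConfig(n_tracks=2, length_um=10.0, seed=5)
    cloud = generate_pulse(cfg)
    again = generate_pulse(cfg)
    assert cloud.energy_ev == again.energy_ev
    assert np.array_equal(cloud.positions_nm, again.positions_nm)
    assert np.array_equal(cloud.species, again.species)
    # expectation: N * LET * L = 2 * 0.3 keV/um * 10 um = 6 keV
    totals = [generate_pulse(PulseConfig(n_tracks=2, length_um=10.0, seed=s)).energy_ev
              for s in range(40)]
    assert abs(np.mean(totals) - 6e3) / 6e3 < 0.15


def test_segment_length_schedule_envelope():
    assert math.isclose(segment_length(1), 100.0)
    assert math.isclose(segment_length(1000), 5.0)
    for n in (1, 10, 50, 100, 500, 1000):
        assert 5.0 - 1e-9 <= segment_length(n) <= 150.0
        if n > 1:
            assert segment_length(n) < segment_length(n - 1 if n > 1 else 1) + 1e-9


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        PulseConfig(n_tracks=0)
    with pytest.raises(ValueError):
        PulseConfig(let_kev_um=-1.0)
    with pytest.raises(ValueError):
        PulseConfig(initial_yields={"OH": -1.0})


def test_zero_tolerance_calibration_declared_unreachable():
    rset = fs.load_reaction_set("fricke_core")
    with pytest.raises(CalibrationError, match="tolerance"):
        calibrate_initial_yields(PulseConfig(), rset, tolerance=0.0)


def test_default_tables_cover_each_other():
    assert set(DEFAULT_INITIAL_YIELDS) == set(DEFAULT_SPUR_RMS_NM)
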