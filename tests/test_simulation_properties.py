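"""End-to-end physical invariants of the IRT simulation."""

import dataclasses
import math

import numpy as np
import pytest

import frickesim as fs
from frickesim.dosimetry import PrimaryYields, stoichiometric_yield


def _g200(run):
    return run.g_at("Fe3+", 200.0)


def test_seed_determinism_of_experiments(reaction_set):
    cfg = fs.PulseConfig(length_um=10.0)
    medium = fs.standard_fricke_medium()
    a = fs.run_pulse_experiment(cfg, medium, reaction_set, 3, master_seed=5)
    b = fs.run_pulse_experiment(cfg, medium, reaction_set, 3, master_seed=5)
    assert np.array_equal(a.counts, b.counts)
    assert np.array_equal(a.energies_ev, b.energies_ev)
    c = fs.run_pulse_experiment(cfg, medium, reaction_set, 3, master_seed=6)
    assert not np.array_equal(a.counts, c.counts)


def test_single_history_refused_for_sem():
    with pytest.raises(ValueError):
        fs.run_pulse_experiment(fs.PulseConfig(), fs.standard_fricke_medium(),
                                fs.load_reaction_set("fricke_core"),
                                n_histories=1, master_seed=0)


def test_ferric_series_nondecreasing_and_nonnegative(baseline_runs):
    for run in baseline_runs.values():
        g = run.g_mean("Fe3+")
        assert np.all(np.diff(g) >= -1e-12)
        for sp in run.species:
            assert np.all(run.g_mean(sp) >= -1e-12)


def test_stoichiometric_consistency_with_own_escape_yields(
        calibration, baseline_runs):
    """G(Fe3+)(200 s) must equal the closed forms evaluated with the same
    configuration's simulated escape yields, within 2 SEM."""
    _cfg, log = calibration
    meas = log[-1]["measured"]
    g = PrimaryYields(g_oh=meas["OH"], g_eh=meas["eH"],
                      g_h2o2=meas["H2O2"], g_ho2=0.02)
    for label, aerated in [("aerated", True), ("deaerated", False)]:
        sim, sem = _g200(baseline_runs[label])
        expected = stoichiometric_yield(g, aerated)
        # escape-yield measurement noise (~1%) adds to the run SEM
        slack = 2.0 * math.hypot(sem, 0.01 * expected)
        assert abs(sim - expected) <= slack, (label, sim, expected)


def test_aerated_exceeds_deaerated(baseline_runs):
    aer, aer_sem = _g200(baseline_runs["aerated"])
    de, de_sem = _g200(baseline_runs["deaerated"])
    assert aer - de > 2.0 * math.hypot(aer_sem, de_sem)
    # the oxygen effect is the tripled hydrogen-atom chain: ~2*g(e+H)
    assert 5.0 < aer - de < 10.0


def test_yield_monotone_in_cystamine(baseline_runs):
    g0, s0 = _g200(baseline_runs["aerated"])
    g5, s5 = _g200(baseline_runs["cys_1e-5"])
    g1, s1 = _g200(baseline_runs["cys_1"])
    assert g5 <= g0 + 2 * math.hypot(s0, s5)
    assert g1 < g5 - 2 * math.hypot(s1, s5)     # 1 M protects strongly


def test_yield_monotone_in_track_number(calibrated_config, reaction_set,
                                        baseline_runs):
    """More simultaneous tracks -> more intertrack recombination -> fewer
    radicals survive for ferrous oxidation (at fixed low cystamine)."""
    g1, s1 = _g200(baseline_runs["cys_1e-5"])
    pulse = dataclasses.replace(calibrated_config, n_tracks=20, length_um=5.0)
    medium = fs.standard_fricke_medium(cystamine=1e-5)
    run20 = fs.run_pulse_experiment(pulse, medium, reaction_set,
                                    n_histories=4, master_seed=23)
    g20, s20 = _g200(run20)
    assert g20 < g1 - 2.0 * math.hypot(s1, s20)


def test_scavenger_limit_matches_homogeneous_oracle(
        calibration, baseline_runs, reaction_set):
    """At N = 1 and cystamine <= 1e-5 M the track has fully dissipated long
    before the slow ferrous steps, so IRT must agree with the well-mixed
    branching model fed the same escape yields."""
    _cfg, log = calibration
    meas = log[-1]["measured"]
    g = PrimaryYields(g_oh=meas["OH"], g_eh=meas["eH"],
                      g_h2o2=meas["H2O2"], g_ho2=0.02)
    for label, conc in [("aerated", 0.0), ("cys_1e-5", 1e-5)]:
        medium = fs.standard_fricke_medium(cystamine=conc)
        oracle = fs.predict_fricke_yield(g, medium, reaction_set)
        sim, sem = _g200(baseline_runs[label])
        # the oracle brackets the second-order fate of the cystamine radical
        # cation, which the well-mixed model cannot resolve by itself
        slack = 2.0 * math.hypot(sem, 0.01 * oracle.value)
        assert oracle.lower - slack <= sim <= oracle.upper + slack, (
            label, sim, oracle.lower, oracle.upper)


def test_reservoir_depletion_warning_fires(reaction_set):
    """A deliberately tiny ferrous reservoir must trip the 5% consumption
    warning rather than silently breaking pseudo-first-order kinetics."""
    medium = fs.speciate_medium(fs.MediumComposition(fe2=1e-10))
    cfg = fs.PulseConfig(length_um=20.0)
    with pytest.warns(RuntimeWarning, match="Fe2"):
        fs.run_pulse_experiment(cfg, medium, reaction_set, 2, master_seed=1)
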