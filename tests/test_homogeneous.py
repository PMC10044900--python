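"""Well-mixed branching-tree oracle and its stiff-ODE twin."""

import math

import numpy as np
import pytest

import frickesim as fs
from frickesim.dosimetry import PRINTED_PRIMARY_YIELDS, stoichiometric_yield
from frickesim.homogeneous import (branching_tree, ode_crosscheck,
                                   predict_fricke_yield)
from frickesim.medium import corrected_rate


@pytest.fixture(scope="module")
def full_set():
    return fs.load_reaction_set("fricke_cystamine_full")


def test_zero_cystamine_reduces_to_closed_forms(full_set):
    g = PRINTED_PRIMARY_YIELDS
    deaer = predict_fricke_yield(g, fs.standard_fricke_medium(aerated=False), full_set)
    assert math.isclose(deaer.value, stoichiometric_yield(g, False), rel_tol=1e-9)
    aer = predict_fricke_yield(g, fs.standard_fricke_medium(aerated=True), full_set)
    # the network keeps the slow H + Fe2+ channel open even when O2 is
    # present (branching fraction ~0.2%), so agreement is to ~0.2%
    assert math.isclose(aer.value, stoichiometric_yield(g, True), rel_tol=2e-3)
    assert aer.lower == aer.upper == aer.value      # no cystamine: no bracket


def test_oh_branching_fractions_against_hand_enumeration(full_set):
    """With the radical cation forced inert, E[OH -> Fe3+] must equal the
    direct capture fraction (Fe2+ and HSO4- routes), enumerated by hand from
    the same corrected rates."""
    medium = fs.standard_fricke_medium(cystamine=1e-5)
    ion = medium.ionic_strength
    k3 = 3.4e8 * 1e-3                              # OH + Fe2+ (neutral OH)
    k12 = 1.7e10 * 1e-5                            # OH + RSSR
    ks1 = corrected_rate(4.7e5, 0, -1, ion) * medium.hso4   # OH + HSO4-
    expected = (k3 + ks1) / (k3 + k12 + ks1)
    tree = branching_tree(full_set, medium, rssr_cation_fate="disproportionation")
    assert math.isclose(tree["OH"], expected, rel_tol=1e-9)
    # with the dilute-limit fate every captured OH still oxidizes one ferrous
    assert math.isclose(branching_tree(full_set, medium)["OH"], 1.0, rel_tol=1e-9)


def test_high_cystamine_limit_bracketed(full_set):
    g = PRINTED_PRIMARY_YIELDS
    res = predict_fricke_yield(g, fs.standard_fricke_medium(cystamine=1.0), full_set)
    base = predict_fricke_yield(g, fs.standard_fricke_medium(), full_set)
    assert res.lower <= res.value <= res.upper
    assert res.upper < base.value          # cystamine always lowers the yield
    assert res.lower > 0.0                 # floor from reactions (13),(14),(17)


@pytest.mark.parametrize("cystamine,aerated", [
    (0.0, True), (0.0, False), (1e-5, True), (1e-3, False)])
def test_tree_and_ode_agree(full_set, cystamine, aerated):
    g = PRINTED_PRIMARY_YIELDS
    medium = fs.standard_fricke_medium(cystamine=cystamine, aerated=aerated)
    tree = predict_fricke_yield(g, medium, full_set)
    _t, g_ode = ode_crosscheck(g, medium, full_set)
    assert abs(g_ode[-1] - tree.value) / tree.value < 1e-3


def test_peroxide_step_sets_the_plateau_timescale(full_set):
    """Half-life of H2O2 + Fe2+ at 1 mM ferrous is ln2/(52e-3) ~ 13.3 s,
    which is why the ferric yield only saturates near 200 s."""
    g = PRINTED_PRIMARY_YIELDS
    medium = fs.standard_fricke_medium()
    t, g_ode = ode_crosscheck(g, medium, full_set)
    half_life = math.log(2) / (52.0 * 1e-3)
    assert math.isclose(half_life, 13.33, abs_tol=0.01)
    g_final = g_ode[-1]
    # the still-missing yield at t = t_1/2 is half the peroxide contribution
    g_at_half = np.interp(half_life, t, g_ode)
    missing = g_final - g_at_half
    h2o2_contrib = 2.0 * g.g_h2o2 + g.g_eh + 3 * g.g_ho2  # chain H2O2 included
    assert 0.2 * h2o2_contrib < missing < h2o2_contrib


def test_linearity_in_injected_yields(full_set):
    from frickesim.dosimetry import PrimaryYields
    g1 = PRINTED_PRIMARY_YIELDS
    g2 = PrimaryYields(2 * g1.g_oh, 2 * g1.g_eh, 2 * g1.g_h2o2, 2 * g1.g_ho2)
    medium = fs.standard_fricke_medium(cystamine=1e-4)
    a = predict_fricke_yield(g1, medium, full_set).value
    b = predict_fricke_yield(g2, medium, full_set).value
    assert math.isclose(b, 2 * a, rel_tol=1e-12)
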