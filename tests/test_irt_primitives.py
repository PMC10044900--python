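"""IRT sampling primitives validated against closed forms and a brute-force
Brownian-dynamics absorption oracle."""

import math

import numpy as np
import pytest

import frickesim as fs
from frickesim.irt import (effective_radius, run_single_cloud,
                           sample_pair_reaction_time, sample_scavenging_time)
from frickesim.tracks import InitialSpeciesCloud, PulseConfig

from brownian import brownian_absorption_fraction


def test_effective_radius_inversion():
    # unit-checked evaluation: 1e10 M^-1 s^-1 at D' = 5e-9 m^2/s -> 0.264 nm
    assert math.isclose(effective_radius(1e10, 5e-9) * 1e9, 0.2643, abs_tol=5e-4)
    assert math.isclose(effective_radius(1e10, 1e-8),
                        effective_radius(1e10, 5e-9) / 2)
    assert effective_radius(1e4, 5e-9) < 1e-15    # k -> 0 gives Reff -> 0
    with pytest.raises(ValueError):
        effective_radius(-1.0, 5e-9)
    with pytest.raises(ValueError):
        effective_radius(1e10, 0.0)


def test_contact_pair_reacts_immediately():
    rng = np.random.default_rng(0)
    t = sample_pair_reaction_time(np.full(1000, 0.25), 0.25, 5e-9, rng)
    assert np.all(t == 0.0)


def test_distant_pair_never_reacts():
    rng = np.random.default_rng(0)
    t = sample_pair_reaction_time(np.full(2000, 2.5e4), 0.25, 5e-9, rng)
    assert np.isinf(t).mean() > 0.999


def test_ultimate_reaction_probability_is_reff_over_r0():
    rng = np.random.default_rng(42)
    reff = 0.25
    t = sample_pair_reaction_time(np.full(100_000, 2 * reff), reff, 5e-9, rng)
    frac = np.isfinite(t).mean()
    assert abs(frac - 0.5) < 3.0 * math.sqrt(0.25 / 100_000)


@pytest.mark.parametrize("ratio", [1.5, 2.0, 5.0])
def test_pair_time_sampler_agrees_with_brownian_oracle(ratio):
    """Reaction fraction by a finite horizon: IRT inverse-CDF sampling vs. a
    random-walk absorption simulation on the same geometry, within 3 sigma."""
    reff, d_mut = 0.5, 5e-9
    r0 = ratio * reff
    d_nm2 = d_mut * 1e18
    t_max = 25.0 * (r0 - reff) ** 2 / (4.0 * d_nm2)
    rng = np.random.default_rng(2024)
    t_irt = sample_pair_reaction_time(np.full(100_000, r0), reff, d_mut, rng)
    frac_irt = float((t_irt <= t_max).mean())
    n_walk = 4000
    frac_walk = brownian_absorption_fraction(
        r0, reff, d_mut, t_max, n_walkers=n_walk, n_steps=3000,
        rng=np.random.default_rng(7))
    sigma = math.sqrt(frac_walk * (1 - frac_walk) / n_walk
                      + frac_irt * (1 - frac_irt) / 100_000)
    assert abs(frac_irt - frac_walk) < 3.0 * sigma


def test_scavenging_time_exponential_mean():
    rng = np.random.default_rng(5)
    k, conc = 3.4e8, 1e-3
    t = sample_scavenging_time(k, conc, rng, size=100_000)
    assert abs(t.mean() * k * conc - 1.0) < 0.01
    assert math.isinf(sample_scavenging_time(k, 0.0, rng))
    with pytest.raises(ValueError):
        sample_scavenging_time(k, -1e-3, rng)


# -- single-radical cascade bookkeeping ------------------------------------

@pytest.fixture(scope="module")
def full_set():
    return fs.load_reaction_set("fricke_cystamine_full")


def _single_radical_fe3(full_set, species, aerated):
    cloud = InitialSpeciesCloud(
        species=np.array([species], dtype=object),
        positions_nm=np.zeros((1, 3)), energy_ev=100.0,
        config=PulseConfig(), seed=0)
    medium = fs.standard_fricke_medium(aerated=aerated)
    ts = run_single_cloud(cloud, medium, full_set, seed=3)
    return int(ts.counts[0, ts.species.index("Fe3+"), -1])


@pytest.mark.parametrize("species,aerated,expected", [
    ("OH", True, 1),        # direct ferrous oxidation
    ("e-aq", True, 3),      # e-aq -> H -> HO2 -> Fe3+ + H2O2 -> OH chain
    ("e-aq", False, 1),     # without O2, H oxidizes a single ferrous ion
])
def test_single_radical_ferric_count(full_set, species, aerated, expected):
    assert _single_radical_fe3(full_set, species, aerated) == expected
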