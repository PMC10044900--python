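"""Brute-force Brownian-dynamics absorption oracle for validating the IRT
pair-time sampler.

Simulates the relative coordinate of a diffusing pair around a perfectly
absorbing sphere of radius Reff, with a Brownian-bridge correction for
barrier crossings between discrete steps.  Independent of the sampler it
checks: no Green's-function inversion, just random walks.
"""

from __future__ import annotations

import numpy as np


def brownian_absorption_fraction(r0_nm: float, reff_nm: float, d_mutual_m2s: float,
                                 t_max_s: float, n_walkers: int, n_steps: int,
                                 rng: np.random.Generator) -> float:
    """Fraction of pairs absorbed by ``t_max_s``, starting at separation r0."""
    d_nm2 = d_mutual_m2s * 1e18
    dt = t_max_s / n_steps
    sigma = np.sqrt(2.0 * d_nm2 * dt)
    pos = np.zeros((n_walkers, 3))
    pos[:, 0] = r0_nm
    alive = np.ones(n_walkers, dtype=bool)
    for _ in range(n_steps):
        idx = np.flatnonzero(alive)
        if not len(idx):
            break
        prev_gap = np.linalg.norm(pos[idx], axis=1) - reff_nm
        step = rng.standard_normal((len(idx), 3)) * sigma
        pos[idx] += step
        gap = np.linalg.norm(pos[idx], axis=1) - reff_nm
        hit = gap <= 0.0
        # Brownian-bridge probability of having touched the sphere in between
        safe = ~hit
        p_cross = np.exp(-np.maximum(prev_gap[safe], 0.0)
                         * np.maximum(gap[safe], 0.0) / (d_nm2 * dt))
        crossed = rng.random(safe.sum()) < p_cross
        absorbed = np.zeros(len(idx), dtype=bool)
        absorbed[hit] = True
        absorbed[np.flatnonzero(safe)[crossed]] = True
        alive[idx[absorbed]] = False
    return 1.0 - alive.mean()
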