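"""Dose-rate dependence of cystamine's protective effect (scaled down).

Compares G(Fe3+) with and without cystamine at N = 1 and N = 200 tracks
per pulse.  At high N, intertrack radical recombination removes the very
radicals cystamine would scavenge, so the drug's incremental protection
shrinks — the mechanism behind the FLASH-regime observation.  Scaled-down
segments and histories keep this desk-sized (several minutes).
"""

import dataclasses

import frickesim as fs

rset = fs.load_reaction_set("fricke_cystamine_full")
config, _ = fs.calibrate_initial_yields(fs.PulseConfig(), rset, seed=12345)

print(f"{'N':>5s} {'[RSSR]/M':>9s} {'G(Fe3+)':>8s} {'SEM':>6s}   dose/pulse")
for n_tracks, length, hist in [(1, 100.0, 6), (200, 3.0, 3)]:
    pulse = dataclasses.replace(config, n_tracks=n_tracks, length_um=length)
    dose = fs.dose_per_pulse(n_tracks, pulse.let_kev_um, length, pulse.r0_um)
    for conc in (0.0, 1e-3):
        medium = fs.standard_fricke_medium(cystamine=conc)
        ts = fs.run_pulse_experiment(pulse, medium, rset,
                                     n_histories=hist, master_seed=5)
        g, sem = ts.g_at("Fe3+", 200.0)
        print(f"{n_tracks:5d} {conc:9.0e} {g:8.2f} {sem:6.2f}   {dose.dose_gy:8.1f} Gy")
print("the cystamine-induced drop is largest at N = 1: at high dose rate the")
print("tracks already destroy their own radicals before the drug can act")
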