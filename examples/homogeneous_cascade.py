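"""Well-mixed competition kinetics: how cystamine diverts the radicals.

The branching-tree oracle resolves each primary species among its
pseudo-first-order channels (Fe2+, O2, H+, HSO4-, cystamine) and follows
the product cascades to ferric or inert leaves; a stiff ODE integration of
the same network confirms it.
"""

import frickesim as fs

rset = fs.load_reaction_set("fricke_cystamine_full")
g = fs.PRINTED_PRIMARY_YIELDS

print("scavenger-limit G(Fe3+) at 200 s [molecules/100 eV]:")
print(f"{'[cystamine]/M':>14s} {'aerated':>9s} {'deaerated':>10s}  bracket (aer)")
for conc in [0.0, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0]:
    aer = fs.predict_fricke_yield(g, fs.standard_fricke_medium(cystamine=conc), rset)
    de = fs.predict_fricke_yield(
        g, fs.standard_fricke_medium(cystamine=conc, aerated=False), rset)
    print(f"{conc:14.0e} {aer.value:9.2f} {de.value:10.2f}"
          f"  [{aer.lower:.2f}, {aer.upper:.2f}]")

m = fs.standard_fricke_medium()
t, g_ode = fs.ode_crosscheck(g, m, rset)
print(f"\nODE twin, no cystamine, aerated: G(200 s) = {g_ode[-1]:.3f}")
print("the bracket covers the second-order fate of the cystamine radical")
print("cation, which the well-mixed model cannot resolve by itself;")
print("the slow H2O2 + Fe2+ step (half-life 13.3 s) sets the ~200 s plateau")
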