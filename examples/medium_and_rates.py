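"""Sulfate speciation of the Fricke medium and ionic-strength corrections.

0.4 M H2SO4 dissociates completely once and partially twice; the resulting
ionic strength (~0.42 M) shifts every ion-ion rate constant via the
Brønsted–Bjerrum factor.
"""

import frickesim as fs
from frickesim.medium import corrected_rate

m = fs.standard_fricke_medium()
print(f"0.4 M H2SO4 + 1 mM FeSO4 (air-saturated):")
print(f"  [H+]   = {m.h_plus:.4f} M")
print(f"  [HSO4-]= {m.hso4:.4f} M, [SO42-] = {m.so4:.4f} M "
      f"(sulfate conserved: {m.hso4 + m.so4:.4f} M)")
print(f"  ionic strength I = {m.ionic_strength:.3f} M")
print(f"  reported pH (H+ activity) = {m.ph:.2f}   <- a pH meter reads ~0.46")

k1 = 2.3e10
k1_eff = corrected_rate(k1, -1, +1, m.ionic_strength)
print(f"\ne-aq + H+ -> H:  k0 = {k1:.2e}  ->  k(I) = {k1_eff:.2e} M^-1 s^-1")
print("  opposite charges attract less effectively in a salty medium, so the")
print(f"  rate drops by {100 * (1 - k1_eff / k1):.0f}%; neutral partners are untouched:")
print(f"  OH + Fe2+: {corrected_rate(3.4e8, 0, 2, m.ionic_strength):.2e} (= k0)")
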