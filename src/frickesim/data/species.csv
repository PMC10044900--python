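name,charge,diffusion_m2_s,tags,provenance,note
e-aq,-1,4.9e-9,radiolytic_primary,literature-default,hydrated electron
H+,1,9.46e-9,radiolytic_primary;background_solute,literature-default,hydronium ion (H3O+)
H,0,7.0e-9,radiolytic_primary,literature-default,hydrogen atom
OH,0,2.2e-9,radiolytic_primary,literature-default,hydroxyl radical
OH-,-1,5.3e-9,radiolytic_primary,literature-default,hydroxide ion
H2,0,4.8e-9,radiolytic_primary,literature-default,molecular hydrogen
H2O2,0,2.3e-9,radiolytic_primary,literature-default,hydrogen peroxide
HO2,0,2.0e-9,radiolytic_primary,literature-default,hydroperoxyl radical
O2-,-1,1.75e-9,radiolytic_primary,literature-default,superoxide radical anion
O2,0,2.4e-9,background_solute,literature-default,dissolved oxygen
HO2-,-1,1.4e-9,product,literature-default,hydroperoxide anion
Fe2+,2,0.72e-9,background_solute,literature-default,ferrous ion
Fe3+,3,0.6e-9,product,literature-default,ferric ion (the dosimeter signal)
HSO4-,-1,1.33e-9,background_solute,literature-default,bisulfate ion
SO42-,-2,1.07e-9,background_solute,literature-default,sulfate ion
SO4-,-1,1.0e-9,product,literature-default,sulfate radical anion
S2O82-,-2,1.0e-9,product,literature-default,peroxydisulfate ion
RSSR,2,0.6e-9,background_solute,literature-default,cystamine; doubly protonated (+NH3-CH2-CH2-S-)2 below pH 8
RSSR-,1,0.6e-9,product,literature-default,cystamine radical anion (disulfide electron adduct; net charge +1 with both amines protonated)
RSSR+,3,0.6e-9,product,literature-default,cystamine radical cation (net +3 with both amines protonated)
RSSR2+,4,0.6e-9,product,literature-default,two-electron oxidized cystamine (inert here)
RS,1,0.8e-9,product,literature-default,cysteamine thiyl radical (amine protonated)
RS-,0,0.8e-9,product,literature-default,cysteamine thiolate (zwitterion; net 0)
RSH,1,0.9e-9,product,literature-default,cysteamine (amine protonated)
RSSSR,2,0.5e-9,product,literature-default,trisulfide product of RS + RSSR
R,1,1.0e-9,product,literature-default,carbon-centred radical from S-C cleavage (amine protonated)
ROO,1,0.8e-9,product,literature-default,peroxyl radical from R + O2
ROO-,0,0.8e-9,product,literature-default,peroxyl electron-transfer product before protonation
ROOH,1,0.8e-9,product,literature-default,hydroperoxide end product
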