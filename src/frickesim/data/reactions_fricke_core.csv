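label,reactants,products,co_reactants,k0,kind,zA,zB,exempt_ionic,provenance,note
F1,e-aq;H+,H,,2.3e10,pair_diffusive,-1,1,false,printed-in-paper,acid conversion of the hydrated electron
F2,H;O2,HO2,,2.1e10,scavenging,0,0,false,printed-in-paper,oxygen capture of H in aerated solution
F3,OH;Fe2+,Fe3+;OH-,,3.4e8,scavenging,0,2,false,printed-in-paper,direct ferrous oxidation by OH
F4,HO2;Fe2+,Fe3+;HO2-,,7.9e5,scavenging,0,2,false,printed-in-paper,ferrous oxidation by hydroperoxyl
F5,HO2-;H+,H2O2,,5.0e10,scavenging,-1,1,false,printed-in-paper,protonation of hydroperoxide anion
F6,H2O2;Fe2+,Fe3+;OH;OH-,,52,scavenging,0,2,false,printed-in-paper,Fenton step; slowest ferrous oxidation channel
F7,H;Fe2+,Fe3+;H2,H+,1.3e7,scavenging,0,2,false,printed-in-paper,deaerated route; consumes one acid proton (reservoir co-reactant)
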