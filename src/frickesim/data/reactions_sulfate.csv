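label,reactants,products,co_reactants,k0,kind,zA,zB,exempt_ionic,provenance,note
S1,OH;HSO4-,SO4-,,4.7e5,scavenging,0,-1,false,literature-default,small OH leak to sulfate radical in 0.4 M acid
S2,SO4-;Fe2+,Fe3+;SO42-,,9.9e8,scavenging,-1,2,false,printed-in-paper,sulfate radical oxidizes ferrous like OH does
S3,SO4-;SO4-,S2O82-,,7.6e8,pair_diffusive,-1,-1,false,literature-default,
S4,SO4-;H2O2,HSO4-;HO2,,1.2e7,pair_diffusive,-1,0,false,literature-default,
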