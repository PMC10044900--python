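label,reactants,products,co_reactants,k0,kind,zA,zB,exempt_ionic,provenance,note
W1,e-aq;e-aq,H2;OH-;OH-,,5.5e9,pair_diffusive,-1,-1,true,literature-default,electron self-recombination; exempt from ionic-strength correction
W2,e-aq;OH,OH-,,3.0e10,pair_diffusive,-1,0,false,literature-default,
W3,e-aq;H,H2;OH-,,2.5e10,pair_diffusive,-1,0,false,literature-default,
W4,e-aq;H2O2,OH;OH-,,1.1e10,pair_diffusive,-1,0,false,literature-default,
W5,e-aq;O2,O2-,,1.9e10,scavenging,-1,0,false,literature-default,
W6,e-aq;HO2,HO2-,,1.3e10,pair_diffusive,-1,0,false,literature-default,
W7,OH;OH,H2O2,,5.5e9,pair_diffusive,0,0,false,literature-default,spur source of peroxide
W8,OH;H,,,7.0e9,pair_diffusive,0,0,false,literature-default,water reformation
W9,OH;H2,H,,4.2e7,pair_diffusive,0,0,false,literature-default,
W10,OH;H2O2,HO2,,2.7e7,pair_diffusive,0,0,false,literature-default,
W11,OH;HO2,O2,,6.0e9,pair_diffusive,0,0,false,literature-default,
W12,H;H,H2,,7.8e9,pair_diffusive,0,0,false,literature-default,
W13,H;H2O2,OH,,9.0e7,pair_diffusive,0,0,false,literature-default,
W14,H;HO2,H2O2,,1.0e10,pair_diffusive,0,0,false,literature-default,
W15,HO2;HO2,H2O2;O2,,8.3e5,pair_diffusive,0,0,false,literature-default,
W16,O2-;H+,HO2,,4.5e10,scavenging,-1,1,false,literature-default,protonation of superoxide; dominant below pKa 4.8
W17,HO2,O2-;H+,,7.0e5,unimolecular,0,0,false,literature-default,HO2 deprotonation; with W16 gives pKa ~= 4.8
W18,OH-;H+,,,1.4e11,pair_diffusive,-1,1,false,literature-default,neutralization
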