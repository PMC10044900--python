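label,reactants,products,co_reactants,k0,kind,zA,zB,exempt_ionic,provenance,note
C10,RSSR;e-aq,RSSR-,,4.1e10,scavenging,2,-1,false,printed-in-paper,electron capture by the disulfide
C11,RSSR;H,RS;RSH,,8.0e9,scavenging,2,0,false,printed-in-paper,H-atom cleavage of the disulfide bond
C12,RSSR;OH,RSSR+;OH-,,1.7e10,scavenging,2,0,false,printed-in-paper,OH oxidation of the disulfide
C13,Fe2+;RS,Fe3+;RS-,,2.5e8,scavenging,2,1,false,printed-in-paper,thiyl radical oxidizes ferrous
C14,Fe2+;RSSR+,Fe3+;RSSR,,2.0e6,scavenging,2,3,false,printed-in-paper,cystamine radical cation oxidizes ferrous
C15,RS;RSSR,RSSSR;R,,1.0e6,scavenging,1,2,false,printed-in-paper,thiyl attack on excess cystamine
C16,R;O2,ROO,,2.0e9,scavenging,1,0,false,printed-in-paper,peroxyl formation in aerated solution
C17,Fe2+;ROO,Fe3+;ROO-,,7.9e5,scavenging,2,1,false,printed-in-paper,electron-transfer half of the printed Fe2+ + ROO + H+ step
C17b,ROO-;H+,ROOH,,5.0e10,scavenging,0,1,false,literature-default,protonation completing the printed step
C18,RSSR+;RSSR+,RSSR2+;RSSR,,2.5e9,pair_diffusive,3,3,false,printed-in-paper,radical-cation disproportionation
C19,RSSR-,RS;RS-,,1.0e8,unimolecular,1,0,false,literature-default,assumed rapid dissociation of the disulfide electron adduct
C20,RS-;H+,RSH,,5.0e10,scavenging,0,1,false,literature-default,thiolate protonation in 0.4 M acid
C21,RS;RS,RSSR,,1.5e9,pair_diffusive,1,1,false,literature-default,thiyl radical dimerization
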