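# Position-parameter registry for AKIE computation.
# n: atoms of the element per molecule; x: atoms at reactive positions;
# z: indistinguishable reactive sites (intramolecular competition).
# provenance "printed" = literature default; "reconstructed" = the unique
# small-integer triple consistent with the published concerted-Cl AKIE.
compound,element,mechanism,n,x,z,provenance
PCE,C,one_step,2,1,4,printed
cDCE,C,one_step,2,1,2,printed
VC,C,one_step,2,1,1,printed
"1,2-DCA",C,concerted,2,2,2,printed
"1,2-DCA",C,stepwise,2,1,2,printed
PCE,Cl,one_step,4,1,4,printed
cDCE,Cl,one_step,2,1,2,printed
VC,Cl,one_step,1,1,1,printed
"1,2-DCA",Cl,concerted,2,2,2,reconstructed
"1,2-DCA",Cl,stepwise,2,1,2,printed
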