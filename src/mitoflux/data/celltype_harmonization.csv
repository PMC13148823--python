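source,target
cancer epithelial,epithelial
normal epithelial,epithelial
epithelial,epithelial
cafs,mesenchymal
caf,mesenchymal
pvl,mesenchymal
mesenchymal,mesenchymal
myeloid,myeloid
t,T
t-cells,T
t cells,T
endothelial,endothelial
plasmablasts,plasmablasts
b,
b-cells,
b cells,
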