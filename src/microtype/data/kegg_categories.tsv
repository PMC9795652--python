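pathway	category
ko00010	carbohydrate
ko00020	carbohydrate
ko00040	carbohydrate
ko00500	carbohydrate
ko00052	carbohydrate
ko00620	carbohydrate
ko00250	amino_acid
ko00260	amino_acid
ko00270	amino_acid
ko00330	amino_acid
ko00380	amino_acid
ko00400	amino_acid
ko00061	lipid
ko00071	lipid
ko00100	lipid
ko00120	lipid
ko00121	lipid
ko00561	lipid
ko00627	xenobiotic
ko00633	xenobiotic
ko00642	xenobiotic
ko00930	xenobiotic
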