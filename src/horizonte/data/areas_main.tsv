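# Leaf -> area coding, main variant: lineages whose range at the time of
# transfer can be narrowed by phylogenetic evidence are restricted —
# psittacid parrots to Australasia, suboscines to the Neotropics.
Trochilidae	Neotropics
Psittacidae	Australasia
Tinamidae	Neotropics
Mesitornithidae	Madagascar
Trogonidae	Africa,Indomalaya,Neotropics
Bucerotidae	Africa,Indomalaya
Suboscines	Africa,Indomalaya,Neotropics
BrugiaWuchereria	Neotropics,Africa,Madagascar,Indomalaya,Australasia
Loa	Neotropics,Africa,Madagascar,Indomalaya,Australasia
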