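# Leaf -> area coding, fossil-augmented variant: as the widest-range
# coding but hummingbirds additionally carry the Old World areas known
# from early-Oligocene fossils.
Trochilidae	Neotropics,Africa,Indomalaya
Psittacidae	Australasia,Africa,Indomalaya,Neotropics
Tinamidae	Neotropics
Mesitornithidae	Madagascar
Trogonidae	Africa,Indomalaya,Neotropics
Bucerotidae	Africa,Indomalaya
Suboscines	Africa,Indomalaya,Neotropics
BrugiaWuchereria	Neotropics,Africa,Madagascar,Indomalaya,Australasia
Loa	Neotropics,Africa,Madagascar,Indomalaya,Australasia
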