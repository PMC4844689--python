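# Leaf -> area coding, "widest distribution" variant: each lineage is
# coded for the widest plausible range at the time of transfer (mostly its
# present-day range); hornbills and suboscines exclude their marginal,
# recent Australasian representatives; nematode lineages are pantropical.
Trochilidae	Neotropics
Psittacidae	Australasia,Africa,Indomalaya,Neotropics
Tinamidae	Neotropics
Mesitornithidae	Madagascar
Trogonidae	Africa,Indomalaya,Neotropics
Bucerotidae	Africa,Indomalaya
Suboscines	Africa,Indomalaya,Neotropics
BrugiaWuchereria	Neotropics,Africa,Madagascar,Indomalaya,Australasia
Loa	Neotropics,Africa,Madagascar,Indomalaya,Australasia
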