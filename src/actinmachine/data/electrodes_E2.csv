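# Laboratory layout E2: every electrode both stimulates and records.
# The published coordinate table parses to 8 rows although the machine
# experiments used six electrodes; all parsed rows are kept here and the
# experiment configuration selects which labels form the k=6 set
# (package default: the first six labels).
label,i,j,z,radius
e0,369,567,6,4
e1,509,580,10,4
e2,631,590,10,4
e3,382,322,12,4
e4,533,331,23,4
e5,369,424,7,4
e6,572,691,17,4
e7,705,394,17,4
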