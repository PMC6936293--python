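# Laboratory layout E1: 10 electrodes on the 1024x1024x30 confocal network.
# Transcribed coordinate rows 1..10 are labelled e0..e9; e0 and e9 are the
# input electrodes of the two-input gate experiments, e1..e8 the outputs.
label,i,j,z,radius
e0,369,567,6,4
e1,509,580,10,4
e2,631,590,10,4
e3,382,322,12,4
e4,533,331,23,4
e5,626,463,7,4
e6,358,676,22,4
e7,369,424,7,4
e8,572,691,17,4
e9,705,394,17,4
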