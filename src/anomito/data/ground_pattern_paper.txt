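# Pancrustacean ground-pattern reference as printed in the comparative
# anomuran literature (32 genes; trnG, trnA, trnV, rrnL and rrnS omitted,
# strands not stated -> all plus by convention).
+cox1,+trnL1,+trnL2,+cox2,+trnK,+nad3,+trnM,+trnI,+nad2,+trnD,+atp8,+atp6,+cox3,+trnR,+trnN,+trnS1,+trnE,+trnF,+nad5,+trnH,+nad4,+nad4L,+trnT,+nad6,+cob,+trnS2,+trnP,+nad1,+trnW,+trnQ,+trnC,+trnY
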