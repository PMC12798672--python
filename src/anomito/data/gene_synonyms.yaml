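# Synonym table mapping heterogeneous GenBank gene/product labels onto the
# canonical 38-symbol vocabulary (13 PCGs, 22 tRNAs, 2 rRNAs, CR).
# Keys are matched case-insensitively after stripping spaces, hyphens,
# underscores and parenthesised anticodons. Editable: ship your own copy and
# pass it to read_genbank(synonyms=...).
cox1: [cox1, coxi, co1, coi, "cytochrome c oxidase subunit 1", "cytochrome c oxidase subunit i", "cytochrome oxidase subunit 1", "cytochrome oxidase subunit i"]
cox2: [cox2, coxii, co2, coii, "cytochrome c oxidase subunit 2", "cytochrome c oxidase subunit ii", "cytochrome oxidase subunit 2"]
cox3: [cox3, coxiii, co3, coiii, "cytochrome c oxidase subunit 3", "cytochrome c oxidase subunit iii", "cytochrome oxidase subunit 3"]
cob: [cob, cytb, cytob, "cytochrome b", "cytochrome b apoenzyme"]
nad1: [nad1, nd1, "nadh dehydrogenase subunit 1"]
nad2: [nad2, nd2, "nadh dehydrogenase subunit 2"]
nad3: [nad3, nd3, "nadh dehydrogenase subunit 3"]
nad4: [nad4, nd4, "nadh dehydrogenase subunit 4"]
nad4L: [nad4l, nd4l, "nadh dehydrogenase subunit 4l"]
nad5: [nad5, nd5, "nadh dehydrogenase subunit 5"]
nad6: [nad6, nd6, "nadh dehydrogenase subunit 6"]
atp6: [atp6, atpase6, "atp synthase f0 subunit 6", "atp synthase subunit 6"]
atp8: [atp8, atpase8, "atp synthase f0 subunit 8", "atp synthase subunit 8"]
rrnL: [rrnl, rrn16, 16s, "16s rrna", "16s ribosomal rna", lrrna, "l-rrna", "large subunit ribosomal rna"]
rrnS: [rrns, rrn12, 12s, "12s rrna", "12s ribosomal rna", srrna, "s-rrna", "small subunit ribosomal rna"]
CR: [cr, "d-loop", dloop, "control region", "putative control region", "at-rich region", "a+t-rich region"]
trnA: [trna, "trna-ala", trnala]
trnC: [trnc, "trna-cys", trncys]
trnD: [trnd, "trna-asp", trnasp]
trnE: [trne, "trna-glu", trnglu]
trnF: [trnf, "trna-phe", trnphe]
trnG: [trng, "trna-gly", trngly]
trnH: [trnh, "trna-his", trnhis]
trnI: [trni, "trna-ile", trnile]
trnK: [trnk, "trna-lys", trnlys]
trnL1: [trnl1, "trna-leu1", "trnl(tag)", "trna-leu(tag)", "trna-leu (cun)", "trnaleu(cun)"]
trnL2: [trnl2, "trna-leu2", "trnl(taa)", "trna-leu(taa)", "trna-leu (uur)", "trnaleu(uur)"]
trnM: [trnm, "trna-met", trnmet]
trnN: [trnn, "trna-asn", trnasn]
trnP: [trnp, "trna-pro", trnpro]
trnQ: [trnq, "trna-gln", trngln]
trnR: [trnr, "trna-arg", trnarg]
trnS1: [trns1, "trna-ser1", "trns(tct)", "trna-ser(tct)", "trna-ser (agn)", "trnaser(agn)"]
trnS2: [trns2, "trna-ser2", "trns(tga)", "trna-ser(tga)", "trna-ser (ucn)", "trnaser(ucn)"]
trnT: [trnt, "trna-thr", trnthr]
trnV: [trnv, "trna-val", trnval]
trnW: [trnw, "trna-trp", trntrp]
trnY: [trny, "trna-tyr", trntyr]
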