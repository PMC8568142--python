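# SYNTHETIC RECONSTRUCTION of the Lysmata vittata mitochondrial gene order,
# not a transcription of the deposited annotation.  It encodes the facts
# stated for this genome — 23 genes on the F strand and 14 on the R strand,
# rrnL between trnL1 and trnV, rrnS between trnV and the first control
# region, control regions flanking trnL2 and preceding trnI, and trnA/trnR
# translocated relative to the ancestral pancrustacean arrangement — with an
# arbitrary (but order-consistent) placement of the translocated pair.
# Qualitative tests assert only the translocation containment, never exact
# positions from this file.
+cox1 +trnL2 +cox2 +trnK +trnD +atp8 +atp6 +cox3 +trnG +nad3 +trnN +trnS1 +trnE -trnF -nad5 -trnH -nad4 -nad4l +trnA +trnT +trnR -trnP +nad6 +cob +trnS2 -nad1 -trnL1 -rrnL -trnV -rrnS +trnI -trnQ +trnM +nad2 +trnW -trnC -trnY
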