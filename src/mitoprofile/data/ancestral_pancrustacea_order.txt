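# Ancestral pancrustacean / Decapoda mitochondrial gene order (the inferred
# plesiomorphic arrangement used as the rearrangement reference), written in
# the one-line sign-prefixed token format, anchored at cox1.  Control regions
# are excluded from order comparison and therefore from this file.
# This file is editable: replace the line below to compare against a
# different reference arrangement.
+cox1 +trnL2 +cox2 +trnK +trnD +atp8 +atp6 +cox3 +trnG +nad3 +trnA +trnR +trnN +trnS1 +trnE -trnF -nad5 -trnH -nad4 -nad4l +trnT -trnP +nad6 +cob +trnS2 -nad1 -trnL1 -rrnL -trnV -rrnS +trnI -trnQ +trnM +nad2 +trnW -trnC -trnY
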