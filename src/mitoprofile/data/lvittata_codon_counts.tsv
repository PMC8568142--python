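# Published codon counts of the 13 protein-coding genes of the Lysmata
# vittata mitogenome (GenBank MT478132), RNA alphabet.  Complete stop codons
# are included; incomplete terminal remnants are not.
codon	count
UUU	300
UUC	57
UUA	283
UUG	32
CUU	131
CUC	33
CUA	59
CUG	5
AUU	266
AUC	42
AUA	191
AUG	24
GUU	95
GUC	8
GUA	87
GUG	19
UCU	129
UCC	29
UCA	92
UCG	12
CCU	101
CCC	14
CCA	28
CCG	6
ACU	85
ACC	23
ACA	61
ACG	5
GCU	93
GCC	25
GCA	50
GCG	6
UAU	101
UAC	28
UAA	10
UAG	1
CAU	53
CAC	19
CAA	55
CAG	13
AAU	108
AAC	23
AAA	83
AAG	11
GAU	56
GAC	18
GAA	64
GAG	31
UGU	32
UGC	9
UGA	92
UGG	15
CGU	12
CGC	2
CGA	38
CGG	11
AGU	45
AGC	7
AGA	93
AGG	25
GGU	61
GGC	20
GGA	106
GGG	43
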