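name	iupac	category
Box-4	ATTAAT	light
G-box	CACGTG	light
GA-motif	AAGGAAGA	light
AE-box	AGAAACAA	light
I-box	GATAAG	light
MRE	AACCTAA	light
ARE	AAACCA	stress
STRE	AGGGG	stress
LTR	CCGAAA	stress
DRE-core	GCCGAC	stress
ABRE	ACGTG	hormone
as-1	TGACG	hormone
CGTCA-motif	CGTCA	hormone
TGACG-motif	TGACG	hormone
ERE	ATTTCAAA	hormone
TGA-element	AACGAC	hormone
TCA-element	CCATCTTTTT	hormone
GARE-motif	TCTGTTG	hormone
CAT-box	GCCACT	development
circadian	CAANNNNATC	development
RY-element	CATGCATG	development
O2-site	GATGAYRTGG	development
GCN4-motif	TGAGTCA	development
MYB	CAACAG	MYB-related
MYC	CANNTG	MYB-related
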