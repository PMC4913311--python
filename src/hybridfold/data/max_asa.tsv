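# Maximum accessible surface area per residue type (A^2), for relative accessibility.
# hubbard: Ala-X-Ala tripeptide values of Hubbard & Thornton (NACCESS-compatible).
# tien2013: theoretical maxima of Tien et al. 2013.
residue	hubbard	tien2013
ALA	107.95	129.0
ARG	238.76	274.0
ASN	143.94	195.0
ASP	140.39	193.0
CYS	134.28	167.0
GLN	178.50	225.0
GLU	172.25	223.0
GLY	80.10	104.0
HIS	182.88	224.0
ILE	175.12	197.0
LEU	178.63	201.0
LYS	200.81	236.0
MET	194.15	224.0
PHE	199.48	240.0
PRO	136.13	159.0
SER	116.50	155.0
THR	139.27	172.0
TRP	249.36	285.0
TYR	212.76	263.0
VAL	151.44	174.0
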