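# Standard amino acid residue masses (Da). monoisotopic: IUPAC 2021 atomic masses;
# average: standard elemental abundances.
residue	monoisotopic	average
G	57.02146	57.05132
A	71.03711	71.07790
S	87.03203	87.07730
P	97.05276	97.11518
V	99.06841	99.13106
T	101.04768	101.10388
C	103.00918	103.14290
L	113.08406	113.15764
I	113.08406	113.15764
N	114.04293	114.10264
D	115.02694	115.08740
Q	128.05858	128.12922
K	128.09496	128.17228
E	129.04259	129.11398
M	131.04048	131.19606
H	137.05891	137.13928
F	147.06841	147.17386
R	156.10111	156.18568
Y	163.06333	163.17326
W	186.07931	186.21032
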