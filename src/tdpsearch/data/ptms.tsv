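# Bundled post-translational modification table (Unimod-style monoisotopic deltas).
# kind: fixed | variable | terminal | chemical. terminus: none | N | C | protein-N | protein-C.
# propensities: per-residue occurrence propensities "R:p,R:p"; empty means 1.0 for targets.
name	delta_mass	residues	terminus	kind	propensities
Phospho	79.966331	STY	none	variable	S:0.60,T:0.45,Y:0.25
Acetyl	42.010565	K	none	variable	K:0.55
Methyl	14.015650	KR	none	variable	K:0.45,R:0.40
Dimethyl	28.031300	KR	none	variable	K:0.35,R:0.30
Trimethyl	42.046950	K	none	variable	K:0.25
Oxidation	15.994915	MW	none	variable	M:0.50,W:0.20
Hydroxylation	15.994915	PK	none	variable	P:0.40,K:0.15
Deamidation	0.984016	NQ	none	variable	N:0.30,Q:0.20
GG-ubiquitinyl	114.042927	K	none	variable	K:0.20
Succinyl	100.016044	K	none	variable	K:0.20
Malonyl	86.000394	K	none	variable	K:0.15
Crotonyl	68.026215	K	none	variable	K:0.15
Glutaryl	114.031694	K	none	variable	K:0.10
Propionyl	56.026215	K	none	variable	K:0.15
Butyryl	70.041865	K	none	variable	K:0.10
Nitration	44.985078	YW	none	variable	Y:0.20,W:0.10
S-nitrosyl	28.990164	C	none	variable	C:0.25
Carbamidomethyl	57.021464	C	none	fixed
Carbamyl	43.005814	K	N	chemical
Formyl	27.994915	G	protein-N	terminal
N-term-acetyl	42.010565	ACDEFGHIKLMNPQRSTVWY	protein-N	terminal
Pyro-glu	-17.026549	Q	protein-N	terminal
Amidation	-0.984016	ACDEFGHIKLMNPQRSTVWY	protein-C	terminal
Myristoyl	210.198366	G	protein-N	terminal
Farnesyl	204.187801	C	none	variable	C:0.10
Geranylgeranyl	272.250401	C	none	variable	C:0.10
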