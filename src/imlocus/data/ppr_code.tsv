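# Synthetic default PPR code table: residue-pair -> RNA base probabilities.
# Built on the combinatorial two-residue code idea (canonical pair/base
# preferences); the probability values are this package's defaults, not a
# transcription of any published matrix.
# positions=4,34
pair	pA	pC	pG	pU
TN	0.85	0.04	0.07	0.04
SN	0.82	0.06	0.05	0.07
TD	0.03	0.03	0.88	0.06
SD	0.10	0.15	0.55	0.20
ND	0.05	0.10	0.05	0.80
SS	0.15	0.35	0.10	0.40
NN	0.08	0.46	0.06	0.40
NS	0.06	0.78	0.05	0.11
NT	0.20	0.30	0.10	0.40
TT	0.30	0.20	0.25	0.25
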