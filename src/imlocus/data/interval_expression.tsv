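name	kind	pos	rpkm_tm1	rpkm_im	log2_im_vs_tm1	p_value	description
CFB5887	marker	10257310	NA	NA	NA	NA	Flanking SNP marker
Gh_A03G0468	gene	10292732	6.4	1.5	-2.1	0.024	Protoheme IX farnesyltransferase
Gh_A03G0469	gene	10294222	1.2	1.4	0.2	0.052	SUMO-activating enzyme 1B
Gh_A03G0473	gene	10352804	1.5	1.3	-0.2	0.752	None
Gh_A03G0475	gene	10381659	3.1	2.9	-0.1	0.685	FRIGIDA-like protein
Gh_A03G0480	gene	10491490	1.4	1.2	-0.2	0.840	Mitochondrial substrate carrier family protein
Gh_A03G0483	gene	10599666	3.0	2.3	-0.4	0.193	CRUMPLED LEAF
Gh_A03G0484	gene	10616903	16.8	15.9	-0.1	0.660	Sec14p-like phosphatidylinositol transfer protein
CFB5888	marker	10999373	NA	NA	NA	NA	Flanking SNP marker
Gh_A03G0489	gene	11022670	2.4	1.0	-1.3	0.164	Pentatricopeptide repeat (PPR) protein, mitochondrial
CFBid0001	marker	11025170	NA	NA	NA	NA	im-linked 22-bp deletion in exon of PPR
Gh_A03G0491	gene	11449872	12.7	9.6	-0.4	0.192	Chaperone protein ClpC, chloroplastic
Gh_A03G0492	gene	11458109	4.0	4.3	0.1	0.139	Copper methylamine oxidase
Gh_A03G0493	gene	11495867	29.6	26.1	-0.2	0.933	NBR1, a selective autophagy substrate
Gh_A03G0495	gene	11523884	2.9	1.8	-0.7	0.676	None
Gh_A03G0496	gene	11525162	1.1	0.3	-1.9	0.126	None
Gh_A03G0498	gene	11626203	14.3	13.5	-0.1	0.457	RAB GTPase homolog E1B
Gh_A03G0500	gene	11796370	1.7	1.9	0.2	0.529	Pectin methylesterase inhibitor superfamily protein
CFBid0002	marker	12155364	NA	NA	NA	NA	Flanking deletion marker
Gh_A03G0506	gene	12155624	0.0	0.0	1.6	0.559	NAC 007
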