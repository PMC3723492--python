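res_id	res_name	res_class	mean_depth	sd_depth
711	PRO	hydrophobic	16.8	1.9
714	PRO	hydrophobic	16.4	2.0
715	TRP	hydrophobic	15.0	1.7
717	LEU	hydrophobic	19.0	2.2
721	VAL	hydrophobic	15.2	1.6
722	PHE	hydrophobic	13.7	1.6
710	ARG	basic	19.0	2.2
719	LYS	basic	18.3	1.6
712	SER	polar	19.4	1.8
713	ASN	polar	20.6	2.0
716	GLU	polar	20.7	1.7
720	THR	polar	17.2	2.0
723	GLY	polar	18.9	1.6
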