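transcript	hgvs_c	hgvs_p	variant_type	evidence	assigned_class	source	allele_count	allele_number	clinvar_label	sift	polyphen2	mutationtaster2	bayesdel	mutpred2	revel	vest4	region_flags
NM_000045.3	c.131-4_131-2del	p.?	splice_site	PVS1	LP	unpublished			not_reported								within_10bp_of_junction
NM_000045.4	c.131-7_131-2del	p.?	splice_site	PVS1	LP	unpublished			VUS								within_10bp_of_junction
NM_001244438.1	c.272delAins	p.(Lys91fs)	frameshift	PVS1	LP	unpublished			not_reported (similar variant classified pathogenic)								coding
NM_000045.4	c.161dupA	p.(Asp54fs)	frameshift	PVS1	LP	unpublished			not_reported								coding
NM_000045.4	c.145_146del	p.(Leu49fs)	frameshift	PVS1	LP	unpublished			VUS								coding
NM_000045.4	c.146dup	p.(Leu49fs)	frameshift	PVS1	LP	unpublished			VUS								coding
NM_000045.4	c.139_140del	p.(Asn47fs)	frameshift	PVS1	LP	unpublished			not_reported								coding
NM_000045.4	c.129del	p.(Val44fs)	frameshift	PVS1	P	unpublished			Pathogenic/likely pathogenic								coding
NM_000045.4	c.57+2_57+6del	p.?	splice_site	PVS1	LP	unpublished			Likely pathogenic								within_10bp_of_junction
NM_000045.4	c.3G>A	p.(Met1?)	start_loss	PVS1, PS1	P	unpublished			Pathogenic/likely pathogenic								coding
NM_000045.4	c.627_628del	p.(Glu210fs)	frameshift	PVS1	LP	unpublished			Pathogenic								coding
NM_000045.4	c.938del	p.(Gly313fs)	frameshift	PVS1	LP	unpublished			not_reported								coding
NM_000045.4	c.946C>T	p.(Arg316Trp)	missense	PM5, PP2, PP3	LP	unpublished			VUS								coding
NM_000045.4	c.164_165del	p.(Val55fs)	frameshift	PVS1	LP	unpublished			Likely pathogenic								coding
NM_000045.4	c.146delTins	p.(Leu49fs)	frameshift	PVS1	LP	unpublished			not_reported								coding
NM_000045.4	c.169_170del	p.(Asp57fs)	frameshift	PVS1	LP	unpublished			not_reported								coding
NM_000045.4	c.161delAinsNN	p.(Asp54fs)	frameshift	PVS1	LP	unpublished			not_reported								coding
NM_000045.4	c.320dupG	p.(Asp108fs)	frameshift	PVS1	LP	unpublished			not_reported								coding
NM_000045.4	c.340G>A	p.(Gly114Arg)	missense	PM1, PM5, PP2, PP3	LP	unpublished			not_reported								coding
NM_000045.4	c.394G>T	p.(Asp132Tyr)	missense	PM1, PP2, PP3	LP	unpublished			Likely pathogenic								coding
NM_000045.4	c.573_576del	p.(Asp191fs)	frameshift	PVS1	LP	unpublished			not_reported								coding
NM_000045.4	c.950_953del	p.(Glu317fs)	frameshift	PVS1	LP	unpublished			not_reported								coding
NM_000045.4	c.962del	p.(Lys321fs)	frameshift	PVS1	P	unpublished			not_reported								coding
NM_000045.4	c.395A>G	p.(Asp132Gly)	missense	PM1, PM5, PP2, PP3	LP	unpublished			not_reported								coding
NM_000045.4	c.437G>T	p.(Gly146Val)	missense	PM1, PP2, PP3	LP	unpublished			Pathogenic/VUS								coding
NM_000045.4	c.489+1G>A	p.?	splice_site	PVS1	LP	unpublished			not_reported								within_10bp_of_junction
NM_000045.4	c.549_552del	p.(Tyr184fs)	frameshift	PVS1	LP	unpublished			not_reported								coding
NM_000045.4	c.620C>A	p.(Ser207*)	nonsense	PVS1	LP	unpublished			not_reported								coding
NM_000045.4	c.925_928del	p.(Ala310fs)	frameshift	PVS1	LP	unpublished			not_reported								coding
NM_000045.4	c.703delAins	p.(Ile235fs)	frameshift	PVS1	LP	unpublished			not_reported								coding
NM_000045.4	c.827-2A>T	p.?	splice_site	PVS1	LP	unpublished			not_reported								within_10bp_of_junction
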