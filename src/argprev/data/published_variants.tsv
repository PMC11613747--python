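transcript	hgvs_c	hgvs_p	variant_type	evidence	assigned_class	source	allele_count	allele_number	clinvar_label	sift	polyphen2	mutationtaster2	bayesdel	mutpred2	revel	vest4	region_flags
NM_000045.4	c.560+5G>A	p.?	splice_site	PP3	VUS	published											within_10bp_of_junction
NM_000045.4	c.231C>A	p.(Ser77Arg)	missense	PP2	VUS	published											coding
NM_000045.4	c.221G>T	p.(Gly74Val)	missense	PP2	VUS	published											coding
NM_000045.4	c.212G>C	p.(Arg71Thr)	missense	PP2	VUS	published											coding
NM_000045.4	c.58-3C>G	p.?	splice_site	PP3	VUS	published											within_10bp_of_junction
NM_000045.4	c.23T>A	p.(Ile8Lys)	missense	PP2	VUS	published											coding
NM_000045.4	c.798A>C	p.(Lys266Asn)	missense	PP2, BS1	VUS	published											coding
NM_000045.4	c.del116_188	p.?	gross_deletion	PVS1	LP	published											coding
NM_000045.4	NC_000006.12:g.131576244_131586997del	p.?	gross_deletion	PVS1	LP	published											coding
NM_000045.4	c.306-611T>C	p.?	intronic	BP7	VUS	published											
NM_000045.4	c.466-2A>G	p.?	splice_site	PVS1	P	published											within_10bp_of_junction
NM_000045.4	c.666-2A>G	p.?	splice_site	PVS1	P	published											within_10bp_of_junction
NM_000045.4	c.466-1G>C	p.?	splice_site	PVS1	P	published											within_10bp_of_junction
NM_000045.4	c.121_122insCTT	p.(Lys41delinsThrTer)	nonsense	PVS1	LP	published											coding
NM_000045.4	c.124G>T	p.(Glu42*)	nonsense	PVS1	P	published											coding
NM_000045.4	c.132del	p.()	frameshift	PVS1	LP	published											coding
NM_000045.4	c.2T>C	p.(Met1?)	start_loss	PVS1, PS1	P	published											coding
NM_000045.4	c.206A>T	p.(Asn69Ile)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.223A>T	p.(Lys75*)	nonsense	PVS1	LP	published											coding
NM_000045.4	c.232dup	p.(Glu78fs)	frameshift	PVS1	LP	published											coding
NM_000045.4	c.263_266del	p.(Lys88fs)	frameshift	PVS1	P	published											coding
NM_000045.4	c.282C>G	p.(Ser94Arg)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.292G>A	p.(Gly98Ser)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.295G>A	p.(Gly99Arg)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.298G>A	p.(Asp100Asn)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.316G>C	p.()	missense	PM1, PM5, PP2, PP3	LP	published											coding
NM_000045.4	c.32T>C	p.(Ile11Thr)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.34G>T	p.(Gly12*)	nonsense	PVS1	LP	published											coding
NM_000045.4	c.365G>A	p.(Trp122*)	nonsense	PVS1	P	published											coding
NM_000045.4	c.374C>T	p.(Ala125Val)	missense	PM1, PP2, PP3	LP	published											coding
NM_000045.4	c.383A>G	p.(Asp128Gly)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.386_388del	p.(Ile129del)	inframe_deletion	PM1, PM4	LP	published											coding
NM_000045.4	c.401C>T	p.(Thr134Ile)	missense	PM1, PP2, PP3	LP	published											coding
NM_000045.4	c.413G>T	p.(Gly138Val)	missense	PM1, PP2, PP3	LP	published											coding
NM_000045.4	c.422A>T	p.(His141Leu)	missense	PM1, PP2, PP3	LP	published											coding
NM_000045.4	c.425G>A	p.(Gly142Glu)	missense	PM1, PP2, PP3	LP	published											coding
NM_000045.4	c.434T>A	p.(Val145Glu)	missense	PM1, PP2, PP3	LP	published											coding
NM_000045.4	c.446T>C	p.(Leu149Pro)	missense	PM1, PP2, PP3	LP	published											coding
NM_000045.4	c.523del	p.(Val175fs)	frameshift	PVS1	LP	published											coding
NM_000045.4	c.53G>A	p.(Gly18Glu)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.539G>C	p.(Arg180Thr)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.551del	p.(Pro184fs)	frameshift	PVS1	LP	published											coding
NM_000045.4	c.603_604del	p.(Glu202fs)	frameshift	PVS1	P	published											coding
NM_000045.4	c.61C>T	p.(Arg21*)	nonsense	PVS1	P	published											coding
NM_000045.4	c.646_649del	p.(Leu216fs)	frameshift	PVS1	P	published											coding
NM_000045.4	c.647T>C	p.(Leu216Pro)	missense	PM3, PP2, PP3	LP	published											coding
NM_000045.4	c.673delA	p.(Arg225fs)	frameshift	PVS1	LP	published											coding
NM_000045.4	c.682C>G	p.(His228Asp)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.695A>T	p.(Asp232Val)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.700G>C	p.(Asp234His)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.70del	p.(Val24fs)	frameshift	PVS1	LP	published											coding
NM_000045.4	c.703G>A	p.(Gly235Arg)	missense	PS1, PP2, PP3	LP	published											coding
NM_000045.4	c.703G>C	p.(Gly235Arg)	missense	PS1, PP2, PP3	LP	published											coding
NM_000045.4	c.704del	p.(Gly235fs)	frameshift	PVS1	LP	published											coding
NM_000045.4	c.707T>C	p.(Leu236Pro)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.708_712dup	p.(Pro238fs)	frameshift	PVS1	LP	published											coding
NM_000045.4	c.78del	p.(Gly27fs)	frameshift	PVS1	P	published											coding
NM_000045.4	c.80G>A	p.(Gly27Asp)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.820G>A	p.(Asp274Asn)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.837C>A	p.(Asn279Lys)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.844del	p.(Leu282fs)	frameshift	PVS1	P	published											coding
NM_000045.4	c.849del	p.(Lys284fs)	frameshift	PVS1	LP	published											coding
NM_000045.4	c.866dup	p.(Thr290fs)	frameshift	PVS1	LP	published											coding
NM_000045.4	c.871C>T	p.(Arg291*)	nonsense	PVS1	P	published											coding
NM_000045.4	c.877del	p.(Val293fs)	frameshift	PVS1	LP	published											coding
NM_000045.4	c.892G>C	p.(Ala298Pro)	missense	PP2	VUS	published											coding
NM_000045.4	c.913G>A	p.(Gly305Arg)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.923G>A	p.(Arg308Gln)	missense	PP2, PP3	VUS	published											coding
NM_000045.4	c.93del	p.(Arg32fs)	frameshift	PVS1	P	published											coding
NM_000045.4	Exon 1 Deletion	p.?	exon_deletion	PVS1	LP	published											coding
NM_000045.4	c.130+1 G>A	p.?	splice_site	PVS1	P	published											within_10bp_of_junction
NM_000045.4	c.57+1G>A	p.?	splice_site	PVS1	P	published											within_10bp_of_junction
NM_000045.4	c.802+2T>G	p.?	splice_site	PVS1	LP	published											within_10bp_of_junction
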