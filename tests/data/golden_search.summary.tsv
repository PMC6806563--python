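variant_id	chrom	pos	edit_class	any_targetable	combined_targetable	combined_preferential	targetable_editors	preferential_editors
1	chr1	251	create_c_to_t	true	true	false	VQR-BE3,xBE3	.
2	chr1	351	create_c_to_t	true	true	true	SaKKH-BE3,xBE3	xBE3
3	chr1	1261	create_c_to_t	true	true	false	SaKKH-BE3,xBE3	.
4	chr1	424	create_c_to_t	false	false	false	.	.
5	chr1	451	correct_t_to_c	true	true	false	SaKKH-BE3	.
6	chr1	806	correct_t_to_c	true	true	true	SaKKH-BE3,VQR-BE3,xBE3	SaKKH-BE3,VQR-BE3,xBE3
7	chr1	147	correct_t_to_c	true	true	true	AncBE4max,BE-PLUS,BE3,BE4max,EE-BE3,VRER-BE3,YE1-BE3,YE2-BE3,YEE-BE3,eBE-S3,hA3A-BE3,hA3A-BE3-Y130F,hA3A-eBE-Y130F,xBE3	EE-BE3,YE1-BE3,YE2-BE3,YEE-BE3
8	chr1	1031	correct_t_to_c	true	true	false	xBE3	.
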