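# Default cytosine base editor panel: targeting geometry only.
# Protospacer positions are counted 5'->3' along the protospacer, position 1 at
# the 5'-most base. For a 3'-PAM (Cas9-family) editor that makes position 1
# PAM-distal; for a 5'-PAM (Cpf1/Cas12a-family) editor position 1 is
# PAM-proximal. pam_side is the side of the PAM relative to the protospacer.
# citation: primary publication the geometry was transcribed from.
name	pam_pattern	pam_side	spacer_length	window_start	window_end	citation
BE3	NGG	three_prime	20	4	8	Komor et al. 2016 Nature 533:420
eBE-S3	NGG	three_prime	20	4	8	Wang et al. 2017 Cell Res 27:1289
BE4max	NGG	three_prime	20	4	8	Koblan et al. 2018 Nat Biotechnol 36:843
AncBE4max	NGG	three_prime	20	4	8	Koblan et al. 2018 Nat Biotechnol 36:843
hA3A-BE3	NGG	three_prime	20	2	13	Wang et al. 2018 Nat Biotechnol 36:946
hA3A-BE3-Y130F	NGG	three_prime	20	3	8	Wang et al. 2018 Nat Biotechnol 36:946
hA3A-eBE-Y130F	NGG	three_prime	20	3	8	Wang et al. 2018 Nat Biotechnol 36:946
YE1-BE3	NGG	three_prime	20	5	7	Kim et al. 2017 Nat Biotechnol 35:371
YE2-BE3	NGG	three_prime	20	5	6	Kim et al. 2017 Nat Biotechnol 35:371
EE-BE3	NGG	three_prime	20	5	6	Kim et al. 2017 Nat Biotechnol 35:371
YEE-BE3	NGG	three_prime	20	5	6	Kim et al. 2017 Nat Biotechnol 35:371
VQR-BE3	NGA	three_prime	20	4	11	Kim et al. 2017 Nat Biotechnol 35:371
EQR-BE3	NGAG	three_prime	20	4	11	Kim et al. 2017 Nat Biotechnol 35:371
VRER-BE3	NGCG	three_prime	20	3	10	Kim et al. 2017 Nat Biotechnol 35:371
SaBE3	NNGRRT	three_prime	21	3	12	Kim et al. 2017 Nat Biotechnol 35:371
SaKKH-BE3	NNNRRT	three_prime	21	3	12	Kim et al. 2017 Nat Biotechnol 35:371
xBE3	NG	three_prime	20	4	8	Hu et al. 2018 Nature 556:57
Target-AID	NGG	three_prime	20	2	4	Nishida et al. 2016 Science 353:aaf8729
BE-PLUS	NGG	three_prime	20	4	14	Jiang et al. 2018 Cell Res 28:855
dCpf1-eBE	TTTV	five_prime	23	8	13	Li et al. 2018 Nat Biotechnol 36:324
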