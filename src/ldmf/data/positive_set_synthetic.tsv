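protein_id	anchor	core	label
PXN	30	DLDALLADLE	positive
PXN	80	ELDRLLLELN	positive
PXN	144	ELDELMASLS	positive
PXN	200	SLDRLLQELE	positive
LPXN	28	ELDSLLQELE	positive
LPXN	85	ALDELLDSLK	positive
LPXN	150	ELDALMSELR	positive
LPXN	210	TLDSLLADLQ	positive
TGFB1I1	35	ELDDLMAQLS	positive
TGFB1I1	90	QLDGLLAELE	positive
TGFB1I1	148	AVDELLHSLD	positive
TGFB1I1	205	ELESLLMRLQ	positive
PAXB	30	NLDSLLSDLE	positive
PAXB	88	SLDELLNNLG	positive
PAXB	145	ELDKLMDSLS	positive
PAXB	202	TVDDLLSTLE	positive
DLC1	60	ALDDLIDTLG	positive
ROXAN	45	SLTSILADLE	positive
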