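roi_id	name	hemisphere	homotopic_partner
L_FP	Frontal Pole Left	L	R_FP
R_FP	Frontal Pole Right	R	L_FP
L_IC	Insular Cortex Left	L	R_IC
R_IC	Insular Cortex Right	R	L_IC
L_SFG	Superior Frontal Gyrus Left	L	R_SFG
R_SFG	Superior Frontal Gyrus Right	R	L_SFG
L_MidFG	Middle Frontal Gyrus Left	L	R_MidFG
R_MidFG	Middle Frontal Gyrus Right	R	L_MidFG
L_IFGtri	Inferior Frontal Gyrus, pars triangularis Left	L	R_IFGtri
R_IFGtri	Inferior Frontal Gyrus, pars triangularis Right	R	L_IFGtri
L_IFGoper	Inferior Frontal Gyrus, pars opercularis Left	L	R_IFGoper
R_IFGoper	Inferior Frontal Gyrus, pars opercularis Right	R	L_IFGoper
L_PreCG	Precentral Gyrus Left	L	R_PreCG
R_PreCG	Precentral Gyrus Right	R	L_PreCG
L_TP	Temporal Pole Left	L	R_TP
R_TP	Temporal Pole Right	R	L_TP
L_aSTG	Superior Temporal Gyrus, anterior division Left	L	R_aSTG
R_aSTG	Superior Temporal Gyrus, anterior division Right	R	L_aSTG
L_pSTG	Superior Temporal Gyrus, posterior division Left	L	R_pSTG
R_pSTG	Superior Temporal Gyrus, posterior division Right	R	L_pSTG
L_aMTG	Middle Temporal Gyrus, anterior division Left	L	R_aMTG
R_aMTG	Middle Temporal Gyrus, anterior division Right	R	L_aMTG
L_pMTG	Middle Temporal Gyrus, posterior division Left	L	R_pMTG
R_pMTG	Middle Temporal Gyrus, posterior division Right	R	L_pMTG
L_toMTG	Middle Temporal Gyrus, temporooccipital part Left	L	R_toMTG
R_toMTG	Middle Temporal Gyrus, temporooccipital part Right	R	L_toMTG
L_aITG	Inferior Temporal Gyrus, anterior division Left	L	R_aITG
R_aITG	Inferior Temporal Gyrus, anterior division Right	R	L_aITG
L_pITG	Inferior Temporal Gyrus, posterior division Left	L	R_pITG
R_pITG	Inferior Temporal Gyrus, posterior division Right	R	L_pITG
L_toITG	Inferior Temporal Gyrus, temporooccipital part Left	L	R_toITG
R_toITG	Inferior Temporal Gyrus, temporooccipital part Right	R	L_toITG
L_PostCG	Postcentral Gyrus Left	L	R_PostCG
R_PostCG	Postcentral Gyrus Right	R	L_PostCG
L_SPL	Superior Parietal Lobule Left	L	R_SPL
R_SPL	Superior Parietal Lobule Right	R	L_SPL
L_aSMG	Supramarginal Gyrus, anterior division Left	L	R_aSMG
R_aSMG	Supramarginal Gyrus, anterior division Right	R	L_aSMG
L_pSMG	Supramarginal Gyrus, posterior division Left	L	R_pSMG
R_pSMG	Supramarginal Gyrus, posterior division Right	R	L_pSMG
L_AG	Angular Gyrus Left	L	R_AG
R_AG	Angular Gyrus Right	R	L_AG
L_sLOC	Lateral Occipital Cortex, superior division Left	L	R_sLOC
R_sLOC	Lateral Occipital Cortex, superior division Right	R	L_sLOC
L_iLOC	Lateral Occipital Cortex, inferior division Left	L	R_iLOC
R_iLOC	Lateral Occipital Cortex, inferior division Right	R	L_iLOC
L_ICC	Intracalcarine Cortex Left	L	R_ICC
R_ICC	Intracalcarine Cortex Right	R	L_ICC
L_SMA	Juxtapositional Lobule Cortex (Supplementary Motor Area) Left	L	R_SMA
R_SMA	Juxtapositional Lobule Cortex (Supplementary Motor Area) Right	R	L_SMA
L_PaCiG	Paracingulate Gyrus Left	L	R_PaCiG
R_PaCiG	Paracingulate Gyrus Right	R	L_PaCiG
L_Cuneal	Cuneal Cortex Left	L	R_Cuneal
R_Cuneal	Cuneal Cortex Right	R	L_Cuneal
L_FOrb	Frontal Orbital Cortex Left	L	R_FOrb
R_FOrb	Frontal Orbital Cortex Right	R	L_FOrb
L_aPaHC	Parahippocampal Gyrus, anterior division Left	L	R_aPaHC
R_aPaHC	Parahippocampal Gyrus, anterior division Right	R	L_aPaHC
L_pPaHC	Parahippocampal Gyrus, posterior division Left	L	R_pPaHC
R_pPaHC	Parahippocampal Gyrus, posterior division Right	R	L_pPaHC
L_LG	Lingual Gyrus Left	L	R_LG
R_LG	Lingual Gyrus Right	R	L_LG
L_aTFusC	Temporal Fusiform Cortex, anterior division Left	L	R_aTFusC
R_aTFusC	Temporal Fusiform Cortex, anterior division Right	R	L_aTFusC
L_pTFusC	Temporal Fusiform Cortex, posterior division Left	L	R_pTFusC
R_pTFusC	Temporal Fusiform Cortex, posterior division Right	R	L_pTFusC
L_TOFusC	Temporal Occipital Fusiform Cortex Left	L	R_TOFusC
R_TOFusC	Temporal Occipital Fusiform Cortex Right	R	L_TOFusC
L_OFusG	Occipital Fusiform Gyrus Left	L	R_OFusG
R_OFusG	Occipital Fusiform Gyrus Right	R	L_OFusG
L_FO	Frontal Operculum Cortex Left	L	R_FO
R_FO	Frontal Operculum Cortex Right	R	L_FO
L_CO	Central Opercular Cortex Left	L	R_CO
R_CO	Central Opercular Cortex Right	R	L_CO
L_PO	Parietal Operculum Cortex Left	L	R_PO
R_PO	Parietal Operculum Cortex Right	R	L_PO
L_PP	Planum Polare Left	L	R_PP
R_PP	Planum Polare Right	R	L_PP
L_HG	Heschl's Gyrus Left	L	R_HG
R_HG	Heschl's Gyrus Right	R	L_HG
L_PT	Planum Temporale Left	L	R_PT
R_PT	Planum Temporale Right	R	L_PT
L_SCC	Supracalcarine Cortex Left	L	R_SCC
R_SCC	Supracalcarine Cortex Right	R	L_SCC
L_OP	Occipital Pole Left	L	R_OP
R_OP	Occipital Pole Right	R	L_OP
L_Thal	Thalamus Left	L	R_Thal
R_Thal	Thalamus Right	R	L_Thal
L_Caud	Caudate Left	L	R_Caud
R_Caud	Caudate Right	R	L_Caud
L_Put	Putamen Left	L	R_Put
R_Put	Putamen Right	R	L_Put
L_Pall	Pallidum Left	L	R_Pall
R_Pall	Pallidum Right	R	L_Pall
L_hippo	Hippocampus Left	L	R_hippo
R_hippo	Hippocampus Right	R	L_hippo
L_amyg	Amygdala Left	L	R_amyg
R_amyg	Amygdala Right	R	L_amyg
L_Acc	Accumbens Left	L	R_Acc
R_Acc	Accumbens Right	R	L_Acc
MedFC	Frontal Medial Cortex	M	.
SubCalC	Subcallosal Cortex	M	.
AC	Cingulate Gyrus, anterior division	M	.
PC	Cingulate Gyrus, posterior division	M	.
Precuneus	Precuneus Cortex	M	.
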