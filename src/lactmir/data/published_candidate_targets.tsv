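# Candidate target genes for the 22 differentially expressed miRNAs with a
# consensus of at least three prediction programs. Columns: miRNA id,
# comma-separated ordered gene list, printed total gene count (TG), printed
# supporting-program count (NS). Gene symbols are kept verbatim as printed.
miRNA	genes	tg	ns
bta-miR-29b	COL3A1,FBN1,COL11A1,COL1A2,IREB2,TRIB2,MYCN,BLMH,PPM1D,DNMT3A,ISL1,PDGFB,ARVCF,ZBTB40	14	7
bta-miR-29c	TRAF4,PMP22,COL4A2,DNAJB11,CRISPLD1,PDGFB,FBN1,BLMH,ISL1,YY1,PPM1D,IREB2,FOS,MYCN,RLF,HMCN1,HMGN3,DNMT3A,SGK	19	6
bta-miR-375	YBX1,QKI,ELAVL4,ZFPM2,HOXA3,UBE3A,PDE4D,YAP1,TSC22D2,TIMM8A,EBF3,PRKD1,HABP2,C13orf23	14	5
bta-miR-135a	NR3C2,CTTNBP2,SP3,VLDLR,PTK2,ARHGEF4,ADCYAP1,KCNMA1,BTBD10,WAC,NBEA,INHBA,TRPM7,ELOVL6,RAP2A,USP15	16	6
bta-miR-22-5p	BIN1,WDR26,SV2A,SATB2,BCL9,MAT2A,MAP3K12,FNBP4,FAM49B,BCL9L,YARS,RBM15,WDFY3,STAG2,DNAJB5,WDTC1,SIRT1,LRRC1	18	5
bta-miR-214	ZBTB20,ARPC5L,KPNA3,ARVCF,RAB14,WDTC1,ITCH,KLC2,RTN2	9	6
bta-miR-33a	ABCA1,KPNA4,ZNF281,SLC25A25,YWHAH,SATB2,HADHB,EEF1A1,CACNA1C,CAMK2G,ATP1B1	11	6
bta-miR-451	TTN,OSR1,PMM2,C11orf30,AEBP2,SAMD4B,TBX1,FBXO33,CDKN2D,YWHAZ,YTHDF2,CAB39,ZNF644	13	3
bta-miR-190a	NEUROD1,WSB1,TNRC6A,NBEA,HECA,C20orf112	6	6
bta-miR-378	TOB2,C11orf49,SOX7,DDAH1,SULF1,SRC,DYRK1A,DBT,STAC2	9	3
bta-miR-423-5p	SUFU,NTN1,STK24,AP2A1,DAB2IP,MYBL2,CAMTA2	7	3
bta-miR-7	SPATA2,ARID4A,GLI3,SNCA,KCNJ2,KLF4,WDR47,PDE4D,PFN2,GATA6,PHF21A,LEMD3,PPARGC1A	13	6
bta-miR-99a	HOXA1,MBNL1,MTMR3,HS3ST2,SMAD7,HNRPU	6	5
bta-miR-185	ATP6V1F,IKZF4,SLC16A2,CA10,EPHB2,PAK6,DTX3,NEUROD2,CDC42,EIF2C1,SF1,PHYHIP,CPEB2,FAM53B,PRX,RAB14,GATAD2B,IGSF4C,RAE1	19	5
bta-miR-1	FNDC3A,E2F5,KTN1,DDX5,CLTC,EIF4E	6	7
bta-miR-125a	GTPBP2,RAPGEFL1,ABHD3,ATP1B4,PPP1CA,ACCN2	6	5
bta-miR-382	TOP1,HSPA2,EEF1A1,RPE,SYNCRIP,CLTC	6	4
bta-miR-22-3p	FAM49B,SIRT1,DNAJB5,RBM15,BCL9L,STAG2,LRRC1,FNBP4,SATB2,BCL9,MAP3K12,SV2A,WDFY3	13	6
bta-miR-660	DCBLD2,SDC1,DNAJA2	3	3
bta-miR-100	HS3ST2,FGFR3,SMARCA5,EIF2C2,FZD8,TRIB2,SMAD7,MTMR3,HOXA1,HNRPU	10	5
bta-miR-146a	IRAK1,STRBP,NOVA1,KLF7,LRRC15,USP3,STC1,CASK,SH3GL2,ROBO1,PHOX2B,PPP1R11,RUNX1T1,ZFYVE1,BCL11A,CNTFR,MYT1,ELAVL1,SYT1,NRP2,HIC2,EIF5A2,FBXL10,KCTD15,DLGAP1,SLC25A14,SPIB	27	4
bta-miR-184	SF1,SIDT2,EIF2C2,CREB3L1,INPPL1,RASL10B,PRKCB1	7	4
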